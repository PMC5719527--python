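"""Synthetic ground truth and mock classifier outputs.

The generator emulates the study design the consensus method targets: a set
of OTUs (default 500, the per-dataset sample size used for comparative
analysis) with known 7-rank lineages drawn from a small consistent taxonomy
tree, and three classifiers that each report a noisy, scored version of the
truth in their native output dialect.

Per source, per OTU, ranks are scanned Kingdom to Species: with probability
``dropout`` the call is dropped and the lineage truncated there (classifiers
abstain hierarchically); otherwise, with probability ``error`` a wrong name
is reported — drawn from the true taxon's siblings so wrong calls stay
plausible — with a confidence from the lower score interval, else the true
name with a confidence from the higher interval.

All randomness flows from a single integer seed through numpy SeedSequence
spawning, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .core import (
    N_RANKS,
    RANKS,
    SOURCES,
    RankedLineage,
    ScoredAssignment,
    TaxonomyError,
    TaxonomyTable,
)
from .refdb import UniteRecord

RateSpec = Union[float, Mapping[str, Sequence[float]]]


@dataclass
class SimulationSpec:
    """Parameters of one synthetic dataset.

    ``dropout`` and ``error`` may be a single rate applied to every source
    and rank, or a mapping source -> 7 per-rank rates.  Scores for correct
    calls are uniform on ``correct_score_range``; wrong or low-confidence
    calls draw from the lower ``wrong_score_range``, so a 0.8 cutoff removes
    most but not all of them.
    """

    n_otus: int = 500
    n_taxa: tuple[int, ...] = (2, 4, 8, 12, 16, 24, 32)
    dropout: RateSpec = 0.2
    error: RateSpec = 0.1
    correct_score_range: tuple[float, float] = (0.85, 1.0)
    wrong_score_range: tuple[float, float] = (0.55, 0.9)
    seed: int = 42

    def __post_init__(self):
        if self.n_otus <= 0:
            raise TaxonomyError("n_otus must be positive")
        if len(self.n_taxa) != N_RANKS or any(n < 1 for n in self.n_taxa):
            raise TaxonomyError(
                "n_taxa must give a positive taxon count for each of the "
                f"{N_RANKS} ranks")
        for spec in (self.dropout, self.error):
            for r in self._flatten(spec):
                if not (0.0 <= r <= 1.0):
                    raise TaxonomyError(f"rate {r} outside [0, 1]")
        for lo, hi in (self.correct_score_range, self.wrong_score_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise TaxonomyError("score intervals must lie within [0, 1]")

    @staticmethod
    def _flatten(spec: RateSpec) -> list[float]:
        if isinstance(spec, Mapping):
            return [float(r) for rates in spec.values() for r in rates]
        return [float(spec)]

    def rate(self, spec: RateSpec, source: str, rank_index: int) -> float:
        if isinstance(spec, Mapping):
            return float(spec[source][rank_index])
        return float(spec)


@dataclass
class TruthSet:
    """A consistent toy taxonomy with per-OTU ground-truth lineages."""

    #: per rank, the taxon names at that rank
    taxa: list[list[str]]
    #: per rank > 0, parent index (at the rank above) of each taxon
    parents: list[np.ndarray]
    #: ground truth, keyed by OTU id
    lineages: dict[str, RankedLineage]
    #: toy UNITE-style reference entries, one per species
    reference: list[UniteRecord] = field(default_factory=list)

    def siblings(self, rank_index: int, taxon_index: int) -> list[int]:
        """Other taxa at this rank sharing the taxon's parent (any other
        taxon at the rank if the parent has a single child)."""
        n = len(self.taxa[rank_index])
        others = [j for j in range(n) if j != taxon_index]
        if rank_index == 0:
            return others
        par = self.parents[rank_index - 1]
        same = [j for j in others if par[j] == par[taxon_index]]
        return same or others


def _rank_name(rank_index: int, taxon_index: int) -> str:
    return f"{RANKS[rank_index]}_{taxon_index + 1:03d}"


def simulate_truth(spec: SimulationSpec,
                   rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Build the toy taxonomy tree, OTU truths and the reference FASTA set.

    Each taxon below Kingdom gets one uniformly drawn parent at the rank
    above, so the taxonomy is a tree by construction; each OTU's lineage is
    the root-ward path from a uniformly drawn species.  Deterministic given
    ``spec.seed``.
    """
    if rng is None:
        rng = np.random.default_rng([spec.seed, 0])
    taxa = [[_rank_name(r, j) for j in range(spec.n_taxa[r])]
            for r in range(N_RANKS)]
    parents = [rng.integers(0, spec.n_taxa[r], size=spec.n_taxa[r + 1])
               for r in range(N_RANKS - 1)]

    def path_from_species(sp: int) -> tuple[str, ...]:
        idx = [0] * N_RANKS
        idx[N_RANKS - 1] = sp
        for r in range(N_RANKS - 1, 0, -1):
            idx[r - 1] = int(parents[r - 1][idx[r]])
        return tuple(taxa[r][idx[r]] for r in range(N_RANKS))

    width = max(5, len(str(spec.n_otus)))
    species_choice = rng.integers(0, spec.n_taxa[-1], size=spec.n_otus)
    lineages = {
        f"OTU_{i + 1:0{width}d}": RankedLineage(path_from_species(int(sp)))
        for i, sp in enumerate(species_choice)}

    bases = np.array(list("ACGT"))
    reference = []
    for sp in range(spec.n_taxa[-1]):
        seq = "".join(rng.choice(bases, size=120))
        reference.append(UniteRecord(
            seq_id=f"ACC{sp + 1:05d}",
            sh_code=f"SH{sp + 1:06d}.07FU",
            lineage=RankedLineage(path_from_species(sp)),
            sequence=seq))
    return TruthSet(taxa, parents, lineages, reference)


def _taxon_index(truth: TruthSet, rank_index: int, name: str) -> int:
    return truth.taxa[rank_index].index(name)


def simulate_classifier_tables(truth: TruthSet, spec: SimulationSpec,
                               rng: Optional[np.random.Generator] = None
                               ) -> dict[str, TaxonomyTable]:
    """Generate the three classifiers' noisy tables (in memory)."""
    if rng is None:
        rng = np.random.default_rng([spec.seed, 1])
    clo, chi = spec.correct_score_range
    wlo, whi = spec.wrong_score_range
    tables = {}
    for source in SOURCES:
        table = TaxonomyTable(source)
        for otu_id, lineage in truth.lineages.items():
            names: list[Optional[str]] = [None] * N_RANKS
            scores: list[Optional[float]] = [None] * N_RANKS
            for r in range(N_RANKS):
                if rng.random() < spec.rate(spec.dropout, source, r):
                    break  # hierarchical truncation at the first dropout
                true_name = lineage.names[r]
                sibs = truth.siblings(r, _taxon_index(truth, r, true_name))
                if sibs and rng.random() < spec.rate(spec.error, source, r):
                    names[r] = truth.taxa[r][int(rng.choice(sibs))]
                    scores[r] = float(rng.uniform(wlo, whi))
                else:
                    names[r] = true_name
                    scores[r] = float(rng.uniform(clo, chi))
            table.assignments[otu_id] = ScoredAssignment(
                otu_id, RankedLineage(tuple(names)), tuple(scores))
        tables[source] = table
    return tables


def simulate_classifier_outputs(truth: TruthSet, spec: SimulationSpec,
                                rng: Optional[np.random.Generator] = None
                                ) -> dict[str, str]:
    """Serialize the noisy tables in each classifier's native dialect."""
    from .classifier_io import write_rdp, write_sintax, write_utax

    tables = simulate_classifier_tables(truth, spec, rng)
    return {
        "RDP": write_rdp(tables["RDP"]),
        "UTAX": write_utax(tables["UTAX"]),
        "SINTAX": write_sintax(tables["SINTAX"]),
    }


@dataclass(frozen=True)
class RankEvaluation:
    """Truth-based confusion counts at one rank."""

    rank: str
    n_assigned: int
    n_correct: int
    n_total: int

    @property
    def accuracy(self) -> Optional[float]:
        """Fraction of assigned OTUs whose name matches the truth; ``None``
        when nothing is assigned at this rank."""
        if self.n_assigned == 0:
            return None
        return self.n_correct / self.n_assigned

    @property
    def assigned_fraction(self) -> float:
        return self.n_assigned / self.n_total

    @property
    def true_positives(self) -> int:
        return self.n_correct

    @property
    def false_positives(self) -> int:
        return self.n_assigned - self.n_correct

    @property
    def false_negatives(self) -> int:
        # every synthetic OTU is in-reference, so an abstention is a miss
        return self.n_total - self.n_assigned


def evaluate_against_truth(table: TaxonomyTable, truth: TruthSet
                           ) -> dict[str, RankEvaluation]:
    """Score any table (classifier or consensus) against the ground truth."""
    missing = set(table.assignments) ^ set(truth.lineages)
    if missing:
        raise TaxonomyError(
            f"OTU ids do not match the truth set (e.g. {sorted(missing)[:3]})")
    out = {}
    n_total = len(truth.lineages)
    for i, rank in enumerate(RANKS):
        n_assigned = n_correct = 0
        for otu_id, sa in table.assignments.items():
            name = sa.lineage.names[i]
            if name is None:
                continue
            n_assigned += 1
            if name == truth.lineages[otu_id].names[i]:
                n_correct += 1
        out[rank] = RankEvaluation(rank, n_assigned, n_correct, n_total)
    return out


def write_truth_tsv(truth: TruthSet) -> str:
    """Ground-truth lineages as a TSV (OTU id + 7 rank columns)."""
    lines = ["\t".join(["OTU_ID", *RANKS])]
    for otu_id, lineage in truth.lineages.items():
        lines.append("\t".join([otu_id, *(n or "" for n in lineage.names)]))
    return "\n".join(lines) + "\n"


def write_unite_fasta(records: Sequence[UniteRecord]) -> str:
    """Toy UNITE-style general FASTA with k__...s__ lineage headers."""
    prefixes = "kpcofgs"
    parts = []
    for rec in records:
        lineage = ";".join(
            f"{prefixes[i]}__{rec.lineage.names[i] or 'unidentified'}"
            for i in range(N_RANKS))
        name = rec.lineage.names[-1] or rec.seq_id
        parts.append(f">{name}|{rec.seq_id}|{rec.sh_code}|reps|{lineage}\n"
                     f"{rec.sequence}\n")
    return "".join(parts)
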
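"""Power, consistency and improvement statistics, and the output files.

Classification power at a rank is the proportion of OTUs that received a
name there.  The percent improvement of the consensus over a classifier
with ``N`` assigned OTUs is ``100 * (1 - N / N_consensus)``; it is reported
against both the best (max ``N``) and the worst (min ``N``) classifier, and
optionally with sources excluded from the comparison.  The agreement
profile partitions OTUs at each rank by how many classifiers assigned a
name and whether those names coincide, and yields the differential-
assignment rate: the fraction of OTUs that received conflicting names at
any rank.

A run writes four main files — ``consensus_taxonomy.txt`` (the final
higher-power table), ``combined_taxonomy.txt`` (all three inputs
side-by-side with the consensus and per-rank rule provenance),
``otu_taxonomy_CountClassified.txt`` (assigned/unidentified counts per rank
and source) and ``Classification_Summary.txt`` (unique-taxon counts per
rank) — plus the cutoff-filtered version of each classifier table in its
native dialect.  All outputs are tab-delimited UTF-8 with LF endings and
byte-deterministic given input and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .classifier_io import write_rdp, write_sintax, write_utax
from .consensus import Config
from .core import (
    CONSENSUS_LABEL,
    N_RANKS,
    RANKS,
    SOURCES,
    ConsensusRecord,
    TaxonomyError,
    TaxonomyTable,
)

#: Agreement categories in which at least two distinct names were given.
CONFLICT_CATEGORIES = frozenset(
    {"three_one_unique", "three_all_unique", "two_unique"})


@dataclass(frozen=True)
class RankSummary:
    """Assigned-OTU counts at one rank, per classifier and for consensus."""

    rank: str
    n_assigned: dict[str, int]
    n_consensus: int
    n_total: int

    def __post_init__(self):
        counts = [*self.n_assigned.values(), self.n_consensus]
        if any(c < 0 or c > self.n_total for c in counts):
            raise TaxonomyError(f"{self.rank}: counts outside [0, n_total]")


@dataclass(frozen=True)
class Improvement:
    """Percent improvement of the consensus at one rank.

    ``vs_best`` compares against the classifier with the most assignments
    (the max-N classifier), ``vs_worst`` against the one with the fewest;
    the raw assigned-count ratios are carried alongside.
    """

    vs_best: float
    vs_worst: float
    ratio_best: float
    ratio_worst: float


@dataclass
class AgreementProfile:
    """Per-rank partition of OTUs by classifier agreement."""

    n_total: int
    by_rank: dict[str, dict]
    #: fraction of OTUs with conflicting names at one or more ranks
    differential_rate: float
    differential_otus: list[str] = field(default_factory=list)


def power(table: TaxonomyTable, n_total: int) -> dict[str, float]:
    """Per-rank proportion of OTUs with an assigned name."""
    if n_total <= 0:
        raise TaxonomyError("n_total must be positive")
    return {RANKS[i]: table.n_assigned_at(i) / n_total
            for i in range(N_RANKS)}


def compute_rank_summaries(tables: Sequence[TaxonomyTable],
                           consensus: TaxonomyTable) -> list[RankSummary]:
    n_total = len(consensus)
    out = []
    for i, rank in enumerate(RANKS):
        out.append(RankSummary(
            rank,
            {t.source: t.n_assigned_at(i) for t in tables},
            consensus.n_assigned_at(i),
            n_total))
    return out


def percent_improvement(rs: RankSummary,
                        exclude: Optional[set[str]] = None
                        ) -> Optional[Improvement]:
    """Improvement of the consensus over the best and worst classifier.

    Excluded sources are removed before taking the extremes (used to
    recompute the statistic without a weak classifier).  Returns ``None``
    when the consensus assigned nothing at this rank, where the ratio is
    undefined.
    """
    exclude = exclude or set()
    counts = [n for src, n in rs.n_assigned.items() if src not in exclude]
    if not counts:
        raise TaxonomyError("all sources excluded")
    if rs.n_consensus == 0:
        return None
    best, worst = max(counts), min(counts)
    return Improvement(
        vs_best=100.0 * (1.0 - best / rs.n_consensus),
        vs_worst=100.0 * (1.0 - worst / rs.n_consensus),
        ratio_best=100.0 * best / rs.n_consensus,
        ratio_worst=100.0 * worst / rs.n_consensus)


def agreement_profile(tables: Sequence[TaxonomyTable]) -> AgreementProfile:
    """Classify every (OTU, rank) cell by agreement across the three tables.

    Categories: three classified and identical / two identical + one other /
    all unique; two classified and identical / unique; one classified
    (subdivided by source); none.  Each OTU lands in exactly one category
    per rank.  An OTU counts once toward the differential-assignment rate
    no matter how many ranks conflict.
    """
    if len(tables) != 3:
        raise TaxonomyError(f"exactly 3 tables required, got {len(tables)}")
    universes = [tuple(t.assignments) for t in tables]
    if len(set(universes)) != 1:
        raise TaxonomyError("tables not harmonized")
    otu_ids = universes[0]
    n_total = len(otu_ids)
    by_rank: dict[str, dict] = {}
    differential: list[str] = []
    for rank in RANKS:
        by_rank[rank] = {
            "three_identical": 0, "three_one_unique": 0,
            "three_all_unique": 0, "two_identical": 0, "two_unique": 0,
            "one_classified": {t.source: 0 for t in tables},
            "unidentified": 0,
        }
    for otu_id in otu_ids:
        conflicted = False
        for i, rank in enumerate(RANKS):
            cat = by_rank[rank]
            named = [(t.source, t.assignments[otu_id].lineage.names[i])
                     for t in tables
                     if t.assignments[otu_id].lineage.names[i] is not None]
            uniq = len({n for _, n in named})
            if len(named) == 3:
                key = {1: "three_identical", 2: "three_one_unique",
                       3: "three_all_unique"}[uniq]
                cat[key] += 1
            elif len(named) == 2:
                key = "two_identical" if uniq == 1 else "two_unique"
                cat[key] += 1
            elif len(named) == 1:
                cat["one_classified"][named[0][0]] += 1
                key = "one_classified"
            else:
                cat["unidentified"] += 1
                key = "unidentified"
            if key in CONFLICT_CATEGORIES:
                conflicted = True
        if conflicted:
            differential.append(otu_id)
    rate = len(differential) / n_total if n_total else 0.0
    return AgreementProfile(n_total, by_rank, rate, differential)


def unique_taxa_counts(table: TaxonomyTable) -> dict[str, int]:
    """Number of distinct taxon names present at each rank."""
    return {
        RANKS[i]: len({sa.lineage.names[i]
                       for sa in table.assignments.values()
                       if sa.lineage.names[i] is not None})
        for i in range(N_RANKS)}


# ---------------------------------------------------------------------------
# file writers

def _cell(name: Optional[str]) -> str:
    return name if name is not None else ""


def _write(path: Path, text: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(text)


def write_outputs(consensus: TaxonomyTable,
                  records: Sequence[ConsensusRecord],
                  tables: Sequence[TaxonomyTable],
                  profile: AgreementProfile,
                  summaries: Sequence[RankSummary],
                  config: Config) -> dict[str, Path]:
    """Write all output files into ``config.output_dir``."""
    if config.output_dir is None:
        raise TaxonomyError("config.output_dir is not set")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # consensus_taxonomy.txt — OTU id + the 7 consensus rank columns
    lines = ["\t".join(["OTU_ID", *RANKS])]
    for otu_id, sa in consensus.assignments.items():
        lines.append("\t".join([otu_id,
                                *(_cell(n) for n in sa.lineage.names)]))
    paths["consensus_taxonomy"] = out_dir / "consensus_taxonomy.txt"
    _write(paths["consensus_taxonomy"], "\n".join(lines) + "\n")

    # combined_taxonomy.txt — all three inputs side-by-side with scores,
    # the consensus, per-rank fired rules, and the chimeric-lineage flag
    header = ["OTU_ID"]
    for t in tables:
        header += [f"{t.source}_{r}" for r in RANKS]
    header += [f"{CONSENSUS_LABEL}_{r}" for r in RANKS]
    header += [f"Rule_{r}" for r in RANKS]
    header.append("Chimeric")
    lines = ["\t".join(header)]
    rec_by_id = {rec.otu_id: rec for rec in records}
    for otu_id, sa in consensus.assignments.items():
        row = [otu_id]
        for t in tables:
            src = t.assignments[otu_id]
            for i in range(N_RANKS):
                call = src.call_at(i)
                row.append(f"{call[0]}({call[1]:.4f})" if call else "")
        row += [_cell(n) for n in sa.lineage.names]
        rec = rec_by_id[otu_id]
        row += [d.rule for d in rec.decisions]
        row.append("1" if rec.chimeric else "0")
        lines.append("\t".join(row))
    paths["combined_taxonomy"] = out_dir / "combined_taxonomy.txt"
    _write(paths["combined_taxonomy"], "\n".join(lines) + "\n")

    # otu_taxonomy_CountClassified.txt — assigned/unidentified per rank
    sources = [t.source for t in tables] + [CONSENSUS_LABEL]
    header = ["Rank"]
    for src in sources:
        header += [f"{src}_classified", f"{src}_unidentified"]
    header.append("Total")
    lines = ["\t".join(header)]
    for rs in summaries:
        row = [rs.rank]
        for src in sources:
            n = rs.n_consensus if src == CONSENSUS_LABEL \
                else rs.n_assigned[src]
            row += [str(n), str(rs.n_total - n)]
        row.append(str(rs.n_total))
        lines.append("\t".join(row))
    paths["count_classified"] = out_dir / "otu_taxonomy_CountClassified.txt"
    _write(paths["count_classified"], "\n".join(lines) + "\n")

    # Classification_Summary.txt — unique-taxon counts per rank
    uniq = {t.source: unique_taxa_counts(t) for t in tables}
    uniq[CONSENSUS_LABEL] = unique_taxa_counts(consensus)
    lines = ["\t".join(["Rank", *sources])]
    for rank in RANKS:
        lines.append("\t".join(
            [rank, *(str(uniq[src][rank]) for src in sources)]))
    paths["classification_summary"] = out_dir / "Classification_Summary.txt"
    _write(paths["classification_summary"], "\n".join(lines) + "\n")

    # cutoff-filtered per-classifier tables, each in its native dialect
    writers = {"RDP": write_rdp, "UTAX": write_utax, "SINTAX": write_sintax}
    for t in tables:
        writer = writers.get(t.source)
        if writer is None:
            continue
        key = f"{t.source.lower()}_filtered"
        paths[key] = out_dir / f"{t.source}_filtered.txt"
        _write(paths[key], writer(t))

    return paths
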
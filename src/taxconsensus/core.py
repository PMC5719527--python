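"""Core domain types shared across the package.

The unit of analysis is the OTU (operational taxonomic unit): a cluster of
fungal ITS amplicon sequences that receives a taxonomic lineage over the
seven Linnaean ranks Kingdom through Species.  Three independent classifiers
(RDP naive Bayesian, UTAX, SINTAX) each produce one scored lineage per OTU;
this package merges them into a consensus.

An unassigned rank is represented by ``None`` everywhere in memory; literal
tokens such as ``unidentified``/``unclassified`` are normalized away at parse
time and never survive into the data model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

#: The seven ranks, in hierarchical order.
RANKS: tuple[str, ...] = (
    "Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species",
)
N_RANKS = len(RANKS)

#: Single-letter rank prefixes used by the ``;tax=`` header dialect
#: (``d`` for domain/kingdom, then p/c/o/f/g/s).
TAX_PREFIXES: tuple[str, ...] = ("d", "p", "c", "o", "f", "g", "s")

#: Two-underscore prefixes used in UNITE reference lineages (k__Fungi, ...).
UNITE_PREFIXES: tuple[str, ...] = ("k", "p", "c", "o", "f", "g", "s")

#: Lower-case rank labels as emitted by the RDP fixed-rank dialect.
RDP_RANK_LABELS: dict[str, int] = {r.lower(): i for i, r in enumerate(RANKS)}

#: Canonical source labels for the three classifiers, in table order.
SOURCES: tuple[str, ...] = ("RDP", "UTAX", "SINTAX")
CONSENSUS_LABEL = "CONSENSUS"

#: Name payloads treated as "no assignment" (case-insensitive).
UNASSIGNED_TOKENS = frozenset({"", "unidentified", "unclassified", "*"})


class TaxonomyError(ValueError):
    """Base error for malformed taxonomy inputs."""


class ParseError(TaxonomyError):
    """A dialect violation, carrying the offending source location."""

    def __init__(self, message: str, *, line: Optional[int] = None,
                 path: Optional[str] = None):
        self.line = line
        self.path = path
        where = ""
        if path is not None:
            where += f"{path}"
        if line is not None:
            where += f":{line}" if where else f"line {line}"
        super().__init__(f"{where}: {message}" if where else message)


def is_unassigned_token(name: Optional[str]) -> bool:
    """True when a raw name payload means "no assignment at this rank"."""
    return name is None or name.strip().lower() in UNASSIGNED_TOKENS


@dataclass(frozen=True)
class RankedLineage:
    """An ordered 7-slot lineage; ``None`` marks an unassigned rank."""

    names: tuple[Optional[str], ...]

    def __post_init__(self):
        if len(self.names) != N_RANKS:
            raise TaxonomyError(
                f"lineage must have exactly {N_RANKS} rank slots, "
                f"got {len(self.names)}")

    @classmethod
    def from_names(cls, names: Iterable[Optional[str]]) -> "RankedLineage":
        """Build a lineage, mapping placeholder tokens to unassigned and
        padding missing trailing ranks."""
        cleaned = [None if is_unassigned_token(n) else n for n in names]
        cleaned += [None] * (N_RANKS - len(cleaned))
        return cls(tuple(cleaned[:N_RANKS]))

    @classmethod
    def empty(cls) -> "RankedLineage":
        return cls((None,) * N_RANKS)

    def is_assigned(self, rank_index: int) -> bool:
        return self.names[rank_index] is not None

    @property
    def n_assigned(self) -> int:
        return sum(n is not None for n in self.names)

    def truncate(self, depth: int) -> "RankedLineage":
        """Unassign every rank at index >= depth."""
        return RankedLineage(self.names[:depth] + (None,) * (N_RANKS - depth))


@dataclass(frozen=True)
class ScoredAssignment:
    """One classifier's call for one OTU: per-rank (name, confidence).

    The invariant is positional: ``scores[i] is not None`` exactly when
    ``lineage.names[i] is not None``.
    """

    otu_id: str
    lineage: RankedLineage
    scores: tuple[Optional[float], ...]

    def __post_init__(self):
        if len(self.scores) != N_RANKS:
            raise TaxonomyError("scores must have exactly 7 slots")
        for i, (nm, sc) in enumerate(zip(self.lineage.names, self.scores)):
            if (nm is None) != (sc is None):
                raise TaxonomyError(
                    f"{self.otu_id}: score present iff rank assigned "
                    f"violated at {RANKS[i]}")
            if sc is not None and not (0.0 <= sc <= 1.0):
                raise TaxonomyError(
                    f"{self.otu_id}: confidence {sc} outside [0, 1] "
                    f"at {RANKS[i]}")

    @classmethod
    def unassigned(cls, otu_id: str) -> "ScoredAssignment":
        return cls(otu_id, RankedLineage.empty(), (None,) * N_RANKS)

    def call_at(self, rank_index: int) -> Optional[tuple[str, float]]:
        nm = self.lineage.names[rank_index]
        if nm is None:
            return None
        return nm, self.scores[rank_index]


@dataclass
class TaxonomyTable:
    """All of one source's assignments, keyed by OTU identifier."""

    source: str
    assignments: dict[str, ScoredAssignment] = field(default_factory=dict)
    #: dialect extras that must survive a round-trip (e.g. SINTAX strands)
    meta: dict = field(default_factory=dict)

    def add(self, sa: ScoredAssignment, *, line: Optional[int] = None,
            path: Optional[str] = None) -> None:
        if sa.otu_id in self.assignments:
            raise ParseError(f"duplicate OTU id {sa.otu_id!r}",
                             line=line, path=path)
        self.assignments[sa.otu_id] = sa

    @property
    def otu_ids(self) -> list[str]:
        return list(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def n_assigned_at(self, rank_index: int) -> int:
        return sum(sa.lineage.is_assigned(rank_index)
                   for sa in self.assignments.values())


#: Per-rank merge provenance labels (see consensus.consensus_rank).
RULE_ALL_AGREE = "all-agree"
RULE_MAJORITY = "majority"
RULE_SCORE_BREAK = "score-break"
RULE_SINGLE = "single"
RULE_NONE = "none"


@dataclass(frozen=True)
class RankDecision:
    """Outcome of merging the (up to) three calls at one rank."""

    name: Optional[str]
    rule: str
    sources: tuple[str, ...]
    score: Optional[float]

    def __post_init__(self):
        if (self.name is None) != (self.rule == RULE_NONE):
            raise TaxonomyError("rule 'none' iff rank unassigned")
        if (self.name is None) != (self.score is None):
            raise TaxonomyError("winning score present iff rank assigned")


@dataclass(frozen=True)
class ConsensusRecord:
    """Per-OTU merged lineage plus, per rank, the fired rule and sources."""

    otu_id: str
    lineage: RankedLineage
    decisions: tuple[RankDecision, ...]
    chimeric: bool = False

    def __post_init__(self):
        if len(self.decisions) != N_RANKS:
            raise TaxonomyError("one decision per rank required")


def strip_size_suffix(otu_id: str) -> str:
    """Drop a trailing ``;size=NN;?`` abundance annotation from an OTU id.

    Abundance data are deliberately unused: the consensus operates on
    representative sequences only.
    """
    base = otu_id.split(";", 1)[0]
    return base.strip()


def sorted_otu_ids(ids: Iterable[str]) -> list[str]:
    """The canonical OTU ordering used after harmonization (lexicographic)."""
    return sorted(set(ids))
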
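"""Confidence filtering and majority/score merging of three taxonomy tables.

The merge is rank-wise.  At each of the seven ranks, the (up to) three
surviving calls are combined by:

* all three agree -> that name;
* two agree (the third differs or is unidentified) -> the majority name;
* no majority (two or three distinct names) -> the name with the highest
  confidence score, exact ties broken by a configurable source order;
* a single call -> that name;
* no calls -> unassigned.

Because any single surviving call is adopted, the consensus can only gain
assignments relative to each individual classifier — this is the source of
the method's higher classification power.

Filtering precedes merging: a call that fails the confidence cutoff is
invisible to the rules, and the cutoff truncates lineages hierarchically
(once a rank fails, every deeper rank is discarded, since a child call under
a rejected parent is taxonomically meaningless).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .core import (
    CONSENSUS_LABEL,
    N_RANKS,
    RULE_ALL_AGREE,
    RULE_MAJORITY,
    RULE_NONE,
    RULE_SCORE_BREAK,
    RULE_SINGLE,
    SOURCES,
    ConsensusRecord,
    RankDecision,
    RankedLineage,
    ScoredAssignment,
    TaxonomyError,
    TaxonomyTable,
)

logger = logging.getLogger(__name__)

#: Default source priority for exact-score ties.
DEFAULT_TIE_ORDER: tuple[str, ...] = ("RDP", "SINTAX", "UTAX")


@dataclass
class Config:
    """Run configuration.

    cutoff
        Minimum per-rank confidence; calls below it are discarded before
        merging.  Default 0.8, the classifiers' recommended threshold.
    tie_order
        Source priority used only to break exact score ties.
    unidentified_as_unassigned
        Whether literal "unidentified" payloads in reference lineages are
        treated as unassigned ranks.
    output_dir
        Where the output files are written.
    """

    cutoff: float = 0.8
    tie_order: tuple[str, ...] = DEFAULT_TIE_ORDER
    unidentified_as_unassigned: bool = True
    output_dir: Optional[Path] = None

    def __post_init__(self):
        if not (0.0 <= self.cutoff <= 1.0):
            raise TaxonomyError(f"cutoff {self.cutoff} outside [0, 1]")
        self.tie_order = tuple(self.tie_order)
        if sorted(self.tie_order) != sorted(SOURCES):
            raise TaxonomyError(
                f"tie_order must be a permutation of {SOURCES}, "
                f"got {self.tie_order}")
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "Config":
        """Load a config from YAML or simple ``key=value`` lines."""
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = None
        if not isinstance(data, dict):
            data = {}
            for raw in text.splitlines():
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise TaxonomyError(
                        f"{path}: cannot parse config line {raw!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                data[key] = value
        return cls._from_mapping(data)

    @classmethod
    def _from_mapping(cls, data: dict) -> "Config":
        kwargs = {}
        if "cutoff" in data:
            kwargs["cutoff"] = float(data["cutoff"])
        if "tie_order" in data:
            to = data["tie_order"]
            if isinstance(to, str):
                to = [s.strip() for s in to.replace(",", " ").split()]
            kwargs["tie_order"] = tuple(to)
        if "unidentified_as_unassigned" in data:
            val = data["unidentified_as_unassigned"]
            if isinstance(val, str):
                val = val.strip().lower() in ("1", "true", "yes", "on")
            kwargs["unidentified_as_unassigned"] = bool(val)
        if "output_dir" in data:
            kwargs["output_dir"] = Path(data["output_dir"])
        return cls(**kwargs)


def apply_cutoff(table: TaxonomyTable, cutoff: float) -> TaxonomyTable:
    """Discard calls below the cutoff, truncating hierarchically.

    Scanning Kingdom to Species, the first rank whose confidence falls below
    the cutoff is unassigned together with every deeper rank.  Surviving
    scores are unchanged.
    """
    if not (0.0 <= cutoff <= 1.0):
        raise TaxonomyError(f"cutoff {cutoff} outside [0, 1]")
    out = TaxonomyTable(table.source)
    out.meta = dict(table.meta)
    for otu_id, sa in table.assignments.items():
        depth = N_RANKS
        for i in range(N_RANKS):
            sc = sa.scores[i]
            if sc is not None and sc < cutoff:
                depth = i
                break
        if depth == N_RANKS:
            out.assignments[otu_id] = sa
        else:
            out.assignments[otu_id] = ScoredAssignment(
                otu_id, sa.lineage.truncate(depth),
                sa.scores[:depth] + (None,) * (N_RANKS - depth))
    return out


def consensus_rank(calls: Sequence[Optional[tuple[str, float]]],
                   tie_order: Sequence[str] = DEFAULT_TIE_ORDER,
                   sources: Sequence[str] = SOURCES) -> RankDecision:
    """Merge the three candidate calls at one rank.

    ``calls[i]`` is source ``sources[i]``'s surviving (name, score) at this
    rank, or ``None`` if that source left the rank unidentified.  The rules
    are those described in the module docstring; the recorded winning score
    is the highest score among the contributing sources.
    """
    present = [(src, name, score)
               for src, call in zip(sources, calls)
               if call is not None
               for name, score in [call]]
    if not present:
        return RankDecision(None, RULE_NONE, (), None)
    if len(present) == 1:
        src, name, score = present[0]
        return RankDecision(name, RULE_SINGLE, (src,), score)

    by_name: dict[str, list[tuple[str, float]]] = {}
    for src, name, score in present:
        by_name.setdefault(name, []).append((src, score))
    if len(by_name) == 1:
        name = next(iter(by_name))
        contributors = by_name[name]
        rule = RULE_ALL_AGREE if len(present) == 3 else RULE_MAJORITY
        return RankDecision(name, rule,
                            tuple(s for s, _ in contributors),
                            max(sc for _, sc in contributors))
    majority = [n for n, c in by_name.items() if len(c) >= 2]
    if majority:
        name = majority[0]
        contributors = by_name[name]
        return RankDecision(name, RULE_MAJORITY,
                            tuple(s for s, _ in contributors),
                            max(sc for _, sc in contributors))

    # no majority: highest score wins, exact ties fall back to tie_order
    def priority(src: str) -> int:
        return (tie_order.index(src) if src in tie_order
                else len(tie_order) + sources.index(src))

    win_src, win_name, win_score = min(
        present, key=lambda t: (-t[2], priority(t[0])))
    return RankDecision(win_name, RULE_SCORE_BREAK, (win_src,), win_score)


def _supported_pair(tables: Sequence[TaxonomyTable], otu_id: str,
                    rank: int, parent: str, child: str) -> bool:
    for t in tables:
        nm = t.assignments[otu_id].lineage.names
        if nm[rank - 1] == parent and nm[rank] == child:
            return True
    return False


def build_consensus(tables: Sequence[TaxonomyTable], config: Config
                    ) -> tuple[TaxonomyTable, list[ConsensusRecord]]:
    """Merge three harmonized, cutoff-filtered tables rank by rank.

    Each rank is decided independently, so the consensus at one rank may be
    carried by different sources than the rank above; when an adjacent
    (parent, child) pair in the consensus lineage is supported by no single
    input table, the record is flagged chimeric and a warning logged.
    """
    if len(tables) != 3:
        raise TaxonomyError(f"exactly 3 tables required, got {len(tables)}")
    universes = [tuple(t.assignments) for t in tables]
    if len(set(universes)) != 1:
        raise TaxonomyError(
            "tables cover different OTU universes; run harmonize first")
    labels = [t.source for t in tables]
    out = TaxonomyTable(CONSENSUS_LABEL)
    records: list[ConsensusRecord] = []
    for otu_id in universes[0]:
        decisions = []
        for r in range(N_RANKS):
            calls = [t.assignments[otu_id].call_at(r) for t in tables]
            decisions.append(consensus_rank(calls, config.tie_order, labels))
        lineage = RankedLineage(tuple(d.name for d in decisions))
        chimeric = False
        for r in range(1, N_RANKS):
            parent, child = lineage.names[r - 1], lineage.names[r]
            if parent is not None and child is not None and \
                    not _supported_pair(tables, otu_id, r, parent, child):
                chimeric = True
                logger.warning(
                    "%s: consensus pair %s/%s at %d mixes parents from "
                    "different sources", otu_id, parent, child, r)
        records.append(ConsensusRecord(otu_id, lineage, tuple(decisions),
                                       chimeric))
        out.assignments[otu_id] = ScoredAssignment(
            otu_id, lineage, tuple(d.score for d in decisions))
    return out, records
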
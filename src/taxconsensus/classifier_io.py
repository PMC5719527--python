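"""Parsers and writers for the three classifiers' native output dialects.

Each classifier reports, per OTU, a partial lineage with a confidence in
[0, 1] at every assigned rank:

* RDP fixed-rank output — tab-separated; the OTU id, a (possibly empty)
  strand field, then repeating (name, rank-label, confidence) triplets.
  Non-canonical rank labels (``rootrank``, ``domain``, sub-ranks) are
  tolerated and dropped.
* UTAX — tab-separated; the OTU id (an ``;size=NN`` abundance suffix is
  stripped), then comma-separated scored calls ``d:Name(0.95),p:Name(0.88)``;
  a trailing cutoff-filtered lineage field may follow and is ignored, since
  filtering is done here at a configurable cutoff.
* SINTAX — four tab-separated fields: OTU id, scored calls as above, strand
  (``+``/``-``), and the classifier's own cutoff-filtered lineage (ignored).

``harmonize`` aligns parsed tables onto one sorted OTU universe so the
consensus stage can merge them rank by rank.
"""

from __future__ import annotations

import io
import re
from typing import Optional, TextIO, Union

from .core import (
    N_RANKS,
    RANKS,
    RDP_RANK_LABELS,
    TAX_PREFIXES,
    ParseError,
    RankedLineage,
    ScoredAssignment,
    TaxonomyTable,
    is_unassigned_token,
    sorted_otu_ids,
    strip_size_suffix,
)
from .refdb import sanitize_name

_CALL_RE = re.compile(r"^([A-Za-z]):(.*)\(([^()]*)\)$")


def _as_lines(stream: Union[str, TextIO]) -> list[str]:
    if isinstance(stream, str):
        return stream.splitlines()
    return stream.read().splitlines()


def _parse_score(text: str, *, line: int, path: Optional[str]) -> float:
    try:
        score = float(text)
    except ValueError:
        raise ParseError(f"unparseable confidence {text!r}",
                         line=line, path=path) from None
    if not (0.0 <= score <= 1.0):
        raise ParseError(f"confidence {score} outside [0, 1]",
                         line=line, path=path)
    return score


def _clean_name(raw: str) -> Optional[str]:
    """Sanitize a reported taxon name; placeholder tokens mean unassigned."""
    if is_unassigned_token(raw):
        return None
    name = sanitize_name(raw)
    return name or None


def _make_assignment(otu_id: str, slots: list[Optional[tuple[str, float]]]
                     ) -> ScoredAssignment:
    names = tuple(s[0] if s else None for s in slots)
    scores = tuple(s[1] if s else None for s in slots)
    return ScoredAssignment(otu_id, RankedLineage(names), scores)


# ---------------------------------------------------------------------------
# RDP fixed-rank dialect

def parse_rdp(stream: Union[str, TextIO], *,
              path: Optional[str] = None) -> TaxonomyTable:
    table = TaxonomyTable("RDP")
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        otu_id = strip_size_suffix(fields[0])
        if not otu_id:
            raise ParseError("missing OTU id", line=lineno, path=path)
        rest = fields[1:]
        while rest and rest[0].strip() in ("", "-"):
            rest.pop(0)
        while rest and not rest[-1].strip():
            rest.pop()
        if len(rest) % 3 != 0:
            raise ParseError(
                f"expected (name, rank, confidence) triplets, got "
                f"{len(rest)} trailing fields", line=lineno, path=path)
        slots: list[Optional[tuple[str, float]]] = [None] * N_RANKS
        for i in range(0, len(rest), 3):
            name_raw, label, conf = rest[i], rest[i + 1], rest[i + 2]
            idx = RDP_RANK_LABELS.get(label.strip().lower())
            if idx is None:
                continue  # rootrank/domain/sub-rank labels are dropped
            score = _parse_score(conf, line=lineno, path=path)
            name = _clean_name(name_raw)
            slots[idx] = (name, score) if name is not None else None
        table.add(_make_assignment(otu_id, slots), line=lineno, path=path)
    return table


def write_rdp(table: TaxonomyTable) -> str:
    lines = []
    for otu_id, sa in table.assignments.items():
        flat: list[str] = []
        for i in range(N_RANKS):
            call = sa.call_at(i)
            if call is not None:
                flat += [call[0], RANKS[i].lower(), f"{call[1]:.4f}"]
        lines.append(otu_id + "\t\t" + "\t".join(flat))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# shared scored-call grammar ("d:Name(0.95),p:Name(0.88),...")

def _parse_scored_calls(text: str, *, line: int, path: Optional[str]
                        ) -> list[Optional[tuple[str, float]]]:
    slots: list[Optional[tuple[str, float]]] = [None] * N_RANKS
    text = text.strip()
    if text in ("", "*"):
        return slots
    for part in text.split(","):
        part = part.strip()
        m = _CALL_RE.match(part)
        if m is None:
            raise ParseError(f"malformed scored call {part!r}",
                             line=line, path=path)
        prefix, name_raw, conf = m.groups()
        prefix = prefix.lower()
        if prefix not in TAX_PREFIXES:
            raise ParseError(f"unknown rank prefix {prefix!r}",
                             line=line, path=path)
        idx = TAX_PREFIXES.index(prefix)
        score = _parse_score(conf, line=line, path=path)
        name = _clean_name(name_raw)
        slots[idx] = (name, score) if name is not None else None
    return slots


def _format_scored_calls(sa: ScoredAssignment) -> str:
    parts = [f"{TAX_PREFIXES[i]}:{call[0]}({call[1]:.4f})"
             for i in range(N_RANKS)
             if (call := sa.call_at(i)) is not None]
    return ",".join(parts)


def _format_plain_calls(sa: ScoredAssignment) -> str:
    return ",".join(f"{TAX_PREFIXES[i]}:{sa.lineage.names[i]}"
                    for i in range(N_RANKS)
                    if sa.lineage.names[i] is not None)


# ---------------------------------------------------------------------------
# UTAX dialect

def parse_utax(stream: Union[str, TextIO], *,
               path: Optional[str] = None) -> TaxonomyTable:
    table = TaxonomyTable("UTAX")
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 2:
            raise ParseError("expected at least (otu id, scored calls)",
                             line=lineno, path=path)
        otu_id = strip_size_suffix(fields[0])
        slots = _parse_scored_calls(fields[1], line=lineno, path=path)
        # any further fields carry UTAX's own cutoff-filtered lineage; ignored
        table.add(_make_assignment(otu_id, slots), line=lineno, path=path)
    return table


def write_utax(table: TaxonomyTable) -> str:
    lines = []
    for otu_id, sa in table.assignments.items():
        calls = _format_scored_calls(sa)
        lines.append(f"{otu_id}\t{calls or '*'}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SINTAX dialect

def parse_sintax(stream: Union[str, TextIO], *,
                 path: Optional[str] = None) -> TaxonomyTable:
    table = TaxonomyTable("SINTAX")
    for lineno, raw in enumerate(_as_lines(stream), start=1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 4:
            raise ParseError(
                f"expected 4 tab-separated fields, got {len(fields)}",
                line=lineno, path=path)
        otu_id = strip_size_suffix(fields[0])
        slots = _parse_scored_calls(fields[1], line=lineno, path=path)
        strand = fields[2].strip()
        sa = _make_assignment(otu_id, slots)
        table.add(sa, line=lineno, path=path)
        table.meta.setdefault("strand", {})[otu_id] = strand or "+"
    return table


def write_sintax(table: TaxonomyTable) -> str:
    strands = table.meta.get("strand", {})
    lines = []
    for otu_id, sa in table.assignments.items():
        calls = _format_scored_calls(sa)
        plain = _format_plain_calls(sa)
        strand = strands.get(otu_id, "+")
        lines.append(f"{otu_id}\t{calls}\t{strand}\t{plain}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------

def harmonize(tables: list[TaxonomyTable]) -> list[TaxonomyTable]:
    """Align tables onto the union of their OTU ids.

    OTUs missing from a table are inserted fully unassigned, and every table
    is re-keyed to one canonical sorted OTU order, so downstream merging can
    iterate the tables in lockstep.  Idempotent; source labels and metadata
    are preserved.
    """
    universe = sorted_otu_ids(
        oid for t in tables for oid in t.assignments)
    out = []
    for t in tables:
        aligned = TaxonomyTable(t.source)
        aligned.meta = dict(t.meta)
        for oid in universe:
            aligned.assignments[oid] = t.assignments.get(
                oid, ScoredAssignment.unassigned(oid))
        out.append(aligned)
    return out
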
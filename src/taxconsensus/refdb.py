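"""UNITE reference-database formatting.

Turns a UNITE-style general FASTA release (headers carrying pipe-delimited
fields with a Species Hypothesis code and a ``k__...;s__...`` lineage) into
the training/reference files the three classifiers expect:

* an RDP-style taxonomy tree plus a lineage-annotated FASTA, and
* a ``;tax=`` annotated FASTA for the k-mer classifiers (UTAX/SINTAX).

Species names shared by several Species Hypotheses are made unique per SH,
and taxon names are sanitized to a safe character set, since downstream
training formats choke on punctuation.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional, TextIO, Union

from Bio import SeqIO

from .core import (
    N_RANKS,
    RANKS,
    TAX_PREFIXES,
    UNITE_PREFIXES,
    ParseError,
    RankedLineage,
    TaxonomyError,
    is_unassigned_token,
)

_SH_RE = re.compile(r"^SH\d+\.\d+FU$")
_ACCESSION_RE = re.compile(r"^[A-Z]{1,6}_?\d+(\.\d+)?$")
_DNA_RE = re.compile(r"^[ACGTRYSWKMBDHVNU]+$", re.IGNORECASE)
_SANITIZE_RE = re.compile(r"[^A-Za-z0-9_-]+")
_ALNUM_RE = re.compile(r"[A-Za-z0-9]")


@dataclass(frozen=True)
class UniteRecord:
    """One reference entry: accession, optional SH code, lineage, sequence."""

    seq_id: str
    sh_code: Optional[str]
    lineage: RankedLineage
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise TaxonomyError(f"{self.seq_id}: empty sequence")
        if not _DNA_RE.match(self.sequence):
            raise TaxonomyError(
                f"{self.seq_id}: sequence contains non-IUPAC characters")


@dataclass(frozen=True)
class ParseIssue:
    """A skipped reference record, with its header line number."""

    line: int
    message: str


@dataclass
class UniteParseResult:
    records: list[UniteRecord]
    issues: list[ParseIssue]


def sanitize_name(raw: str) -> str:
    """Normalize a taxon name to ``[A-Za-z0-9_-]``.

    Disallowed characters become underscores, underscore runs collapse, and
    leading/trailing underscores are stripped.  A name with no alphanumeric
    content sanitizes to the empty string.  Idempotent by construction.
    """
    if not _ALNUM_RE.search(raw):
        return ""
    out = _SANITIZE_RE.sub("_", raw)
    out = re.sub(r"_+", "_", out).strip("_")
    return out


def _parse_lineage_block(block: str, *, unidentified_as_unassigned: bool
                         ) -> RankedLineage:
    """Map a ``k__X;p__Y;...`` block onto the 7 rank slots."""
    slots: list[Optional[str]] = [None] * N_RANKS
    for element in block.split(";"):
        element = element.strip()
        if not element:
            continue
        if len(element) < 3 or element[1:3] != "__":
            raise TaxonomyError(f"lineage element {element!r} lacks a "
                                "rank prefix")
        prefix, payload = element[0].lower(), element[3:]
        if prefix not in UNITE_PREFIXES:
            continue  # tolerate non-canonical sub-ranks
        idx = UNITE_PREFIXES.index(prefix)
        if unidentified_as_unassigned and is_unassigned_token(payload):
            slots[idx] = None
        elif payload:
            slots[idx] = payload
    return RankedLineage(tuple(slots))


def _pick_accession(fields: list[str]) -> str:
    for f in fields:
        if _ACCESSION_RE.match(f) and not _SH_RE.match(f):
            return f
    # fall back: UNITE releases conventionally put the accession second
    return fields[1] if len(fields) > 1 else fields[0]


def parse_unite_fasta(stream: Union[str, TextIO], *,
                      unidentified_as_unassigned: bool = True
                      ) -> UniteParseResult:
    """Parse a UNITE-style general FASTA release.

    Headers are pipe-delimited; the lineage block is located as the first
    field containing ``k__`` (header layouts vary across UNITE releases, so
    other fields are treated positionally tolerant).  Records whose header
    carries no lineage block are skipped and reported as issues with the
    header's line number.  An empty stream is an error.

    With ``unidentified_as_unassigned`` (the default), lineage payloads that
    literally read "unidentified" are recorded as unassigned rather than as
    taxon names, so they cannot pollute downstream consensus counts.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    header_lines = [i + 1 for i, ln in enumerate(text.splitlines())
                    if ln.startswith(">")]
    records: list[UniteRecord] = []
    issues: list[ParseIssue] = []
    for n, rec in enumerate(SeqIO.parse(io.StringIO(text), "fasta")):
        line = header_lines[n] if n < len(header_lines) else -1
        header = rec.description
        fields = [f for f in header.split("|")]
        lineage_field = next((f for f in fields if "k__" in f), None)
        if lineage_field is None:
            issues.append(ParseIssue(line, "header has no lineage block"))
            continue
        try:
            lineage = _parse_lineage_block(
                lineage_field,
                unidentified_as_unassigned=unidentified_as_unassigned)
            rest = [f for f in fields if f is not lineage_field]
            sh = next((f for f in rest if _SH_RE.match(f)), None)
            accession = _pick_accession([f for f in rest if f != sh])
            records.append(UniteRecord(accession, sh, lineage, str(rec.seq)))
        except TaxonomyError as exc:
            issues.append(ParseIssue(line, str(exc)))
    if not records and not issues:
        raise ParseError("empty FASTA stream: no records found")
    return UniteParseResult(records, issues)


def sanitize_records(records: Iterable[UniteRecord]) -> list[UniteRecord]:
    """Apply sanitize_name to every assigned rank of every record."""
    out = []
    for rec in records:
        names = tuple(None if n is None else (sanitize_name(n) or None)
                      for n in rec.lineage.names)
        out.append(replace(rec, lineage=RankedLineage(names)))
    return out


def uniquify_species(records: list[UniteRecord]
                     ) -> tuple[list[UniteRecord], dict[str, list[str]]]:
    """Give each Species Hypothesis a unique species-rank name.

    A species name claimed by more than one distinct SH code gets the
    (sanitized) SH code suffixed, so classifier training sees one label per
    SH.  Other ranks are untouched; record count and order are preserved.
    Returns the renamed records and an old-name -> new-names mapping.
    """
    sp_idx = N_RANKS - 1
    sh_by_species: dict[str, set[str]] = {}
    for rec in records:
        sp = rec.lineage.names[sp_idx]
        if sp is not None and rec.sh_code is not None:
            sh_by_species.setdefault(sp, set()).add(rec.sh_code)
    mapping: dict[str, list[str]] = {}
    out: list[UniteRecord] = []
    for rec in records:
        sp = rec.lineage.names[sp_idx]
        if (sp is not None and rec.sh_code is not None
                and len(sh_by_species.get(sp, ())) > 1):
            new_sp = f"{sp}_{sanitize_name(rec.sh_code)}"
            names = rec.lineage.names[:sp_idx] + (new_sp,)
            out.append(replace(rec, lineage=RankedLineage(names)))
            mapping.setdefault(sp, [])
            if new_sp not in mapping[sp]:
                mapping[sp].append(new_sp)
        else:
            out.append(rec)
    return out, mapping


# ---------------------------------------------------------------------------
# RDP training files

def _bridged_names(lineage: RankedLineage) -> list[Optional[str]]:
    """Fill internal gaps (named rank below an unassigned rank) with
    deterministic placeholder nodes ``<parent>_unclassified_<rank>`` so the
    taxonomy stays a connected tree; trailing unassigned ranks stay open."""
    names = list(lineage.names)
    last = max((i for i, n in enumerate(names) if n is not None), default=-1)
    parent = "Root"
    for i in range(last + 1):
        if names[i] is None:
            names[i] = f"{parent}_unclassified_{RANKS[i].lower()}"
        parent = names[i]
    return names


def write_rdp_training(records: list[UniteRecord], *,
                       delimiter: str = "*") -> tuple[str, str]:
    """Emit the RDP trainer's (taxonomy tree, lineage-annotated FASTA) pair.

    The tree file has one line per unique taxon path node with fields
    (id, name, parent id, depth, rank label); ids are dense and assigned in
    first-seen order during an input-order walk, so output is deterministic.
    The FASTA headers carry the accession then the full semicolon-joined
    lineage from Root.
    """
    d = delimiter
    lines = [d.join(["0", "Root", "-1", "0", "rootrank"])]
    node_ids: dict[tuple[str, ...], int] = {(): 0}
    fasta_parts: list[str] = []
    for rec in records:
        names = _bridged_names(rec.lineage)
        path: list[str] = []
        for depth, name in enumerate(names, start=1):
            if name is None:
                break
            parent_id = node_ids[tuple(path)]
            path.append(name)
            key = tuple(path)
            if key not in node_ids:
                nid = len(node_ids)
                node_ids[key] = nid
                lines.append(d.join([str(nid), name, str(parent_id),
                                     str(depth), RANKS[depth - 1].lower()]))
        fasta_parts.append(
            f">{rec.seq_id}\t{';'.join(['Root'] + path)}\n{rec.sequence}\n")
    return "\n".join(lines) + "\n", "".join(fasta_parts)


# ---------------------------------------------------------------------------
# ;tax= annotated FASTA (UTAX / SINTAX reference dialect)

def format_tax_field(lineage: RankedLineage) -> str:
    """``tax=d:K,p:P,...;`` with unassigned ranks omitted."""
    parts = [f"{TAX_PREFIXES[i]}:{n}"
             for i, n in enumerate(lineage.names) if n is not None]
    return "tax=" + ",".join(parts) + ";"


def parse_tax_field(field: str, *, line: Optional[int] = None,
                    path: Optional[str] = None) -> RankedLineage:
    """Inverse of :func:`format_tax_field` (scores not carried here)."""
    body = field.strip()
    if body.startswith("tax="):
        body = body[4:]
    body = body.rstrip(";")
    slots: list[Optional[str]] = [None] * N_RANKS
    if body:
        for part in body.split(","):
            if ":" not in part:
                raise ParseError(f"malformed tax element {part!r}",
                                 line=line, path=path)
            prefix, name = part.split(":", 1)
            prefix = prefix.strip().lower()
            if prefix not in TAX_PREFIXES:
                raise ParseError(f"unknown rank prefix {prefix!r}",
                                 line=line, path=path)
            if not is_unassigned_token(name):
                slots[TAX_PREFIXES.index(prefix)] = name.strip()
    return RankedLineage(tuple(slots))


def write_kmer_classifier_fasta(records: list[UniteRecord],
                                dialect: str = "sintax") -> str:
    """Emit the ``>seqid;tax=...;`` FASTA used to build UTAX/SINTAX
    references.  Both dialects share the header grammar; ``dialect`` is kept
    for symmetry with the classifier names."""
    if dialect not in ("utax", "sintax"):
        raise ValueError(f"unknown dialect {dialect!r}")
    parts = []
    for rec in records:
        parts.append(f">{rec.seq_id};{format_tax_field(rec.lineage)}\n"
                     f"{rec.sequence}\n")
    return "".join(parts)


def parse_kmer_classifier_fasta(stream: Union[str, TextIO]
                                ) -> list[UniteRecord]:
    """Parse a ``;tax=`` annotated FASTA back into records (round-trip of
    :func:`write_kmer_classifier_fasta`; SH codes are not represented in
    this dialect)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for rec in SeqIO.parse(stream, "fasta"):
        header = rec.description
        if ";tax=" not in header:
            raise ParseError(f"header {header!r} lacks a tax= annotation")
        seq_id, tax = header.split(";", 1)
        out.append(UniteRecord(seq_id, None, parse_tax_field(tax),
                               str(rec.seq)))
    return out
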
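"""End-to-end run: parse, harmonize, filter, merge, summarize, write."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from . import __version__
from .classifier_io import harmonize, parse_rdp, parse_sintax, parse_utax
from .consensus import Config, apply_cutoff, build_consensus
from .core import RANKS, ConsensusRecord, TaxonomyTable
from .summaries import (
    AgreementProfile,
    RankSummary,
    agreement_profile,
    compute_rank_summaries,
    write_outputs,
)


@dataclass
class PipelineResult:
    consensus: TaxonomyTable
    records: list[ConsensusRecord]
    filtered: list[TaxonomyTable]
    summaries: list[RankSummary]
    profile: AgreementProfile
    output_paths: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(rdp: Union[str, Path], utax: Union[str, Path],
                 sintax: Union[str, Path], config: Config,
                 write_files: bool = True) -> PipelineResult:
    """Run the full consensus workflow on three classifier output files.

    Stages, in order: parse each native dialect; harmonize onto the union
    OTU universe; filter each table at the confidence cutoff; merge rank by
    rank into the consensus; compute power/agreement summaries; write the
    output files and a machine-readable run manifest.
    """
    paths = {"RDP": Path(rdp), "UTAX": Path(utax), "SINTAX": Path(sintax)}
    parsers = {"RDP": parse_rdp, "UTAX": parse_utax, "SINTAX": parse_sintax}
    tables = []
    for src, p in paths.items():
        with open(p, encoding="utf-8") as fh:
            tables.append(parsers[src](fh, path=str(p)))
    tables = harmonize(tables)
    filtered = [apply_cutoff(t, config.cutoff) for t in tables]
    consensus, records = build_consensus(filtered, config)
    summaries = compute_rank_summaries(filtered, consensus)
    profile = agreement_profile(filtered)

    manifest = {
        "tool": "taxconsensus",
        "version": __version__,
        "config": {
            "cutoff": config.cutoff,
            "tie_order": list(config.tie_order),
            "unidentified_as_unassigned": config.unidentified_as_unassigned,
        },
        "inputs": {src: {"path": str(p), "sha256": _sha256(p)}
                   for src, p in paths.items()},
        "counts": {
            "n_otus": len(consensus),
            "assigned_per_rank": {
                t.source: {RANKS[i]: t.n_assigned_at(i)
                           for i in range(len(RANKS))}
                for t in [*filtered, consensus]},
            "chimeric_records": sum(r.chimeric for r in records),
            "differential_otus": len(profile.differential_otus),
        },
        "warnings": [f"{r.otu_id}: chimeric consensus lineage"
                     for r in records if r.chimeric],
    }

    result = PipelineResult(consensus, records, filtered, summaries,
                            profile, manifest=manifest)
    if write_files:
        result.output_paths = write_outputs(
            consensus, records, filtered, profile, summaries, config)
        manifest_path = Path(config.output_dir) / "run_manifest.json"
        with open(manifest_path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        result.output_paths["manifest"] = manifest_path
    return result
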
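"""Tabular and FASTA/GFF3 writers for scan and target results.

Coordinates are converted to 1-based inclusive on output; internal data
stay 0-based half-open.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

from .degradome import TargetCall
from .phas_core import PhasLocus, PhasiRNA
from .sequence_io import SENSE


def write_loci_tsv(loci: Sequence[PhasLocus], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["name", "transcript", "start", "end", "p", "register", "k", "n",
             "max_phase_score", "raw_p", "fdr"]
        )
        for lo in loci:
            w.writerow(
                [lo.name, lo.transcript_id, lo.start + 1, lo.end, lo.p,
                 lo.best_register, lo.k, lo.n, f"{lo.max_phase_score:.4f}",
                 f"{lo.min_p_value:.4g}", f"{lo.fdr:.4g}"]
            )


def write_phasirna_fasta(phasirnas: Sequence[PhasiRNA], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ph in phasirnas:
            fh.write(f">{ph.name} count={ph.abundance}\n{ph.seq}\n")


def write_gff3(
    loci: Sequence[PhasLocus], phasirnas: Sequence[PhasiRNA], path: str | Path
) -> None:
    by_locus: dict[str, list[PhasiRNA]] = {}
    for ph in phasirnas:
        by_locus.setdefault(ph.locus_name, []).append(ph)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for lo in loci:
            attrs = (
                f"ID={lo.name};phase_score={lo.max_phase_score:.3f};"
                f"fdr={lo.fdr:.3g};register={lo.best_register}"
            )
            fh.write(
                f"{lo.transcript_id}\tphasfinder\tsiRNA_locus\t{lo.start + 1}\t"
                f"{lo.end}\t{lo.max_phase_score:.3f}\t+\t.\t{attrs}\n"
            )
            for ph in by_locus.get(lo.name, []):
                strand = "+" if ph.strand == SENSE else "-"
                fh.write(
                    f"{lo.transcript_id}\tphasfinder\tsiRNA\t{ph.position + 1}\t"
                    f"{ph.position + ph.length}\t{ph.abundance}\t{strand}\t.\t"
                    f"ID={ph.name};Parent={lo.name}\n"
                )


def write_targets_tsv(
    calls: Sequence[TargetCall], path: str | Path, section: str = "target"
) -> None:
    with open(path, "w", newline="") as fh:
        _write_target_rows(fh, calls, section, header=True)


def _write_target_rows(fh, calls: Sequence[TargetCall], section: str,
                       header: bool) -> None:
    w = csv.writer(fh, delimiter="\t", lineterminator="\n")
    if header:
        w.writerow(
            ["section", "small_rna", "transcript", "site_start", "site_end",
             "target_strand", "mismatches", "valid_reads",
             "cleavage_position", "cis_trans", "trigger_consistent"]
        )
    for c in calls:
        s = c.site
        w.writerow(
            [section, s.small_rna_id, s.transcript_id, s.site_start + 1,
             s.site_end, s.strand_of_target, s.mismatches, c.valid_reads,
             c.cleavage_position + 1, "cis" if c.is_cis else "trans",
             "yes" if c.trigger_consistent else "no"]
        )


def write_combined_targets_tsv(
    trigger_calls: Sequence[TargetCall],
    target_calls: Sequence[TargetCall],
    path: str | Path,
) -> None:
    """Trigger (OR-rule) and phasiRNA-target (AND-rule) sections in one TSV."""
    with open(path, "w", newline="") as fh:
        _write_target_rows(fh, trigger_calls, "trigger", header=True)
        _write_target_rows(fh, target_calls, "phasirna_target", header=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    version: str,
    config: dict,
    inputs: Iterable[str | Path],
    seed: int | None,
    counts: dict[str, int],
) -> None:
    manifest = {
        "tool": "phasfinder",
        "version": version,
        "config": config,
        "inputs": {str(p): file_sha256(p) for p in inputs},
        "seed": seed,
        "counts": counts,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
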
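"""Synthetic PHAS data: transcriptomes, phased read stacks, degradome peaks.

The generator implants a trigger-miRNA complementary site on a transcript,
places the inferred cleavage position between small-RNA positions 10 and
11, and lays phasiRNA duplexes head-to-tail downstream of the cut: sense
reads at the register positions, antisense partners two nucleotides to the
left per the 2-nt 3'-overhang duplex geometry.  Duplex abundances decay
geometrically along the locus.  Background reads of mixed lengths fall
uniformly over every transcript, and a configured fraction of noise inside
locus regions lands off-register to exercise the U_i term of the phase
score.  The degradome carries a peak of configured height at the cleavage
position over Poisson background.  Everything is emitted in the exact
formats the ingest layer consumes, alongside a ground-truth table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phas_core import PhasLocus
from .sequence_io import (
    ANTISENSE,
    SENSE,
    MappedRead,
    Transcript,
    UniqueRead,
    revcomp,
    write_collapsed_fasta,
    write_fasta,
)


@dataclass
class SimConfig:
    """Knobs of the simulator; the defaults define the standard test regime."""

    seed: int = 1
    n_transcripts: int = 5
    transcript_length: tuple[int, int] = (800, 2000)  # uniform [min, max] nt
    gc_fraction: float = 0.42
    n_phas_loci: int = 1
    p: int = 21
    window_cycles: int = 10  # the scan window must fit downstream of the cut
    duplexes_per_locus: int = 6
    top_abundance: int = 20
    abundance_decay: float = 0.7
    antisense_fraction: float = 0.5
    noise_reads_per_transcript: int = 2
    offregister_noise_fraction: float = 0.5
    noise_lengths: tuple[int, ...] = (20, 21, 22, 24)
    trigger_length: int = 22
    trigger_mismatches: int = 2
    degradome_peak: int = 50
    degradome_background: float = 5.0  # Poisson mean per position
    degradome_tag_length: int = 20

    def __post_init__(self) -> None:
        if self.n_phas_loci > self.n_transcripts:
            raise ValueError("more loci requested than transcripts")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


@dataclass
class TruthLocus:
    """Ground truth for one implanted locus."""

    transcript_id: str
    start: int  # cleavage position == first sense phasiRNA 5' end
    end: int  # start + duplexes * p
    register: int
    p: int
    phasirna_seqs: list[str]
    phasirna_counts: list[int]
    trigger_id: str
    site_start: int
    site_end: int
    cleavage_position: int


@dataclass
class SimResult:
    config: SimConfig
    transcripts: list[Transcript]
    srna_reads: list[UniqueRead]
    mirnas: dict[str, str]
    degradome_reads: list[UniqueRead]
    truth: list[TruthLocus]


class GeometryError(ValueError):
    """An implanted locus cannot fit on its transcript."""


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _mutate(rng: np.random.Generator, seq: str, n_sites: int,
            protected: set[int]) -> str:
    """Substitute n_sites positions (0-based), never inside `protected`."""
    candidates = [i for i in range(len(seq)) if i not in protected]
    picks = rng.choice(len(candidates), size=n_sites, replace=False)
    out = list(seq)
    for i in picks:
        pos = candidates[int(i)]
        out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out)


def simulate(cfg: SimConfig) -> SimResult:
    """Generate one synthetic dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.transcript_length
    p, L_mi = cfg.p, cfg.trigger_length
    locus_span = cfg.duplexes_per_locus * p
    scan_span = cfg.window_cycles * p

    transcripts: list[Transcript] = []
    seqs: list[list[str]] = []
    for i in range(cfg.n_transcripts):
        tlen = int(rng.integers(lo, hi + 1))
        seqs.append(list(_random_seq(rng, tlen, cfg.gc_fraction)))
        transcripts.append(Transcript(id=f"SYN{i + 1:04d}", seq=""))

    # place loci on the first n_phas_loci transcripts
    srna_counts: dict[str, int] = {}
    mirnas: dict[str, str] = {}
    truth: list[TruthLocus] = []
    deg_peaks: list[tuple[int, int, int]] = []  # (transcript index, pos, height)

    for li in range(cfg.n_phas_loci):
        ti = li
        tlen = len(seqs[ti])
        # trigger site [ts, ts+L_mi); cleavage c = ts + L_mi - 10;
        # the full scan window and the antisense overhang must fit
        min_ts = max(0, 10 - L_mi + 2)  # c - 2 >= 0
        max_ts = tlen - max(locus_span, scan_span) - L_mi + 10
        if max_ts < min_ts:
            raise GeometryError(
                f"locus (span {max(locus_span, scan_span)} nt + trigger) does "
                f"not fit transcript of {tlen} nt"
            )
        ts = int(rng.integers(min_ts, max_ts + 1))
        c = ts + L_mi - 10

        mseq = _random_seq(rng, L_mi, 0.5)
        mirnas[f"synmiR{li + 1}"] = mseq
        # implant the complementary site with the configured mismatches,
        # keeping positions 9-11 (the slicing window) perfectly paired
        site = revcomp(mseq)
        protected = {L_mi - j for j in (9, 10, 11)}  # site indices pairing 9-11
        if cfg.trigger_mismatches:
            site = _mutate(rng, site, cfg.trigger_mismatches, protected)
        seqs[ti][ts : ts + L_mi] = list(site)

        phasirna_seqs: list[str] = []
        phasirna_counts: list[int] = []
        tseq = "".join(seqs[ti])
        for j in range(cfg.duplexes_per_locus):
            s = c + j * p
            count = max(1, round(cfg.top_abundance * cfg.abundance_decay**j))
            sense_seq = tseq[s : s + p]
            srna_counts[sense_seq] = srna_counts.get(sense_seq, 0) + count
            phasirna_seqs.append(sense_seq)
            phasirna_counts.append(count)
            if rng.random() < cfg.antisense_fraction:
                anti_seq = revcomp(tseq[s - 2 : s - 2 + p])
                srna_counts[anti_seq] = srna_counts.get(anti_seq, 0) + count
                phasirna_seqs.append(anti_seq)
                phasirna_counts.append(count)
        truth.append(
            TruthLocus(
                transcript_id=transcripts[ti].id,
                start=c,
                end=c + locus_span,
                register=c % p,
                p=p,
                phasirna_seqs=phasirna_seqs,
                phasirna_counts=phasirna_counts,
                trigger_id=f"synmiR{li + 1}",
                site_start=ts,
                site_end=ts + L_mi,
                cleavage_position=c,
            )
        )
        deg_peaks.append((ti, c, cfg.degradome_peak))

    transcripts = [
        Transcript(id=t.id, seq="".join(s)) for t, s in zip(transcripts, seqs)
    ]

    # background small-RNA noise
    for ti, t in enumerate(transcripts):
        tl = truth[ti] if ti < len(truth) else None
        n_off = (
            round(cfg.offregister_noise_fraction * cfg.noise_reads_per_transcript)
            if tl is not None
            else 0
        )
        for j in range(cfg.noise_reads_per_transcript):
            if tl is not None and j < n_off:
                # off-register length-p read inside the locus
                offset = int(rng.integers(1, p))
                cycle = int(rng.integers(0, cfg.duplexes_per_locus))
                pos = tl.start + cycle * p + offset
                rlen = p
            else:
                rlen = int(rng.choice(cfg.noise_lengths))
                pos = int(rng.integers(0, t.length - rlen + 1))
            seq = t.seq[pos : pos + rlen]
            if int(rng.integers(0, 2)):
                seq = revcomp(seq)
            count = int(rng.integers(1, 6))
            srna_counts[seq] = srna_counts.get(seq, 0) + count

    srna_reads = [
        UniqueRead(seq=s, count=n) for s, n in sorted(srna_counts.items())
    ]

    # degradome: Poisson background everywhere plus the cleavage peaks
    tag = cfg.degradome_tag_length
    deg_counts: dict[str, int] = {}
    for ti, t in enumerate(transcripts):
        n_pos = max(0, t.length - tag + 1)
        if cfg.degradome_background > 0 and n_pos > 0:
            bg = rng.poisson(cfg.degradome_background, size=n_pos)
            for pos in np.nonzero(bg)[0]:
                s = t.seq[pos : pos + tag]
                deg_counts[s] = deg_counts.get(s, 0) + int(bg[pos])
    for ti, pos, height in deg_peaks:
        s = transcripts[ti].seq[pos : pos + tag]
        deg_counts[s] = deg_counts.get(s, 0) + height
    degradome_reads = [
        UniqueRead(seq=s, count=n) for s, n in sorted(deg_counts.items())
    ]

    return SimResult(
        config=cfg,
        transcripts=transcripts,
        srna_reads=srna_reads,
        mirnas=mirnas,
        degradome_reads=degradome_reads,
        truth=truth,
    )


_TRUTH_COLUMNS = [
    "transcript_id", "start", "end", "register", "p", "phasirna_seqs",
    "phasirna_counts", "trigger_id", "site_start", "site_end",
    "cleavage_position",
]


def write_sim(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the five simulator files; returns {role: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "srna": outdir / "srna_collapsed.fasta",
        "mirna": outdir / "mirna.fasta",
        "degradome": outdir / "degradome_collapsed.fasta",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(((t.id, t.seq) for t in result.transcripts), paths["transcripts"])
    write_collapsed_fasta(result.srna_reads, paths["srna"], prefix="srna")
    write_fasta(result.mirnas.items(), paths["mirna"])
    write_collapsed_fasta(result.degradome_reads, paths["degradome"], prefix="deg")
    with open(paths["truth"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TRUTH_COLUMNS)
        for tl in result.truth:
            w.writerow(
                [
                    tl.transcript_id, tl.start, tl.end, tl.register, tl.p,
                    ";".join(tl.phasirna_seqs),
                    ";".join(map(str, tl.phasirna_counts)),
                    tl.trigger_id, tl.site_start, tl.site_end,
                    tl.cleavage_position,
                ]
            )
    return paths


def read_truth(path: str | Path) -> list[TruthLocus]:
    out: list[TruthLocus] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthLocus(
                    transcript_id=row["transcript_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    register=int(row["register"]),
                    p=int(row["p"]),
                    phasirna_seqs=row["phasirna_seqs"].split(";") if row["phasirna_seqs"] else [],
                    phasirna_counts=[int(x) for x in row["phasirna_counts"].split(";")] if row["phasirna_counts"] else [],
                    trigger_id=row["trigger_id"],
                    site_start=int(row["site_start"]),
                    site_end=int(row["site_end"]),
                    cleavage_position=int(row["cleavage_position"]),
                )
            )
    return out


@dataclass
class EvalMetrics:
    locus_recall: float
    locus_precision: float
    register_accuracy: float  # fraction of matched truth loci with correct register
    trigger_recovery: float
    n_truth: int
    n_called: int


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def evaluate(
    called_loci: list[PhasLocus],
    trigger_calls: list,
    truth: list[TruthLocus],
) -> EvalMetrics:
    """Score called loci and trigger calls against the simulator's truth.

    A called locus matches a truth locus when they share a transcript, the
    intervals overlap, and the registers agree.  The trigger is recovered
    when, among trigger calls on the truth transcript, the top valid-read
    call is the implanted miRNA at (an overlap of) the implanted site.
    """
    matched_truth = 0
    register_ok = 0
    matched_calls: set[int] = set()
    for tl in truth:
        hit = False
        for idx, locus in enumerate(called_loci):
            if locus.transcript_id != tl.transcript_id:
                continue
            if not _overlaps(locus.start, locus.end, tl.start, tl.end):
                continue
            hit = True
            matched_calls.add(idx)
            if locus.p == tl.p and locus.best_register == tl.register:
                register_ok += 1
                break
        if hit:
            matched_truth += 1

    trigger_hits = 0
    for tl in truth:
        calls = [
            c
            for c in trigger_calls
            if c.site.transcript_id == tl.transcript_id
            and c.site.strand_of_target == SENSE
        ]
        if not calls:
            continue
        top = max(calls, key=lambda c: c.valid_reads)
        if top.site.small_rna_id == tl.trigger_id and _overlaps(
            top.site.site_start, top.site.site_end, tl.site_start, tl.site_end
        ):
            trigger_hits += 1

    n_truth = len(truth)
    n_called = len(called_loci)
    return EvalMetrics(
        locus_recall=matched_truth / n_truth if n_truth else 1.0,
        locus_precision=len(matched_calls) / n_called if n_called else 1.0,
        register_accuracy=register_ok / n_truth if n_truth else 1.0,
        trigger_recovery=trigger_hits / n_truth if n_truth else 1.0,
        n_truth=n_truth,
        n_called=n_called,
    )
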
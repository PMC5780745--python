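"""PHAS locus calling: phasing statistics, window scan, merge, FDR, extraction.

The phasing model
-----------------
A PHAS precursor is diced from a defined 5' end into head-to-tail increments
of the cycle length ``p`` (21 or 24 nt), so the 5' ends of its small RNAs
share a residue class mod ``p`` — the *register*.  Antisense reads sit 2 nt
to the left of their sense partners because Dicer duplexes carry 2-nt 3'
overhangs, so an antisense read's *effective position* is its leftmost
sense-strand coordinate plus two.

For a window of ``m`` consecutive cycles (``p*m`` nt) anchored at a
candidate register position, with ``n`` unique length-``p`` reads in the
window of which ``k`` are in-register, the phasing P-value is the
upper-tail hypergeometric probability of seeing at least ``k`` in-register
placements by chance:

    P(X >= k) = sum_{x=k}^{min(m,n)} C(m, x) C((p-1)m, n-x) / C(pm, n)

and the phase score weighs the abundance of in-register reads against
off-register abundance:

    score = (k - 2) * ln(1 + 10 * sum(P_i) / (1 + sum(U_i)))    for k >= 3

where P_i / U_i are the phased / non-phased read abundances per cycle.
Windows with raw P < 0.05 are extended 100 bp at both ends, overlapping
windows are merged, merged regions are corrected with Benjamini-Hochberg,
and regions with max score >= 5 and corrected P < 0.05 become PHAS loci.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .sequence_io import ANTISENSE, MappedRead, SENSE, Transcript


@dataclass
class PhaseConfig:
    """Tunable parameters of the PHAS scan.

    p: cycle length in nt (21 or 24; any p >= 2 accepted).
    m: number of cycles per window (window span = p*m).
    extension: nt added to each end of significant windows before merging.
    extend_p: raw P-value threshold for extending a window.
    min_phase_score: minimum max phase score for a locus.
    alpha: corrected-P (FDR) threshold for a locus.
    min_unique_phased: minimum k for the phase score to be defined.
    """

    p: int = 21
    m: int = 10
    extension: int = 100
    extend_p: float = 0.05
    min_phase_score: float = 5.0
    alpha: float = 0.05
    min_unique_phased: int = 3

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError(f"cycle length p must be >= 2, got {self.p}")
        if self.m < 2:
            raise ValueError(f"phases per window m must be >= 2, got {self.m}")

    @property
    def span(self) -> int:
        return self.p * self.m


@dataclass
class WindowStats:
    """Phasing statistics of one candidate window."""

    transcript_id: str
    window_start: int
    p: int
    m: int
    k: int
    n: int
    sum_P: int
    sum_U: int
    p_value: float
    phase_score: float

    @property
    def register(self) -> int:
        return self.window_start % self.p


@dataclass
class MergedRegion:
    """Extended and merged significant windows on one transcript."""

    transcript_id: str
    start: int
    end: int
    p: int
    min_p_value: float
    max_phase_score: float
    best_window_start: int
    n_windows: int
    fdr: float | None = None

    @property
    def best_register(self) -> int:
        return self.best_window_start % self.p


@dataclass
class PhasLocus:
    name: str
    transcript_id: str
    start: int
    end: int
    p: int
    best_window_start: int
    best_register: int
    max_phase_score: float
    min_p_value: float
    fdr: float
    k: int = 0
    n: int = 0


@dataclass
class PhasiRNA:
    name: str
    locus_name: str
    seq: str
    strand: str
    position: int  # effective phase coordinate
    abundance: int

    @property
    def length(self) -> int:
        return len(self.seq)


def effective_position(read: MappedRead) -> int:
    """Phase coordinate of a read's 5' end.

    Sense reads phase at their start; antisense reads at start + 2, because
    the 2-nt 3' overhang of the Dicer duplex shifts the antisense partner
    two nucleotides to the left of the sense register.
    """
    return read.start + 2 if read.strand == ANTISENSE else read.start


def phasing_p_value(k: int, n: int, m: int, p: int) -> float:
    """Upper-tail hypergeometric probability of >= k in-register reads.

    Of the ``p*m`` positions in a window, ``m`` are in-register.  Drawing
    the ``n`` observed distinct read positions uniformly without
    replacement, this is P(X >= k) for X hypergeometric(pm, m, n).
    """
    if not (0 <= k <= min(n, m)):
        raise ValueError(f"need 0 <= k <= min(n, m); got k={k}, n={n}, m={m}")
    if n > p * m:
        raise ValueError(f"n={n} exceeds window positions p*m={p * m}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, p * m, m, n))


def phase_score(k: int, sum_P: float, sum_U: float, m: int = 10,
                min_unique_phased: int = 3) -> float:
    """Abundance-weighted phasing score; 0.0 below the unique-read gate."""
    if k < min_unique_phased:
        return 0.0
    return (k - 2) * math.log1p(10.0 * sum_P / (1.0 + sum_U))


def scan_transcript(
    reads: list[MappedRead], transcript: Transcript, cfg: PhaseConfig
) -> list[WindowStats]:
    """Compute phasing statistics at every candidate window of one transcript.

    Windows are anchored at the distinct effective positions of length-``p``
    reads whose window ``[anchor, anchor + p*m)`` lies fully on the
    transcript (an anchor with no read starting in-register would have k=0,
    so other anchor choices add nothing).  Only reads of length exactly
    ``p`` enter the statistic: ``k``/``n`` count distinct occupied effective
    positions (a sense read and its antisense duplex partner share one
    phase position, which keeps k <= min(n, m) as the hypergeometric model
    requires), while ``sum_P``/``sum_U`` count abundance of in-register /
    off-register placements.
    """
    p, span = cfg.p, cfg.span
    tlen = transcript.length
    placed = [
        (effective_position(r), r)
        for r in reads
        if r.len == p and r.transcript_id == transcript.id
    ]
    anchors = sorted({e for e, _ in placed if 0 <= e and e + span <= tlen})
    out: list[WindowStats] = []
    for a in anchors:
        phased_pos: set[int] = set()
        all_pos: set[int] = set()
        sum_P = sum_U = 0
        for e, r in placed:
            if a <= e < a + span:
                all_pos.add(e)
                if (e - a) % p == 0:
                    phased_pos.add(e)
                    sum_P += r.read.count
                else:
                    sum_U += r.read.count
        k, n = len(phased_pos), len(all_pos)
        out.append(
            WindowStats(
                transcript_id=transcript.id,
                window_start=a,
                p=p,
                m=cfg.m,
                k=k,
                n=n,
                sum_P=sum_P,
                sum_U=sum_U,
                p_value=phasing_p_value(k, n, cfg.m, p),
                phase_score=phase_score(k, sum_P, sum_U, cfg.m,
                                        cfg.min_unique_phased),
            )
        )
    return out


def extend_and_merge(
    windows: list[WindowStats], cfg: PhaseConfig, transcript_len: int
) -> list[MergedRegion]:
    """Extend significant windows and merge transitive overlaps.

    Windows with raw P below ``cfg.extend_p`` are widened by
    ``cfg.extension`` nt at both ends (clipped to the transcript) and
    transitively overlapping intervals are merged.  A merged region keeps
    the minimum raw P, the maximum phase score, and the anchor of its
    best-scoring member window.  Idempotent on its own output intervals.
    """
    sig = [w for w in windows if w.p_value < cfg.extend_p]
    if not sig:
        return []
    spans = sorted(
        (
            max(0, w.window_start - cfg.extension),
            min(transcript_len, w.window_start + cfg.span + cfg.extension),
            w,
        )
        for w in sig
    )
    regions: list[MergedRegion] = []
    cur_start, cur_end, w0 = spans[0]
    members = [w0]
    for s, e, w in spans[1:]:
        if s < cur_end:  # overlap (half-open)
            cur_end = max(cur_end, e)
            members.append(w)
        else:
            regions.append(_make_region(cur_start, cur_end, members))
            cur_start, cur_end, members = s, e, [w]
    regions.append(_make_region(cur_start, cur_end, members))
    return regions


def _make_region(start: int, end: int, members: list[WindowStats]) -> MergedRegion:
    best = max(members, key=lambda w: (w.phase_score, -w.window_start))
    return MergedRegion(
        transcript_id=members[0].transcript_id,
        start=start,
        end=end,
        p=members[0].p,
        min_p_value=min(w.p_value for w in members),
        max_phase_score=max(w.phase_score for w in members),
        best_window_start=best.window_start,
        n_windows=len(members),
    )


def fdr_correct(regions: list[MergedRegion]) -> list[MergedRegion]:
    """Benjamini-Hochberg correction over all merged regions (in place)."""
    if not regions:
        return regions
    pvals = [r.min_p_value for r in regions]
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(regions, adjusted):
        r.fdr = float(q)
    return regions


def sanitize_id(transcript_id: str) -> str:
    """Transcript id as used in locus names: '|' and whitespace become '_'."""
    return re.sub(r"[|\s]+", "_", transcript_id.strip())


def call_loci(regions: list[MergedRegion], cfg: PhaseConfig) -> list[PhasLocus]:
    """Threshold FDR-corrected regions into named PHAS loci.

    A region becomes a locus when its max phase score reaches
    ``cfg.min_phase_score`` and its corrected P is below ``cfg.alpha``.
    Loci are named ``P{p}_{transcript}_{serial}`` with serials assigned per
    transcript in ascending coordinate order starting at 1.
    """
    passing = [
        r
        for r in regions
        if r.fdr is not None
        and r.max_phase_score >= cfg.min_phase_score
        and r.fdr < cfg.alpha
    ]
    passing.sort(key=lambda r: (r.transcript_id, r.start))
    loci: list[PhasLocus] = []
    serial: dict[str, int] = {}
    for r in passing:
        serial[r.transcript_id] = serial.get(r.transcript_id, 0) + 1
        name = f"P{r.p}_{sanitize_id(r.transcript_id)}_{serial[r.transcript_id]}"
        loci.append(
            PhasLocus(
                name=name,
                transcript_id=r.transcript_id,
                start=r.start,
                end=r.end,
                p=r.p,
                best_window_start=r.best_window_start,
                best_register=r.best_register,
                max_phase_score=r.max_phase_score,
                min_p_value=r.min_p_value,
                fdr=r.fdr,
            )
        )
    return loci


def extract_phasirnas(locus: PhasLocus, reads: list[MappedRead]) -> list[PhasiRNA]:
    """All in-register length-``p`` reads inside a locus, serial-named 5'->3'.

    Ties at the same effective position order sense before antisense.
    """
    p = locus.p
    found: list[tuple[int, int, MappedRead]] = []
    for r in reads:
        if r.transcript_id != locus.transcript_id or r.len != p:
            continue
        if r.start < locus.start or r.end > locus.end:
            continue
        e = effective_position(r)
        if e % p == locus.best_register:
            found.append((e, 0 if r.strand == SENSE else 1, r))
    found.sort(key=lambda t: (t[0], t[1]))
    return [
        PhasiRNA(
            name=f"{locus.name}_siR{i}",
            locus_name=locus.name,
            seq=r.read.seq,
            strand=r.strand,
            position=e,
            abundance=r.read.count,
        )
        for i, (e, _, r) in enumerate(found, start=1)
    ]


def find_phas_loci(
    transcripts: list[Transcript],
    mapped: list[MappedRead],
    cfg: PhaseConfig,
) -> tuple[list[PhasLocus], list[PhasiRNA], list[MergedRegion]]:
    """Full scan across a transcriptome: windows -> regions -> FDR -> loci.

    FDR correction is joint over the merged regions of all transcripts.
    Returns the called loci, their phasiRNAs, and all merged regions (with
    corrected P attached) for reporting.
    """
    by_tid: dict[str, list[MappedRead]] = {}
    for r in mapped:
        by_tid.setdefault(r.transcript_id, []).append(r)
    regions: list[MergedRegion] = []
    for t in transcripts:
        reads = by_tid.get(t.id, [])
        if not reads:
            continue
        windows = scan_transcript(reads, t, cfg)
        regions.extend(extend_and_merge(windows, cfg, t.length))
    fdr_correct(regions)
    loci = call_loci(regions, cfg)
    # attach the best window's k/n for reporting
    tmap = {t.id: t for t in transcripts}
    phasirnas: list[PhasiRNA] = []
    for locus in loci:
        reads = by_tid.get(locus.transcript_id, [])
        wins = scan_transcript(reads, tmap[locus.transcript_id], cfg)
        for w in wins:
            if w.window_start == locus.best_window_start:
                locus.k, locus.n = w.k, w.n
                break
        phasirnas.extend(extract_phasirnas(locus, reads))
    return loci, phasirnas, regions
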
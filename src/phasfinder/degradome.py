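"""Degradome (PARE) support for trigger miRNAs and phasiRNA targets.

Degradome sequencing captures the uncapped 5' ends of polyadenylated
transcripts; a read 5' end marks a cleavage position on the sense strand.
A small RNA is tied to a candidate site by ungapped complementarity, and
the site is supported when degradome reads start opposite positions 9-11
of the small RNA ("valid reads") — the canonical slicing site lies between
small-RNA positions 10 and 11.

Trigger miRNAs for PHAS loci use an OR rule (>= 1 valid read OR < 4
mismatches, because conserved miRNA/target pairs are trusted on pairing
alone); phasiRNA targets use the stricter AND rule (>= 1 valid read AND
< 4 mismatches).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .phas_core import PhasLocus, PhasiRNA
from .sequence_io import ANTISENSE, SENSE, Transcript, UniqueRead, revcomp

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # G:U pairs in DNA alphabet


@dataclass
class DegradomeProfile:
    """Per-transcript counts of degradome read 5' ends (sense strand only)."""

    counts: dict[str, dict[int, int]] = field(default_factory=dict)

    def add(self, transcript_id: str, position: int, count: int = 1) -> None:
        per = self.counts.setdefault(transcript_id, {})
        per[position] = per.get(position, 0) + count

    def at(self, transcript_id: str, position: int) -> int:
        return self.counts.get(transcript_id, {}).get(position, 0)


def build_profile(
    reads: Sequence[UniqueRead],
    transcripts: Sequence[Transcript],
    tag_len: int = 20,
) -> DegradomeProfile:
    """Map degradome tags to transcripts and tally 5'-end positions.

    PARE tags are fixed-length; the 5'-most ``tag_len`` nt of each read is
    matched exactly against the sense strand of every transcript, and the
    full count is added at every match (multi-mapping tags count at each
    location).
    """
    profile = DegradomeProfile()
    for t in transcripts:
        s = t.seq
        for r in reads:
            tag = r.seq[:tag_len]
            if not tag:
                continue
            idx = s.find(tag)
            while idx >= 0:
                profile.add(t.id, idx, r.count)
                idx = s.find(tag, idx + 1)
    return profile


@dataclass
class ComplementarySite:
    """An ungapped complementarity hit of a small RNA on a transcript."""

    small_rna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    strand_of_target: str  # SENSE or ANTISENSE
    mismatches: float
    pairing: str  # '|' Watson-Crick, 'o' G:U wobble, '.' mismatch; 5'->3' of the small RNA


@dataclass
class TargetCall:
    site: ComplementarySite
    valid_reads: int
    total_reads_at_9_11: int
    cleavage_position: int
    is_cis: bool = False
    trigger_consistent: bool = False
    antisense_no_degradome: bool = False


def _pair_class(a: str, b: str) -> str:
    if (a, b) in _WC:
        return "|"
    if (a, b) in _WOBBLE:
        return "o"
    return "."


def find_complementary_sites(
    small_rna_id: str,
    small_rna_seq: str,
    transcript: Transcript,
    max_mismatches: float = 3,
    gu_weight: float = 1.0,
    strands: Iterable[str] = (SENSE, ANTISENSE),
) -> list[ComplementarySite]:
    """Scan both strands of a transcript for ungapped complementary sites.

    Small-RNA position ``j`` (1-based from its 5' end) pairs the target
    base at the ``j``-th position from the target's 3' end; for a sense
    site paired to the transcript interval ``[s, e)`` that is transcript
    position ``e - j``.  Any non-Watson-Crick pair counts ``1`` mismatch
    except G:U, which counts ``gu_weight`` (1.0 by default, 0.5 to treat
    wobbles as half-mismatches).  Sites with total weight <=
    ``max_mismatches`` are reported.
    """
    srna = small_rna_seq.upper().replace("U", "T")
    L = len(srna)
    out: list[ComplementarySite] = []
    for strand in strands:
        for s in range(transcript.length - L + 1):
            target = transcript.seq[s : s + L]
            if strand == ANTISENSE:
                target = revcomp(target)
            mm = 0.0
            pairing = []
            for j in range(1, L + 1):
                cls = _pair_class(srna[j - 1], target[L - j])
                pairing.append(cls)
                if cls == "o":
                    mm += gu_weight
                elif cls == ".":
                    mm += 1.0
                if mm > max_mismatches:
                    break
            else:
                out.append(
                    ComplementarySite(
                        small_rna_id=small_rna_id,
                        transcript_id=transcript.id,
                        site_start=s,
                        site_end=s + L,
                        strand_of_target=strand,
                        mismatches=mm,
                        pairing="".join(pairing),
                    )
                )
    return out


def count_valid_reads(
    site: ComplementarySite, degradome: DegradomeProfile
) -> tuple[int, dict[int, int], bool]:
    """Sum degradome 5' ends opposite small-RNA positions 9-11.

    Returns ``(valid_reads, {small_rna_position: count}, undefined_flag)``.
    The transcript position opposite small-RNA position ``j`` of a site
    paired to ``[s, e)`` is ``e - j``.  Degradome reads cover only the
    sense (polyadenylated) strand, so for an antisense site the count is
    undefined: 0 with the flag set.
    """
    if site.strand_of_target == ANTISENSE:
        return 0, {}, True
    breakdown = {
        j: degradome.at(site.transcript_id, site.site_end - j) for j in (9, 10, 11)
    }
    return sum(breakdown.values()), breakdown, False


def cleavage_position(site: ComplementarySite) -> int:
    """Transcript position opposite small-RNA position 10 (slicing is 10/11)."""
    return site.site_end - 10


def _register_distance(pos: int, register: int, p: int) -> int:
    d = (pos - register) % p
    return min(d, p - d)


def _make_call(
    site: ComplementarySite, degradome: DegradomeProfile
) -> TargetCall:
    valid, breakdown, undefined = count_valid_reads(site, degradome)
    return TargetCall(
        site=site,
        valid_reads=valid,
        total_reads_at_9_11=sum(breakdown.values()),
        cleavage_position=cleavage_position(site),
        antisense_no_degradome=undefined,
    )


def call_triggers(
    mirnas: Mapping[str, str],
    loci: Sequence[PhasLocus],
    transcripts: Sequence[Transcript],
    degradome: DegradomeProfile,
    scan_max_mismatches: float = 6,
    gu_weight: float = 1.0,
) -> list[TargetCall]:
    """Candidate trigger miRNA sites on PHAS transcripts (OR rule).

    Every miRNA is scanned against both strands of every PHAS transcript
    up to ``scan_max_mismatches``; a site is reported when it has at least
    one valid degradome read OR fewer than 4 mismatches.  A reported site
    is flagged trigger-consistent when its inferred cleavage position sits
    in the register of a locus on that transcript (within 1 nt, tolerating
    the 10/11 slicing convention).
    """
    tmap = {t.id: t for t in transcripts}
    loci_by_tid: dict[str, list[PhasLocus]] = {}
    for locus in loci:
        loci_by_tid.setdefault(locus.transcript_id, []).append(locus)
    calls: list[TargetCall] = []
    for tid, tloci in loci_by_tid.items():
        transcript = tmap[tid]
        for mid, mseq in mirnas.items():
            for site in find_complementary_sites(
                mid, mseq, transcript, scan_max_mismatches, gu_weight
            ):
                call = _make_call(site, degradome)
                if call.valid_reads >= 1 or site.mismatches < 4:
                    call.trigger_consistent = any(
                        _register_distance(
                            call.cleavage_position, locus.best_register, locus.p
                        )
                        <= 1
                        for locus in tloci
                    )
                    calls.append(call)
    return calls


def call_phasirna_targets(
    phasirnas: Sequence[PhasiRNA],
    source_transcript: Mapping[str, str],
    transcripts: Sequence[Transcript],
    degradome: DegradomeProfile,
    gu_weight: float = 1.0,
) -> list[TargetCall]:
    """PhasiRNA target sites with degradome support (AND rule).

    A site is reported only when it has fewer than 4 mismatches AND at
    least one valid degradome read.  ``source_transcript`` maps phasiRNA
    names to the transcript their locus lives on; a target on that same
    transcript is a cis-target, anything else trans.
    """
    calls: list[TargetCall] = []
    for phasirna in phasirnas:
        src = source_transcript.get(phasirna.name)
        for transcript in transcripts:
            for site in find_complementary_sites(
                phasirna.name, phasirna.seq, transcript, 3, gu_weight
            ):
                call = _make_call(site, degradome)
                if call.valid_reads >= 1 and site.mismatches < 4:
                    call.is_cis = transcript.id == src
                    calls.append(call)
    return calls
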
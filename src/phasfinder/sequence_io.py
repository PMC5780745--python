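"""Sequence I/O, read collapsing, and exact-match transcriptome alignment.

Small-RNA libraries arrive as FASTQ, plain FASTA, or collapsed FASTA (one
record per unique sequence with the abundance encoded in the header, e.g.
``read1_x42``).  This module normalises all of them into :class:`UniqueRead`
objects, places them on a transcriptome by exact full-length matching on
both strands, and can also import precomputed alignments from SAM.

Coordinates are 0-based, half-open everywhere inside the package; 1-based
conventions appear only at the SAM/GFF boundary.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: trailing abundance suffix of collapsed-FASTA headers: "_x<INT>" or "-<INT>"
_COUNT_SUFFIX = re.compile(r"(?:_x(\d+)|-(\d+))$")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ/SAM input."""


@dataclass(frozen=True)
class Transcript:
    """A reference cDNA sequence.

    ``id`` is the verbatim first whitespace-delimited token of the FASTA
    header (e.g. ``TR101427|c8_g4_i1``); ``seq`` is upper-case DNA with U
    already converted to T.
    """

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class UniqueRead:
    """A unique small-RNA sequence with its summed abundance."""

    seq: str
    count: int = 1
    per_library_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"UniqueRead count must be >= 1, got {self.count}")
        if self.per_library_counts is not None:
            total = sum(self.per_library_counts.values())
            if total != self.count:
                raise ValueError(
                    f"per-library counts sum to {total}, but count={self.count}"
                )

    def __len__(self) -> int:
        return len(self.seq)


SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class MappedRead:
    """A unique read placed on a transcript.

    ``start`` is the 0-based leftmost sense-strand coordinate of the covered
    interval ``[start, start+len)`` regardless of strand.  For antisense
    placements the read sequence equals the reverse complement of the covered
    transcript interval.
    """

    read: UniqueRead
    transcript_id: str
    start: int
    strand: str  # SENSE or ANTISENSE

    @property
    def len(self) -> int:
        return len(self.read.seq)

    @property
    def end(self) -> int:
        return self.start + self.len


def verify_mapped_read(mr: MappedRead, transcript: Transcript) -> bool:
    """Check the placement invariant against the transcript sequence."""
    if mr.start < 0 or mr.end > transcript.length:
        return False
    covered = transcript.seq[mr.start : mr.end]
    expect = covered if mr.strand == SENSE else revcomp(covered)
    return mr.read.seq == expect


# ---------------------------------------------------------------------------
# FASTA / FASTQ ingest
# ---------------------------------------------------------------------------

def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a transcriptome FASTA into a list of :class:`Transcript`.

    Record order is preserved; sequences are upper-cased with U converted to
    T.  Duplicate ids and syntactically malformed records raise
    :class:`ParseError` (with a line number where one can be attributed).
    """
    path = Path(path)
    # find the first non-blank line to give a usable error for non-FASTA input
    with open(path) as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(
                        f"{path}:{lineno}: expected FASTA header line starting "
                        f"with '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            return []

    out: list[Transcript] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            tid = header.split()[0] if header.split() else ""
            if not tid:
                raise ParseError(f"{path}: FASTA record with empty header")
            if tid in seen:
                raise ParseError(f"{path}: duplicate transcript id {tid!r}")
            seen.add(tid)
            out.append(Transcript(id=tid, seq=_normalize(seq)))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (header, sequence) pairs as FASTA."""
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n{seq}\n")


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ParseError(f"{path}: not FASTA or FASTQ")
    return "empty"


def _parse_count(header: str, forced: bool) -> int:
    m = _COUNT_SUFFIX.search(header.split()[0]) if header.split() else None
    if m is None:
        if forced:
            raise ParseError(
                f"collapsed-FASTA dialect forced but header {header!r} has no "
                "_x<INT> or -<INT> count suffix"
            )
        return 1
    return int(m.group(1) or m.group(2))


def _trim_adapter(seq: str, adapter_prefix: str | None) -> str:
    """Remove everything from the leftmost exact match of the adapter prefix."""
    if not adapter_prefix:
        return seq
    idx = seq.find(adapter_prefix)
    return seq[:idx] if idx >= 0 else seq


def collapse_reads(
    paths: Sequence[str | Path] | str | Path,
    min_len: int = 18,
    max_len: int = 30,
    adapter3: str | None = None,
    min_quality: int = 20,
    collapsed_dialect: str = "auto",
) -> list[UniqueRead]:
    """Collapse FASTQ/FASTA small-RNA files into unique reads with counts.

    FASTQ reads containing any base below ``min_quality`` (Phred+33) are
    discarded before adapter trimming.  The 3' adapter is located as the
    leftmost exact match of its first 8 nt and everything from that point is
    removed.  Reads outside ``[min_len, max_len]`` after trimming are dropped.
    Collapsed-FASTA abundance suffixes (``_x<INT>`` / ``-<INT>``) are parsed
    from headers; ``collapsed_dialect='forced'`` makes a missing suffix an
    error, ``'plain'`` disables suffix parsing.

    Collapsing is idempotent: re-collapsing the emitted unique reads (written
    back as collapsed FASTA) yields the same multiset.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    adapter_prefix = adapter3[:8] if adapter3 else None
    per_lib: dict[str, dict[str, int]] = {}

    for path in paths:
        path = Path(path)
        lib = path.name
        counts = per_lib.setdefault(lib, {})
        fmt = _sniff_format(path)
        if fmt == "empty":
            continue
        if fmt == "fastq":
            with open(path) as fh:
                for title, seq, qual in FastqGeneralIterator(fh):
                    if len(seq) != len(qual):
                        raise ParseError(
                            f"{path}: length/quality mismatch for read {title!r}"
                        )
                    if any(ord(c) - 33 < min_quality for c in qual):
                        continue
                    seq = _trim_adapter(_normalize(seq), adapter_prefix)
                    if min_len <= len(seq) <= max_len:
                        counts[seq] = counts.get(seq, 0) + 1
        else:
            forced = collapsed_dialect == "forced"
            with open(path) as fh:
                for header, seq in SimpleFastaParser(fh):
                    n = 1
                    if collapsed_dialect != "plain":
                        n = _parse_count(header, forced)
                    seq = _trim_adapter(_normalize(seq), adapter_prefix)
                    if min_len <= len(seq) <= max_len:
                        counts[seq] = counts.get(seq, 0) + n

    merged: dict[str, dict[str, int]] = {}
    for lib, counts in per_lib.items():
        for seq, n in counts.items():
            merged.setdefault(seq, {})[lib] = merged.setdefault(seq, {}).get(lib, 0) + n

    out = []
    for seq in sorted(merged):
        libs = merged[seq]
        out.append(
            UniqueRead(seq=seq, count=sum(libs.values()), per_library_counts=dict(libs))
        )
    return out


def write_collapsed_fasta(
    reads: Iterable[UniqueRead], path: str | Path, prefix: str = "read"
) -> None:
    """Write unique reads as collapsed FASTA with ``_x<count>`` headers."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">{prefix}{i}_x{r.count}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_exact(
    reads: Sequence[UniqueRead], transcripts: Sequence[Transcript]
) -> list[MappedRead]:
    """Place every read at every exact full-length match, both strands.

    A read maps sense where its sequence occurs verbatim, and antisense where
    its reverse complement occurs (reported with the leftmost sense-strand
    coordinate of the covered interval).  Multi-mapping reads are reported at
    every location with their full count; reads with no hit are simply absent.
    """
    sense_idx: dict[str, UniqueRead] = {}
    anti_idx: dict[str, UniqueRead] = {}
    for r in reads:
        sense_idx[r.seq] = r
        anti_idx[revcomp(r.seq)] = r
    lengths = sorted({len(r.seq) for r in reads})
    hits: list[MappedRead] = []
    for t in transcripts:
        s = t.seq
        L = len(s)
        for start in range(L):
            for k in lengths:
                end = start + k
                if end > L:
                    break
                sub = s[start:end]
                r = sense_idx.get(sub)
                if r is not None:
                    hits.append(MappedRead(r, t.id, start, SENSE))
                r = anti_idx.get(sub)
                if r is not None:
                    hits.append(MappedRead(r, t.id, start, ANTISENSE))
    return hits


def import_sam(
    path: str | Path, transcripts: Sequence[Transcript]
) -> list[MappedRead]:
    """Convert SAM alignments to :class:`MappedRead`.

    Only ungapped, full-length, zero-mismatch (NM==0) primary and secondary
    alignments are kept; soft-clipped or indel-containing records are skipped
    with a logged count.  FLAG 16 becomes an antisense placement and the read
    sequence is restored to its original orientation.  An abundance suffix on
    the read name (``_x<INT>`` / ``-<INT>``) is honoured; otherwise count=1.
    """
    known = {t.id for t in transcripts}
    hits: list[MappedRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in known:
                raise ParseError(f"{path}: SAM reference {ref!r} not in transcriptome")
        for rec in sam:
            if rec.is_unmapped:
                continue
            cigar = rec.cigartuples or []
            full_match = len(cigar) == 1 and cigar[0][0] == 0  # single M op
            try:
                nm = rec.get_tag("NM")
            except KeyError:
                nm = 0
            if not full_match or nm != 0:
                skipped += 1
                continue
            seq = rec.query_sequence
            if seq is None:
                skipped += 1
                continue
            seq = _normalize(seq)
            strand = ANTISENSE if rec.is_reverse else SENSE
            # SAM stores the reference-oriented sequence
            read_seq = revcomp(seq) if strand == ANTISENSE else seq
            count = _parse_count(rec.query_name or "", forced=False)
            hits.append(
                MappedRead(
                    UniqueRead(seq=read_seq, count=count),
                    rec.reference_name,
                    rec.reference_start,
                    strand,
                )
            )
    if skipped:
        log.info("import_sam: skipped %d clipped/gapped/mismatched records", skipped)
    return hits
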
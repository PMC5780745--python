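"""Phasing statistics, window scan, merging, FDR and locus calling."""

import math
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import hypergeom_tail_oracle
from phasfinder.phas_core import (
    MergedRegion,
    PhaseConfig,
    WindowStats,
    call_loci,
    effective_position,
    extend_and_merge,
    extract_phasirnas,
    fdr_correct,
    phase_score,
    phasing_p_value,
    sanitize_id,
    scan_transcript,
)
from phasfinder.sequence_io import (
    ANTISENSE,
    SENSE,
    MappedRead,
    Transcript,
    UniqueRead,
    revcomp,
)


def _mk_read(seq, tid, start, strand=SENSE, count=1):
    return MappedRead(UniqueRead(seq=seq, count=count), tid, start, strand)


class TestEffectivePosition:
    def test_sense_is_identity(self):
        assert effective_position(_mk_read("A" * 21, "t", 42)) == 42

    def test_antisense_shifted_plus_two(self):
        assert effective_position(_mk_read("A" * 21, "t", 40, ANTISENSE)) == 42

    @pytest.mark.parametrize("p", [21, 24])
    def test_perfect_duplex_partners_share_register(self, p):
        """Dicer duplexes with 2-nt 3' overhangs: the antisense partner of a
        sense read at s covers [s-2, s+p-2), and both phase to s mod p."""
        rng = random.Random(99)
        for _ in range(100):
            s = rng.randrange(2, 5000)
            sense = _mk_read("G" * p, "t", s, SENSE)
            anti = _mk_read("C" * p, "t", s - 2, ANTISENSE)
            assert effective_position(sense) % p == s % p
            assert effective_position(anti) % p == s % p


class TestPhasingPValue:
    def test_k0_is_exactly_one(self):
        assert phasing_p_value(0, 17, 10, 21) == 1.0

    # expected values frozen from the exact-rational enumeration oracle
    @pytest.mark.parametrize(
        "k,n,m,p,expected",
        [
            (3, 3, 10, 21, 7.88684999211315e-05),
            (5, 12, 10, 24, 2.764107455967958e-05),
        ],
    )
    def test_matches_exact_enumeration(self, k, n, m, p, expected):
        assert phasing_p_value(k, n, m, p) == pytest.approx(expected, abs=1e-12)
        assert float(hypergeom_tail_oracle(k, n, m, p)) == pytest.approx(
            expected, rel=1e-15
        )

    def test_full_support_sums_to_one(self):
        """Vandermonde identity: the complete tail from k=0 is exactly 1."""
        for p in (21, 24):
            for n in (1, 7, 25):
                assert hypergeom_tail_oracle(0, n, 10, p) == Fraction(1)

    def test_strictly_decreasing_in_k(self):
        for p in (21, 24):
            vals = [phasing_p_value(k, 12, 10, p) for k in range(11)]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            phasing_p_value(5, 3, 10, 21)  # k > n
        with pytest.raises(ValueError):
            phasing_p_value(0, 500, 10, 21)  # n > p*m


class TestPhaseScore:
    def test_below_gate_is_zero(self):
        assert phase_score(2, 1000, 0) == 0.0
        assert phase_score(0, 0, 0) == 0.0

    def test_closed_forms(self):
        assert phase_score(3, 10, 0) == pytest.approx(math.log(101), rel=1e-12)
        assert phase_score(4, 20, 19) == pytest.approx(2 * math.log(11), rel=1e-12)

    @settings(max_examples=250, derandomize=True)
    @given(
        k=st.integers(3, 10),
        sum_p=st.integers(1, 10_000),
        sum_u=st.integers(0, 10_000),
    )
    def test_monotone_in_k_and_abundances(self, k, sum_p, sum_u):
        base = phase_score(k, sum_p, sum_u)
        assert phase_score(k + 1, sum_p, sum_u) >= base
        assert phase_score(k, sum_p + 1, sum_u) >= base
        assert phase_score(k, sum_p, sum_u + 1) <= base


def _uniq(p, i):
    """Distinct p-mer sequences for synthetic stacks."""
    body = format(i, "010b").replace("0", "AC").replace("1", "GT")
    return (body * 3)[:p]


class TestScanTranscript:
    def _transcript(self, length=400):
        return Transcript(id="t", seq="A" * length)

    def test_pure_phased_stack(self):
        t = self._transcript()
        reads = [_mk_read(_uniq(21, i), "t", 30 + 21 * i) for i in range(5)]
        cfg = PhaseConfig(p=21)
        wins = {w.window_start: w for w in scan_transcript(reads, t, cfg)}
        w = wins[30]
        assert (w.k, w.n, w.sum_U) == (5, 5, 0)
        assert w.sum_P == 5

    def test_other_lengths_invisible(self):
        t = self._transcript()
        reads = [_mk_read(_uniq(21, i), "t", 30 + 21 * i) for i in range(5)]
        reads.append(_mk_read(_uniq(22, 7), "t", 40))  # a 22-mer inside the window
        w = {w.window_start: w for w in scan_transcript(reads, t, PhaseConfig(p=21))}[30]
        assert (w.k, w.n) == (5, 5)

    def test_offregister_read_counts_in_n_and_sum_u(self):
        t = self._transcript()
        reads = [_mk_read(_uniq(21, i), "t", 30 + 21 * i) for i in range(5)]
        reads.append(_mk_read(_uniq(21, 9), "t", 31, SENSE, count=7))
        w = {w.window_start: w for w in scan_transcript(reads, t, PhaseConfig(p=21))}[30]
        assert (w.k, w.n, w.sum_U) == (5, 6, 7)

    def test_window_must_fit_transcript(self):
        t = self._transcript(length=200)  # shorter than one 210-nt window
        reads = [_mk_read(_uniq(21, 0), "t", 10)]
        assert scan_transcript(reads, t, PhaseConfig(p=21)) == []

    def test_strand_symmetry(self):
        """Swapping every read to its duplex partner on the other strand
        (same effective positions) leaves all window statistics unchanged."""
        t = self._transcript()
        fwd = [_mk_read(_uniq(21, i), "t", 30 + 21 * i) for i in range(5)]
        flipped = [
            _mk_read(revcomp(r.read.seq), "t", r.start - 2, ANTISENSE)
            for r in fwd
        ]
        cfg = PhaseConfig(p=21)
        a = [(w.window_start, w.k, w.n, w.sum_P, w.sum_U, w.p_value, w.phase_score)
             for w in scan_transcript(fwd, t, cfg)]
        b = [(w.window_start, w.k, w.n, w.sum_P, w.sum_U, w.p_value, w.phase_score)
             for w in scan_transcript(flipped, t, cfg)]
        assert a == b


def _win(tid, start, pval, score, p=21):
    return WindowStats(tid, start, p, 10, 5, 5, 10, 0, pval, score)


class TestExtendAndMerge:
    def test_two_overlapping_windows_merge(self):
        cfg = PhaseConfig(p=21)
        wins = [_win("t", 0, 0.001, 6.0), _win("t", 50, 0.002, 8.0)]
        (region,) = extend_and_merge(wins, cfg, transcript_len=360)
        assert (region.start, region.end) == (0, 360)
        assert region.min_p_value == 0.001
        assert region.max_phase_score == 8.0
        assert region.best_window_start == 50

    def test_insignificant_window_dropped(self):
        cfg = PhaseConfig(p=21)
        assert extend_and_merge([_win("t", 0, 0.2, 9.0)], cfg, 1000) == []

    def test_empty_input(self):
        assert extend_and_merge([], PhaseConfig(p=21), 1000) == []

    def test_idempotent_on_own_intervals(self):
        cfg = PhaseConfig(p=21)
        wins = [_win("t", 0, 0.001, 6.0), _win("t", 400, 0.003, 7.0),
                _win("t", 430, 0.002, 5.5)]
        regions = extend_and_merge(wins, cfg, transcript_len=2000)
        intervals = [(r.start, r.end) for r in regions]
        # re-merging the merged intervals changes nothing
        merged_again = []
        for s, e in sorted(intervals):
            if merged_again and s < merged_again[-1][1]:
                merged_again[-1] = (merged_again[-1][0], max(merged_again[-1][1], e))
            else:
                merged_again.append((s, e))
        assert merged_again == sorted(intervals)


class TestFdrAndCalling:
    def test_bh_single_test_is_identity(self):
        r = MergedRegion("t", 0, 210, 21, 0.01, 6.0, 0, 1)
        fdr_correct([r])
        assert r.fdr == pytest.approx(0.01)

    def test_bh_hand_computed(self):
        regions = [
            MergedRegion("t", i * 500, i * 500 + 210, 21, pv, 6.0, i * 500, 1)
            for i, pv in enumerate([0.01, 0.02, 0.03])
        ]
        fdr_correct(regions)
        assert [r.fdr for r in regions] == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_all_ones(self):
        regions = [
            MergedRegion("t", i * 500, i * 500 + 210, 21, 1.0, 6.0, i * 500, 1)
            for i in range(4)
        ]
        fdr_correct(regions)
        assert all(r.fdr == 1.0 for r in regions)

    def test_locus_naming_matches_field_convention(self):
        cfg = PhaseConfig(p=21)
        tid = "TR101427|c8_g4_i1"
        regions = [
            MergedRegion(tid, 100, 600, 21, 0.001, 6.0, 200, 2, fdr=0.01),
            MergedRegion(tid, 900, 1300, 21, 0.002, 7.5, 1000, 1, fdr=0.01),
        ]
        loci = call_loci(regions, cfg)
        assert [lo.name for lo in loci] == [
            "P21_TR101427_c8_g4_i1_1",
            "P21_TR101427_c8_g4_i1_2",
        ]
        assert loci[0].best_register == 200 % 21

    def test_score_and_fdr_thresholds(self):
        cfg = PhaseConfig(p=21)
        low_score = MergedRegion("t", 0, 210, 21, 1e-6, 4.9, 0, 1, fdr=0.001)
        high_fdr = MergedRegion("t", 500, 710, 21, 0.04, 9.0, 500, 1, fdr=0.06)
        assert call_loci([low_score, high_fdr], cfg) == []

    def test_sanitize_id(self):
        assert sanitize_id("TR101427|c8_g4_i1") == "TR101427_c8_g4_i1"


class TestExtractPhasirnas:
    def _locus(self, register=9, start=0, end=300):
        from phasfinder.phas_core import PhasLocus

        return PhasLocus(
            name="P21_t_1", transcript_id="t", start=start, end=end, p=21,
            best_window_start=register, best_register=register,
            max_phase_score=10.0, min_p_value=1e-6, fdr=1e-4,
        )

    def test_serial_naming_in_coordinate_order(self):
        locus = self._locus(register=9)
        reads = [_mk_read(_uniq(21, i), "t", 9 + 21 * i) for i in range(5)]
        phas = extract_phasirnas(locus, reads)
        assert [p.name for p in phas] == [f"P21_t_1_siR{i}" for i in range(1, 6)]
        assert all(p.position % 21 == 9 for p in phas)

    def test_offregister_read_excluded(self):
        locus = self._locus(register=9)
        reads = [_mk_read(_uniq(21, 0), "t", 9), _mk_read(_uniq(21, 1), "t", 12)]
        assert len(extract_phasirnas(locus, reads)) == 1

    def test_antisense_in_register_included_and_ordered_after_sense(self):
        locus = self._locus(register=9)
        reads = [
            _mk_read(_uniq(21, 0), "t", 9, SENSE),
            _mk_read(_uniq(21, 1), "t", 7, ANTISENSE),  # effective position 9
        ]
        phas = extract_phasirnas(locus, reads)
        assert [p.strand for p in phas] == [SENSE, ANTISENSE]
        assert phas[0].position == phas[1].position == 9
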
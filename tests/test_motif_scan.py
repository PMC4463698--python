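"""Match-style PWM scanning: MSS/CSS scores, two-stage filter, strands."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pycher.errors import ValidationError
from pycher.motif_scan import (
    PWM,
    core_similarity,
    load_pwm,
    load_pwms,
    matrix_similarity,
    revcomp,
    scan_sequence,
)

BASES = "ACGT"

JASPAR_TEXT = """>MA0001.1 TOY
A [ 10  0  2  8  0  1 ]
C [  0 12  2  0  0  1 ]
G [  1  0  6  2 12  9 ]
T [  1  0  2  2  0  1 ]
"""

TRANSFAC_TEXT = """VV  test collection
XX
//
AC  M00001
XX
ID  TOY_TF
XX
DE  toy matrix
XX
P0      A      C      G      T
01     10      0      1      1      A
02      0     12      0      0      C
03      2      2      6      2      G
04      8      0      2      2      A
05      0      0     12      0      G
06      1      1      9      1      G
XX
//
"""


def sharp_pwm(consensus="ACGGAT", weight=0.91):
    freqs = np.full((len(consensus), 4), (1 - weight) / 3)
    for i, b in enumerate(consensus):
        freqs[i, BASES.index(b)] = weight
    return PWM("sharp", freqs)


def oracle_scores(freqs, seq):
    """Literal evaluation of the information-weighted similarity sums."""
    info = []
    for row in freqs:
        info.append(sum(f * math.log(4 * f) if f > 0 else 0.0 for f in row))
    current = sum(
        info[i] * freqs[i][BASES.index(base)] for i, base in enumerate(seq)
    )
    lo = sum(info[i] * min(row) for i, row in enumerate(freqs))
    hi = sum(info[i] * max(row) for i, row in enumerate(freqs))
    return (current - lo) / (hi - lo)


class TestLoading:
    def test_jaspar_counts_normalize_per_position(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT)
        pwm = load_pwm(path, "jaspar")
        assert pwm.length == 6
        np.testing.assert_allclose(pwm.freqs.sum(axis=1), 1.0)
        assert pwm.freqs[1, 1] == 1.0  # the all-C column

    def test_transfac_dialect(self, tmp_path):
        path = tmp_path / "m.transfac"
        path.write_text(TRANSFAC_TEXT)
        pwm = load_pwm(path, "transfac")
        assert pwm.matrix_id == "M00001"
        assert pwm.length == 6
        np.testing.assert_allclose(pwm.freqs.sum(axis=1), 1.0)

    def test_uniform_positions_carry_zero_information(self):
        pwm = PWM("uniform-ish", np.array([[0.25] * 4] * 4 + [[1, 0, 0, 0]]))
        np.testing.assert_allclose(pwm.info[:4], 0.0, atol=1e-12)

    def test_single_base_column_information_is_ln4(self):
        pwm = PWM("hard", np.eye(4)[[0, 1, 2, 3, 0]])
        np.testing.assert_allclose(pwm.info, math.log(4))

    def test_short_matrix_rejected(self):
        with pytest.raises(ValidationError):
            PWM("short", np.full((4, 4), 0.25))

    def test_core_is_leftmost_maximal_window(self):
        # positions 0-4 and 1-5 tie in summed information -> leftmost wins
        freqs = np.vstack([np.eye(4)[[0, 1, 2, 3, 0, 1]]])
        pwm = PWM("tie", freqs)
        assert pwm.core_start == 0


class TestSimilarity:
    def test_consensus_scores_one_anticonsensus_zero(self):
        pwm = sharp_pwm()
        assert matrix_similarity(pwm, pwm.consensus) == pytest.approx(1.0)
        anti = "".join(BASES[int(np.argmin(col))] for col in pwm.freqs)
        assert matrix_similarity(pwm, anti) == pytest.approx(0.0)
        assert core_similarity(pwm, pwm.consensus) == pytest.approx(1.0)

    def test_mixed_sequence_matches_literal_oracle(self):
        freqs = np.array(
            [
                [0.6, 0.2, 0.1, 0.1],
                [0.1, 0.7, 0.1, 0.1],
                [0.25, 0.25, 0.25, 0.25],
                [0.1, 0.1, 0.1, 0.7],
                [0.4, 0.3, 0.2, 0.1],
            ]
        )
        pwm = PWM("toy5", freqs)
        for seq in ("ACGTA", "TGCAT", "AAGTA", "CCATG"):
            assert matrix_similarity(pwm, seq) == pytest.approx(
                oracle_scores(freqs.tolist(), seq), abs=1e-12
            )
            core = freqs[pwm.core_start : pwm.core_start + 5]
            assert core_similarity(pwm, seq) == pytest.approx(
                oracle_scores(core.tolist(), seq), abs=1e-12
            )

    def test_core_and_full_scores_decouple(self):
        # consensus outside the core, anti-consensus at the core
        pwm = sharp_pwm("AACGTAA")  # core = 5 sharp positions, leftmost
        core = pwm.core_positions
        seq = list(pwm.consensus)
        for i in core:
            seq[i] = BASES[int(np.argmin(pwm.freqs[i]))]
        seq = "".join(seq)
        assert core_similarity(pwm, seq) == pytest.approx(0.0)
        assert matrix_similarity(pwm, seq) > 0.0

    def test_ambiguous_base_rejected_at_single_call_level(self):
        pwm = sharp_pwm()
        with pytest.raises(ValidationError):
            matrix_similarity(pwm, "ACGGNT")

    def test_degenerate_uniform_matrix_rejected(self):
        pwm = PWM("flat", np.full((5, 4), 0.25))
        with pytest.raises(ValidationError):
            matrix_similarity(pwm, "ACGTA")

    @given(st.text(alphabet=BASES, min_size=6, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_scores_bounded_in_unit_interval(self, seq):
        pwm = sharp_pwm()
        assert 0.0 <= matrix_similarity(pwm, seq) <= 1.0
        assert 0.0 <= core_similarity(pwm, seq) <= 1.0


def oracle_scan(pwm, seq, css_cut, mss_cut):
    """Score every window on both strands with the literal sums."""
    freqs = pwm.freqs.tolist()
    core = pwm.freqs[pwm.core_start : pwm.core_start + 5].tolist()
    L = pwm.length
    hits = []
    for strand, s in ((+1, seq), (-1, revcomp(seq))):
        for i in range(len(s) - L + 1):
            window = s[i : i + L]
            if "N" in window:
                continue
            css = oracle_scores(core, window[pwm.core_start : pwm.core_start + 5])
            mss = oracle_scores(freqs, window)
            if css >= css_cut and mss >= mss_cut:
                pos = i + 1 if strand == +1 else len(seq) - i - L + 1
                hits.append((pos, strand, round(mss, 9), round(css, 9)))
    return sorted(hits)


class TestScanning:
    def test_planted_consensus_found_once(self):
        pwm = sharp_pwm("ACGGATTC")
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("AC"), 60)) + pwm.consensus + "".join(
            rng.choice(list("AC"), 40)
        )
        pwm = PWM("sharp", pwm.freqs, css_cutoff=0.99, mss_cutoff=0.99)
        hits = scan_sequence(pwm, seq)
        plus = [h for h in hits if h.strand == +1]
        assert len(plus) == 1
        assert plus[0].position == 61
        assert plus[0].matched_sequence == pwm.consensus

    def test_reverse_complement_reports_mirrored_minus_hit(self):
        pwm = PWM("sharp", sharp_pwm("ACGGATTC").freqs, css_cutoff=0.99, mss_cutoff=0.99)
        seq = "AATTCGAA" + pwm.consensus + "GGCCTTAA"
        [fwd] = [h for h in scan_sequence(pwm, seq) if h.mss > 0.99]
        rc_hits = [h for h in scan_sequence(pwm, revcomp(seq)) if h.mss > 0.99]
        assert len(rc_hits) == 1
        assert rc_hits[0].strand == -fwd.strand
        assert rc_hits[0].position == len(seq) - (fwd.position + pwm.length - 1) + 1

    def test_windows_containing_n_are_skipped(self):
        pwm = PWM("sharp", sharp_pwm("ACGGATTC").freqs, css_cutoff=0.0, mss_cutoff=0.0)
        seq = "ACGGNTTC" * 3
        assert all("N" not in h.matched_sequence for h in scan_sequence(pwm, seq))

    def test_raising_cutoffs_never_adds_hits(self, rng):
        base = sharp_pwm("ACGGAT", weight=0.7)
        seq = "".join(rng.choice(list(BASES), 500))
        loose = scan_sequence(PWM("m", base.freqs, css_cutoff=0.5, mss_cutoff=0.5), seq)
        tight = scan_sequence(PWM("m", base.freqs, css_cutoff=0.7, mss_cutoff=0.7), seq)
        loose_keys = {(h.position, h.strand) for h in loose}
        assert {(h.position, h.strand) for h in tight} <= loose_keys

    def test_scan_matches_exhaustive_window_oracle(self, rng):
        base = sharp_pwm("ACGGATAC", weight=0.6)
        for trial in range(15):
            seq = "".join(rng.choice(list(BASES + "N"), 300, p=[0.24] * 4 + [0.04]))
            pwm = PWM("m", base.freqs, css_cutoff=0.8, mss_cutoff=0.75)
            got = sorted(
                (h.position, h.strand, round(h.mss, 9), round(h.css, 9))
                for h in scan_sequence(pwm, seq)
            )
            assert got == oracle_scan(pwm, seq, 0.8, 0.75)


def test_load_pwms_returns_every_matrix(tmp_path):
    path = tmp_path / "multi.jaspar"
    path.write_text(JASPAR_TEXT + "\n" + JASPAR_TEXT.replace("MA0001.1", "MA0002.1"))
    assert len(load_pwms(path, "jaspar")) == 2
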
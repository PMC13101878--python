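"""PWM scanning, per-motif statistics, York regression, family enrichment."""

import numpy as np
import pandas as pd
import pytest

from evostrat.motifs import (
    PWM,
    MotifScanError,
    family_enrichment,
    motif_language_stat,
    motif_selection_stat,
    read_jaspar,
    scan_delta,
    york_regression,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def _rc(seq):
    return seq.translate(REVCOMP)[::-1]


def _random_pwm(rng, length):
    counts = rng.integers(1, 50, size=(length, 4)).astype(float)
    return PWM("mX", "MX", counts / counts.sum(axis=1, keepdims=True))


class TestPWMParsing:
    def test_jaspar_roundtrip(self, tmp_path):
        p = tmp_path / "motifs.pfm"
        p.write_text(
            ">MA0001.1 TEST1\n"
            "A [ 10  0  5 ]\n"
            "C [  0 10  5 ]\n"
            "G [  0  0  5 ]\n"
            "T [  0  0  5 ]\n"
            ">MA0002.1 TEST2\n"
            "A 1 1\nC 1 1\nG 1 1\nT 1 1\n"
        )
        pwms = read_jaspar(p, families={"MA0001.1": "Homeobox"})
        assert [m.motif_id for m in pwms] == ["MA0001.1", "MA0002.1"]
        assert pwms[0].family == "Homeobox"
        assert np.allclose(pwms[0].probs.sum(axis=1), 1.0)
        assert pwms[0].probs[0, 0] == pytest.approx(1.0, abs=1e-3)
        assert len(pwms[1]) == 2

    def test_pwm_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            PWM("m", "m", np.array([[0.5, 0.5, 0.5, 0.5]]))
        with pytest.raises(ValueError, match="positive"):
            PWM("m", "m", np.array([[1.0, 0.0, 0.0, 0.0]]))


class TestScanDelta:
    def test_identical_contexts_zero(self):
        pwm = _random_pwm(np.random.default_rng(0), 4)
        assert scan_delta("ACGTACGTA", "ACGTACGTA", pwm) == 0.0

    def test_uniform_pwm_zero(self):
        pwm = PWM("u", "u", np.full((3, 4), 0.25))
        assert scan_delta("AACGTTA", "AATGTTA", pwm) == pytest.approx(0.0)

    def test_hand_logodds_single_window(self):
        probs = np.array([[0.9, 1 / 30, 1 / 30, 1 / 30], [0.9, 1 / 30, 1 / 30, 1 / 30]])
        pwm = PWM("m", "m", probs)
        # length-2 contexts, variant at index 1: exactly one forward window,
        # and the reverse strand scores lower for both alleles
        delta = scan_delta("AA", "AC", pwm)
        expected = np.log2((1 / 30) / 0.25) - np.log2(0.9 / 0.25)
        assert delta == pytest.approx(expected)

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(1)
        pwm = _random_pwm(rng, 5)
        bases = np.array(list("ACGT"))
        for rep in range(10):
            ctx = "".join(rng.choice(bases, size=11))
            alt_base = rng.choice([b for b in "ACGT" if b != ctx[5]])
            alt = ctx[:5] + alt_base + ctx[6:]
            d_fwd = scan_delta(ctx, alt, pwm)
            d_rc = scan_delta(_rc(ctx), _rc(alt), pwm)
            assert d_fwd == pytest.approx(d_rc, abs=1e-12)

    def test_n_windows_skipped_and_errors(self):
        pwm = _random_pwm(np.random.default_rng(2), 3)
        # N near the edge: windows containing it are skipped, others remain
        d = scan_delta("NACGTAC", "NACTTAC", pwm)
        assert np.isfinite(d)
        with pytest.raises(MotifScanError, match="non-ACGTN"):
            scan_delta("ACXGT", "ACGGT", pwm)
        with pytest.raises(MotifScanError, match="shorter"):
            scan_delta("AC", "AG", _random_pwm(np.random.default_rng(3), 5))
        with pytest.raises(MotifScanError, match="equal length"):
            scan_delta("ACGT", "ACG", pwm)


class TestMotifStats:
    def test_selection_stat_hand_means(self):
        rng = np.random.default_rng(4)
        rev = np.full(20, -1.0) + rng.normal(0, 1e-6, 20)
        other = rng.normal(0, 1e-6, 20)
        x, se, p = motif_selection_stat(rev, other)
        assert x == pytest.approx(1.0, abs=1e-4)
        assert se > 0 and p < 1e-10

    def test_selection_stat_antisymmetry_and_null(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=50), rng.normal(size=50)
        x1, _, _ = motif_selection_stat(a, b)
        x2, _, _ = motif_selection_stat(b, a)
        assert x1 == pytest.approx(-x2)
        x_eq, _, _ = motif_selection_stat(a, a)
        assert x_eq == pytest.approx(0.0)

    def test_language_stat_perfect_and_errors(self):
        rng = np.random.default_rng(6)
        burden = rng.normal(size=100)
        y, se, p = motif_language_stat(burden, burden)
        assert y == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-8)
        with pytest.raises(ValueError):
            motif_language_stat([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            motif_language_stat(np.ones(10), rng.normal(size=10))

    def test_language_stat_null_centered(self):
        rng = np.random.default_rng(7)
        ys = [
            motif_language_stat(rng.normal(size=200), rng.normal(size=200))[0]
            for _ in range(100)
        ]
        assert abs(np.mean(ys)) < 0.03


class TestYorkRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = york_regression(x, 2 * x + 1, np.full(5, 0.2), np.full(5, 0.3))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_wls_limit_to_six_digits(self):
        rng = np.random.default_rng(8)
        for rep in range(5):
            x = rng.normal(size=25)
            sy = rng.uniform(0.2, 0.6, size=25)
            y = 1.3 * x - 0.4 + rng.normal(size=25) * sy
            fit = york_regression(x, y, np.full(25, 1e-9), sy)
            w = 1.0 / sy**2
            # weighted least squares closed form
            sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
            b_wls = ((w * x * y).sum() - swx * swy / sw) / ((w * x * x).sum() - swx**2 / sw)
            assert fit.slope == pytest.approx(b_wls, rel=1e-6)

    def test_equal_error_swap_symmetry(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = 0.8 * x + rng.normal(size=30) * 0.5
        s = np.full(30, 0.4)
        b_xy = york_regression(x, y, s, s).slope
        b_yx = york_regression(y, x, s, s).slope
        assert b_xy == pytest.approx(1.0 / b_yx, rel=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="positive"):
            york_regression([0, 1, 2], [0, 1, 2], [0.1, 0.0, 0.1], [1, 1, 1])
        with pytest.raises(ValueError, match="3 points"):
            york_regression([0, 1], [0, 1], [0.1, 0.1], [0.1, 0.1])


class TestFamilyEnrichment:
    def _points(self, families, conc):
        n = len(families)
        return pd.DataFrame(
            {
                "motif_id": [f"m{i}" for i in range(n)],
                "family": families,
                "x": np.where(conc, 1.0, -1.0),
                "p_x": np.where(conc, 0.01, 0.5),
                "y": np.where(conc, 1.0, -1.0),
                "p_y": np.where(conc, 0.01, 0.5),
            }
        )

    def test_haldane_corrected_table(self):
        pts = self._points(["F"] * 10 + ["G"] * 30, [True] * 10 + [False] * 30)
        out = family_enrichment(pts).set_index("family")
        assert out.loc["F", "odds_ratio"] == pytest.approx(1281.0)
        assert out.loc["F", "log2_or"] == pytest.approx(np.log2(1281.0))

    def test_uncorrected_hand_table(self):
        # family F: 10 concordant, 5 not; elsewhere: 2 concordant, 20 not
        fams = ["F"] * 15 + ["G"] * 22
        conc = [True] * 10 + [False] * 5 + [True] * 2 + [False] * 20
        out = family_enrichment(self._points(fams, conc)).set_index("family")
        assert out.loc["F", "odds_ratio"] == pytest.approx(20.0)

    def test_null_log2or_centered(self):
        rng = np.random.default_rng(10)
        vals = []
        for rep in range(100):
            fams = rng.choice(["F", "G", "H"], size=60)
            conc = rng.random(60) < 0.3
            out = family_enrichment(self._points(fams, conc))
            vals.extend(out["log2_or"])
        assert abs(np.mean(vals)) < 0.3

    def test_requires_two_families(self):
        with pytest.raises(ValueError):
            family_enrichment(self._points(["F"] * 10, [True] * 10))


class TestEndToEndRecovery:
    def test_york_slope_positive_when_selection_drives_language(self):
        # desk-scale emulation: 50 motifs, 500 individuals; motifs whose
        # binding was gained in hominins (reversions destroy it) also carry
        # phenotype signal, so the York slope across motifs is positive
        rng = np.random.default_rng(11)
        n_motifs, n_ind, detected = 50, 500, 0
        for rep in range(100):
            gains = rng.uniform(0.0, 1.0, size=n_motifs)
            xs, sxs, ys, sys_ = [], [], [], []
            phen_signal = np.zeros(n_ind)
            burdens = rng.normal(size=(n_ind, n_motifs))
            weights = 0.08 * gains
            phenotype = burdens @ weights + rng.normal(size=n_ind)
            for m in range(n_motifs):
                d_rev = -gains[m] + rng.normal(0, 0.5, size=30)
                d_other = rng.normal(0, 0.5, size=60)
                x, sx, _ = motif_selection_stat(d_rev, d_other)
                y, sy, _ = motif_language_stat(burdens[:, m], phenotype)
                xs.append(x), sxs.append(sx), ys.append(y), sys_.append(max(sy, 1e-6))
            fit = york_regression(xs, ys, sxs, sys_)
            detected += (fit.slope > 0) and (fit.p < 0.05)
        assert detected / 100 >= 0.90
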
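"""Repeatability statistics: drift correction, wCV, ICC, bias, T2 rescaling."""

import numpy as np
import pandas as pd
import pytest

from fcivim.model import AcquisitionPoint, AcquisitionScheme
from fcivim.repeatability import (
    ROISeries,
    drift_correct,
    icc_a_k,
    protocol_bias,
    t2_adjust_f,
    wcv,
    wcv_table,
)


def _series(signals, times, n=10):
    pts = [AcquisitionPoint(0.0, 100.0, 0)] * n
    sch = AcquisitionScheme(pts)
    return ROISeries("s1", "liver", "s1a", signals, times, sch)


class TestDriftCorrect:
    def test_zero_slope_unchanged(self):
        t = np.arange(10) * 20.0
        s = np.full(10, 100.0)
        series = _series(s, t)
        out, fit = drift_correct(series)
        assert not fit.corrected
        assert np.array_equal(out.signals, s)

    def test_noiseless_linear_drift_removed_exactly(self):
        t = np.arange(10) * 60.0
        s = 100.0 * (1.0 - 1e-4 * t)
        out, fit = drift_correct(_series(s, t))
        assert fit.corrected
        assert fit.p_value < 0.05
        assert np.allclose(out.signals, out.signals[0], rtol=1e-6)
        # re-test: corrected series shows no significant slope
        _, refit = drift_correct(out)
        assert not refit.corrected

    def test_insignificant_slope_left_alone(self):
        rng = np.random.default_rng(0)
        t = np.arange(10) * 60.0
        s = 100.0 + rng.normal(0, 5.0, 10)  # pure noise
        out, fit = drift_correct(_series(s, t), alpha=0.05)
        if fit.p_value >= 0.05:  # the expected branch for pure noise
            assert np.array_equal(out.signals, s)
        # tighter alpha never corrects this draw
        out2, fit2 = drift_correct(_series(s, t), alpha=1e-12)
        assert not fit2.corrected

    def test_degenerate_times_rejected(self):
        with pytest.raises(ValueError):
            drift_correct(_series(np.ones(10), np.zeros(10)))

    def test_too_few_b0_rejected(self):
        pts = [AcquisitionPoint(0.0, 100.0, 0)] * 2 + [AcquisitionPoint(100.0, 100.0, 0)] * 8
        sch = AcquisitionScheme(pts)
        series = ROISeries("s", "o", "x", np.ones(10), np.arange(10.0), sch)
        with pytest.raises(ValueError, match=">= 3"):
            drift_correct(series)


class TestWcv:
    def test_identical_repeats_zero(self):
        assert wcv([[5.0, 5.0], [9.0, 9.0], [2.0, 2.0]]) == 0.0

    def test_hand_computed_example(self):
        # subjects {(10,12), (20,22)}: sd = sqrt(2), cv = {0.12857, 0.06734},
        # RMS of the cv's = 10.26%
        expected = 100 * np.sqrt(((np.sqrt(2) / 11) ** 2 + (np.sqrt(2) / 21) ** 2) / 2)
        assert wcv([[10.0, 12.0], [20.0, 22.0]]) == pytest.approx(expected, abs=1e-9)
        assert round(expected, 2) == 10.26

    def test_scale_invariance(self):
        a = wcv([[10.0, 12.0], [20.0, 22.0]])
        b = wcv([[70.0, 84.0], [140.0, 154.0]])
        assert a == pytest.approx(b)

    def test_pooled_estimator_available(self):
        v = wcv([[10.0, 12.0], [20.0, 22.0]], method="pooled")
        assert 0 < v < 20
        with pytest.raises(ValueError):
            wcv([[10.0, 12.0], [20.0, 22.0]], method="geometric")

    def test_preconditions(self):
        with pytest.raises(ValueError):
            wcv([[1.0, 2.0]])  # one subject
        with pytest.raises(ValueError):
            wcv([[1.0], [2.0]])  # one measurement
        with pytest.raises(ValueError):
            wcv([[1.0, -1.0], [2.0, 3.0]])  # zero mean


class TestIcc:
    def test_perfect_agreement(self):
        m = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        res = icc_a_k(m)
        assert res.icc == pytest.approx(1.0)
        assert res.reliability == "good"

    def test_matches_published_anova_formula_via_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        m = np.array([[9.0, 10.0], [7.5, 8.1], [6.0, 6.6], [5.1, 4.9]])
        res = icc_a_k(m)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(4), 2),
                "rater": np.tile(["a", "b"], 4),
                "score": m.ravel(),
            }
        )
        icc_df = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        icc2k = icc_df.loc[icc_df["Type"].isin(["ICC2k", "ICC(A,k)"]), "ICC"].iloc[0]
        assert res.icc == pytest.approx(icc2k, abs=1e-6)

    def test_negative_icc_flagged_na(self):
        # within-subject variability dominates the between-subject spread
        m = np.array([[3.0, 5.0], [4.9, 3.1], [4.0, 6.1], [6.0, 4.1]])
        res = icc_a_k(m)
        assert res.icc < 0
        assert res.reliability == "n.a."

    def test_pathological_denominator_flagged_na(self):
        m = np.array([[10.0, -10.0], [-9.0, 9.5], [8.0, -8.5], [-10.0, 10.5]])
        assert icc_a_k(m).reliability == "n.a."

    def test_recovers_analytic_icc_from_variance_components(self):
        """Two-way model with known variances: mean estimate near analytic ICC."""
        rng = np.random.default_rng(4)
        n, k = 30, 3
        s_r, s_c, s_e = 2.0, 0.5, 1.0
        analytic = s_r**2 / (s_r**2 + (s_c**2 + s_e**2) / k)
        est = []
        for _ in range(200):
            r = rng.normal(0, s_r, (n, 1))
            c = rng.normal(0, s_c, (1, k))
            e = rng.normal(0, s_e, (n, k))
            est.append(icc_a_k(r + c + e).icc)
        assert np.mean(est) == pytest.approx(analytic, abs=0.03)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            icc_a_k(np.ones((2, 2)))  # too few subjects
        m = np.ones((4, 2))
        m[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc_a_k(m)


class TestProtocolBias:
    def test_zero_when_equal(self):
        assert protocol_bias([2.0, 3.0], [2.0, 3.0]) == 0.0

    def test_sign_convention(self):
        assert protocol_bias([2.0], [1.8]) == pytest.approx(+10.0)
        assert protocol_bias([2.0], [2.2]) == pytest.approx(-10.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            protocol_bias([0.0, 1.0], [1.0, 1.0])


class TestT2AdjustF:
    def test_identity_cases(self):
        assert t2_adjust_f(0.3, 80.0, 80.0, 46.0, 181.0) == pytest.approx(0.3)
        assert t2_adjust_f(0.3, 122.0, 50.0, 90.0, 90.0) == pytest.approx(0.3)

    def test_liver_echo_time_rescaling(self):
        """45.0% at TE 122 ms maps to 20.3% at TE 50 ms for T2 46/181 ms."""
        f = t2_adjust_f(0.450, 122.0, 50.0, 46.0, 181.0)
        assert round(100 * f, 1) == 20.3

    def test_preconditions(self):
        with pytest.raises(ValueError):
            t2_adjust_f(0.0, 122.0, 50.0, 46.0, 181.0)
        with pytest.raises(ValueError):
            t2_adjust_f(0.5, -1.0, 50.0, 46.0, 181.0)


def test_wcv_table_groups_by_organ():
    rows = []
    for organ, base in (("liver", 10.0), ("spleen", 20.0)):
        for subject, off in (("s1", 0.0), ("s2", 10.0)):
            for occ, jit in (("s1a", 0.0), ("s2", 2.0)):
                rows.append(
                    dict(subject=subject, organ=organ, occasion=occ,
                         D=base + off + jit, f_pct=1.0, tau_ms=1.0, v_mm_s=1.0)
                )
    df = pd.DataFrame(rows)
    out = wcv_table(df, occasions=("s1a", "s2"))
    assert set(out.index) == {"liver", "spleen"}
    expected_liver = wcv([[10.0, 12.0], [20.0, 22.0]])
    assert out.loc["liver", "D"] == pytest.approx(expected_liver)
    assert out.loc["liver", "f_pct"] == 0.0


class TestAlgebraicProperties:
    """Property-based checks of the pure-arithmetic statistics."""

    def test_t2_adjustment_round_trips_and_preserves_range(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=200, deadline=None, derandomize=True)
        @given(
            f=st.floats(0.01, 0.99),
            te_a=st.floats(20.0, 200.0),
            te_b=st.floats(20.0, 200.0),
            t2_t=st.floats(20.0, 120.0),
            t2_b=st.floats(80.0, 300.0),
        )
        def check(f, te_a, te_b, t2_t, t2_b):
            g = t2_adjust_f(f, te_a, te_b, t2_t, t2_b)
            assert 0.0 < g < 1.0
            back = t2_adjust_f(g, te_b, te_a, t2_t, t2_b)
            assert back == pytest.approx(f, rel=1e-9)
            # shorter target TE with t2_tissue < t2_blood lowers f
            if te_b < te_a and t2_t < t2_b:
                assert g < f

        check()

    def test_wcv_scale_invariance_property(self):
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=100, deadline=None, derandomize=True)
        @given(
            rows=st.lists(
                st.lists(st.floats(1.0, 100.0), min_size=2, max_size=4),
                min_size=2, max_size=6,
            ),
            scale=st.floats(0.1, 50.0),
        )
        def check(rows, scale):
            a = wcv(rows)
            b = wcv([[x * scale for x in r] for r in rows])
            assert b == pytest.approx(a, rel=1e-9)

        check()
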
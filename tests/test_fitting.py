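"""Constrained FC-IVIM estimation: normalization, initialization, recovery."""

import numpy as np
import pytest

from fcivim.fitting import (
    ErrorNorms,
    FcIvim,
    FitBounds,
    fit_fc_ivim,
    init_high_b,
    normalize_curve,
    normalized_errors,
)
from fcivim.model import (
    AcquisitionPoint,
    AcquisitionScheme,
    SignalCurve,
    TissueParams,
    forward_signal,
)


def _curve(scheme, values):
    return SignalCurve(np.asarray(values, float), scheme)


@pytest.fixture(scope="module")
def small_scheme():
    pts = [AcquisitionPoint(0.0, 100.0, 0), AcquisitionPoint(0.0, 100.0, 1)] + [
        AcquisitionPoint(float(b), 100.0, 0) for b in (50, 150, 300, 500)
    ] + [AcquisitionPoint(float(b), 100.0, 1) for b in (60, 100, 150)]
    return AcquisitionScheme(pts)


class TestNormalize:
    def test_mean_b0_scaled_to_one(self, small_scheme):
        vals = np.concatenate([[90.0, 110.0], np.full(7, 50.0)])
        out = normalize_curve(_curve(small_scheme, vals))
        assert out.normalized
        assert out.values[:2].mean() == pytest.approx(1.0)
        assert np.allclose(out.values, vals / 100.0)  # scale factor 1/mean

    def test_halves_when_b0_is_two(self, small_scheme):
        vals = np.concatenate([[2.0, 2.0], np.full(7, 1.2)])
        out = normalize_curve(_curve(small_scheme, vals))
        assert np.allclose(out.values, vals / 2.0)

    def test_idempotent(self, small_scheme):
        vals = np.concatenate([[1.0, 1.0], np.full(7, 0.5)])
        once = normalize_curve(_curve(small_scheme, vals))
        twice = normalize_curve(once)
        assert np.array_equal(once.values, twice.values)

    def test_rejects_nonpositive_reference_signal(self, small_scheme):
        vals = np.concatenate([[0.0, 0.0], np.full(7, 0.5)])
        with pytest.raises(ValueError, match="positive"):
            normalize_curve(_curve(small_scheme, vals))


class TestInitHighB:
    def test_recovers_d_and_f_in_monoexponential_regime(self, tables):
        # fast pseudo-diffusion (tau=20 ms, v=10 mm/s => D* ~ 0.33 mm^2/s)
        # suppresses the perfusion compartment at b >= 150 entirely
        pts = [AcquisitionPoint(0.0, 100.0, 0)] + [
            AcquisitionPoint(float(b), 100.0, 0) for b in (150, 250, 400, 600)
        ]
        sch = AcquisitionScheme(pts)
        truth = TissueParams(D=1.5e-3, f=0.2, tau=20.0, v=10.0)
        curve = forward_signal(sch, truth, tables=tables)
        D0, f0 = init_high_b(normalize_curve(curve))
        assert D0 == pytest.approx(1.5e-3, rel=0.02)
        assert f0 == pytest.approx(0.2, abs=0.02)

    def test_pure_monoexponential_gives_zero_f(self, tables):
        pts = [AcquisitionPoint(0.0, 100.0, 0)] + [
            AcquisitionPoint(float(b), 100.0, 0) for b in (150, 250, 400, 600)
        ]
        sch = AcquisitionScheme(pts)
        curve = forward_signal(sch, TissueParams(D=1e-3, f=0.0, tau=100.0, v=4.0), tables=tables)
        D0, f0 = init_high_b(normalize_curve(curve))
        assert abs(f0) < 1e-9
        assert D0 == pytest.approx(1e-3, rel=1e-6)

    def test_fc_only_curve_rejected(self, tables):
        pts = [AcquisitionPoint(0.0, 100.0, 1)] + [
            AcquisitionPoint(float(b), 100.0, 1) for b in (60, 100, 150, 200)
        ]
        sch = AcquisitionScheme(pts)
        curve = forward_signal(sch, TissueParams(D=1e-3, f=0.2, tau=100.0, v=4.0), tables=tables)
        with pytest.raises(ValueError, match="bipolar"):
            init_high_b(normalize_curve(curve))


class TestFit:
    def test_noiseless_recovery_on_rich_scheme(self, noiseless_curve, tables, interior_truth):
        res = fit_fc_ivim(noiseless_curve, bounds=FitBounds.default(), tables=tables)
        assert res.converged
        t = interior_truth
        assert res.params.D == pytest.approx(t.D, rel=0.01)
        assert res.params.f == pytest.approx(t.f, rel=0.01)
        assert res.params.tau == pytest.approx(t.tau, rel=0.05)
        assert res.params.v == pytest.approx(t.v, rel=0.05)

    def test_recovery_median_error_below_one_percent(self, rich_scheme, tables):
        """Noiseless self-consistency over random interior truths."""
        rng = np.random.default_rng(0)
        errD, errf = [], []
        for _ in range(60):
            truth = TissueParams(
                D=rng.uniform(0.7e-3, 2.8e-3),
                f=rng.uniform(0.05, 0.55),
                tau=rng.uniform(30.0, 450.0),
                v=rng.uniform(0.5, 14.0),
            )
            curve = forward_signal(rich_scheme, truth, tables=tables)
            res = fit_fc_ivim(curve, bounds=FitBounds.default(), tables=tables)
            e = normalized_errors(res.params, truth, ErrorNorms.from_truth(truth))
            errD.append(abs(e["D"]))
            errf.append(abs(e["f"]))
        assert np.median(errD) < 1.0
        assert np.median(errf) < 1.0

    def test_broad_bounds_leave_interior_recovery_unchanged(
        self, noiseless_curve, tables, interior_truth
    ):
        res = fit_fc_ivim(noiseless_curve, bounds=FitBounds.broad(), tables=tables)
        assert res.params.D == pytest.approx(interior_truth.D, rel=0.01)
        assert res.params.f == pytest.approx(interior_truth.f, rel=0.01)

    def test_estimates_respect_bounds_under_noise(self, rich_scheme, tables):
        from fcivim.design import add_rician

        rng = np.random.default_rng(1)
        bounds = FitBounds.default()
        lo, hi = bounds.lower(), bounds.upper()
        for i in range(60):
            truth = TissueParams(
                D=rng.uniform(*bounds.D), f=rng.uniform(0.02, 0.58),
                tau=rng.uniform(*bounds.tau), v=rng.uniform(*bounds.v),
            )
            clean = forward_signal(rich_scheme, truth, tables=tables)
            noisy = add_rician(clean, 15.0, 6, rng)
            res = fit_fc_ivim(noisy, bounds=bounds, tables=tables)
            assert np.all(res.x >= lo - 1e-12) and np.all(res.x <= hi + 1e-12)

    def test_spleen_bounds_confine_d(self, rich_scheme, tables):
        from fcivim.design import add_rician

        rng = np.random.default_rng(2)
        bounds = FitBounds.for_organ("spleen")
        truth = TissueParams(D=0.9e-3, f=0.09, tau=150.0, v=6.0)
        for _ in range(15):
            noisy = add_rician(forward_signal(rich_scheme, truth, tables=tables), 12.0, 6, rng)
            res = fit_fc_ivim(noisy, bounds=bounds, tables=tables)
            assert 0.5e-3 - 1e-12 <= res.params.D <= 1.5e-3 + 1e-12

    def test_fit_invariant_to_curve_scaling(self, rich_scheme, tables, interior_truth):
        truth7 = TissueParams(
            D=interior_truth.D, f=interior_truth.f, tau=interior_truth.tau,
            v=interior_truth.v, S0=7.0,
        )
        curve = forward_signal(rich_scheme, truth7, tables=tables)
        res = fit_fc_ivim(curve, bounds=FitBounds.default(), tables=tables)
        assert res.params.D == pytest.approx(interior_truth.D, rel=0.01)
        assert res.params.S0 == pytest.approx(1.0, rel=0.01)  # scale absorbed

    def test_degenerate_scheme_rejected(self, tables):
        pts = [AcquisitionPoint(0.0, 100.0, 0)] * 3 + [AcquisitionPoint(100.0, 100.0, 0)] * 3
        sch = AcquisitionScheme(pts)
        curve = SignalCurve(np.ones(6), sch)
        with pytest.raises(ValueError, match="distinct"):
            FcIvim(curve, tables=tables)

    def test_jacobian_matches_finite_differences(self, noiseless_curve, tables):
        m = FcIvim(noiseless_curve, bounds=FitBounds.default(), tables=tables)
        x = np.array([0.97, 1.3e-3, 0.31, 220.0, 6.5])
        J = m._jacobian(x)
        for j in range(5):
            h = np.zeros(5)
            h[j] = 1e-6 * max(abs(x[j]), 1e-3)
            num = (m.predict(x + h) - m.predict(x - h)) / (2 * h[j])
            assert np.allclose(J[:, j], num, rtol=2e-3, atol=1e-8), f"param {j}"

    def test_results_summary_and_uncertainty(self, noiseless_curve, tables):
        res = fit_fc_ivim(noiseless_curve, bounds=FitBounds.default(), tables=tables)
        s = res.summary()
        for name in ("S0", "D", "f", "tau", "v", "converged"):
            assert name in s
        assert res.bse.shape == (5,)
        assert res.residual_norm < 1e-6  # noiseless
        row = res.to_row("x")
        assert row["f_pct"] == pytest.approx(100 * res.params.f)

    def test_from_dataframe_constructor(self, noiseless_curve, tables):
        df = noiseless_curve.to_frame()
        m = FcIvim.from_dataframe(df, tables=tables)
        res = m.fit()
        assert res.converged


class TestNormalizedErrors:
    def test_zero_when_fit_equals_truth(self):
        t = TissueParams(D=1.5e-3, f=0.25, tau=260.0, v=5.5)
        e = normalized_errors(t, t, ErrorNorms())
        assert all(v == 0.0 for v in e.values())

    def test_sign_convention_truth_minus_fit(self):
        truth = TissueParams(D=1.5e-3, f=0.25, tau=260.0, v=5.5)
        fit = TissueParams(D=1.65e-3, f=0.25, tau=234.0, v=5.5)
        e = normalized_errors(fit, truth, ErrorNorms(D=1.5e-3, tau=260.0))
        assert e["D"] == pytest.approx(-10.0)
        assert e["tau"] == pytest.approx(+10.0)

    def test_norms_validated(self):
        with pytest.raises(ValueError):
            ErrorNorms(D=-1.0)


def test_bounds_presets():
    assert FitBounds.for_organ("spleen").tau == (50.0, 300.0)
    assert FitBounds.for_organ("left_kidney").v == (3.0, 15.0)
    with pytest.raises(KeyError):
        FitBounds.for_organ("brain")
    with pytest.raises(ValueError):
        FitBounds(D=(2e-3, 1e-3))
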
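import numpy as np
import pytest

import nrdecomp as nd
from nrdecomp import fitting
from nrdecomp.membrane_model import Parameter, ParameterSet
from nrdecomp.reflect_kernel import ReflectivityCurve, ResolutionSpec, Slab, abeles_reflectivity, smear


class SlabModel:
    """Minimal fittable model: one film on silicon, per-contrast backing."""

    def __init__(self, thickness=50.0, sld=4.0e-6, backing=None, resolution=None):
        self.backing = backing or {"d2o": 6.36e-6, "h2o": -0.56e-6}
        self.resolution = resolution or ResolutionSpec(0.05)
        self.parameters = ParameterSet(
            [
                Parameter("thickness", thickness, 10.0, 120.0),
                Parameter("sld", sld, 1.0e-6, 7.0e-6),
            ]
        )

    def model_r(self, contrast, q):
        stack = [
            Slab(0, 2.07e-6),
            Slab(self.parameters.value("thickness"), self.parameters.value("sld"), 2.0),
            Slab(0, self.backing[contrast], 2.0),
        ]
        return smear(lambda qq: abeles_reflectivity(stack, qq), q, self.resolution)

    def copy(self):
        m = SlabModel(backing=self.backing, resolution=self.resolution)
        m.parameters = self.parameters.copy()
        return m


class LinearModel:
    """y = a * x toy model for Monte-Carlo calibration against the analytic
    standard error of a weighted slope."""

    def __init__(self, slope=2.0):
        self.parameters = ParameterSet([Parameter("slope", slope, 0.0, 10.0, vary=True)])

    def model_r(self, contrast, q):
        return self.parameters.value("slope") * q

    def copy(self):
        m = LinearModel()
        m.parameters = self.parameters.copy()
        return m


def make_curves(model, q, noise=0.0, seed=0):
    """Self-generated data; noise=0 gives exact data with 1% weights."""
    rng = np.random.default_rng(seed)
    out = {}
    for contrast in model.backing if hasattr(model, "backing") else ["x"]:
        r = model.model_r(contrast, q)
        dr = np.maximum((noise if noise > 0 else 0.01) * r, 1e-12)
        if noise > 0:
            r = np.maximum(r + rng.normal(0, dr), 0)
        out[contrast] = ReflectivityCurve(q, r, dr=dr)
    return out


@pytest.fixture(scope="module")
def q():
    return np.geomspace(0.012, 0.3, 90)


class TestObjective:
    def test_zero_for_self_generated_data(self, q):
        model = SlabModel()
        curves = make_curves(model, q)
        assert fitting.objective(model, curves) == pytest.approx(0.0, abs=1e-16)

    def test_single_point_perturbation_adds_one(self, q):
        model = SlabModel()
        curves = make_curves(model, q)
        c = curves["d2o"]
        r2 = c.r.copy()
        r2[40] += c.dr[40]
        curves["d2o"] = ReflectivityCurve(c.q, r2, dr=c.dr)
        assert fitting.objective(model, curves) == pytest.approx(1.0, rel=1e-9)

    def test_additive_over_contrasts(self, q):
        model = SlabModel()
        curves = make_curves(model, q, noise=0.05, seed=3)
        total = fitting.objective(model, curves)
        parts = sum(fitting.objective(model, {k: v}) for k, v in curves.items())
        assert total == pytest.approx(parts, rel=1e-12)

    def test_contrast_order_irrelevant(self, q):
        model = SlabModel()
        curves = make_curves(model, q, noise=0.05, seed=3)
        swapped = dict(reversed(list(curves.items())))
        assert fitting.objective(model, curves) == pytest.approx(
            fitting.objective(model, swapped), rel=1e-15
        )

    def test_missing_dr_is_instructive_error(self, q):
        model = SlabModel()
        curve = ReflectivityCurve(q, model.model_r("d2o", q))
        with pytest.raises(fitting.FitError, match="synthetic"):
            fitting.objective(model, {"d2o": curve})


class TestCoRefine:
    def test_all_fixed_returns_input_model(self, q):
        model = SlabModel()
        curves = make_curves(model, q, noise=0.01, seed=1)
        fit = fitting.co_refine(model, curves, seed=1)
        assert fit.parameters.value("thickness") == 50.0
        assert fit.chi2 > 0

    def test_recovers_thickness_within_one_angstrom(self, q):
        truth = SlabModel(thickness=50.0, sld=4.0e-6)
        curves = make_curves(truth, q, noise=0.01, seed=11)
        model = SlabModel(thickness=70.0, sld=3.0e-6)
        model.parameters["thickness"].vary = True
        model.parameters["sld"].vary = True
        fit = fitting.co_refine(model, curves, seed=2, de_maxiter=80)
        assert fit.parameters.value("thickness") == pytest.approx(50.0, abs=1.0)
        assert fit.parameters.value("sld") == pytest.approx(4.0e-6, rel=0.02)

    def test_deterministic_given_seed(self, q):
        truth = SlabModel()
        curves = make_curves(truth, q, noise=0.02, seed=5)
        model = SlabModel(thickness=60.0)
        model.parameters["thickness"].vary = True
        a = fitting.co_refine(model, curves, seed=9, de_maxiter=20)
        b = fitting.co_refine(model, curves, seed=9, de_maxiter=20)
        assert np.array_equal(a.parameters.free_values(), b.parameters.free_values())

    def test_identity_recovery_from_noise_free_data(self, q):
        truth = SlabModel(thickness=62.0, sld=3.1e-6)
        curves = make_curves(truth, q, noise=0.0)
        model = SlabModel(thickness=40.0, sld=5.0e-6)
        model.parameters["thickness"].vary = True
        model.parameters["sld"].vary = True
        fit = fitting.co_refine(model, curves, seed=4, de_maxiter=120)
        assert fit.parameters.value("thickness") == pytest.approx(62.0, abs=1e-3)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_no_varied_parameters_in_mc_is_error(self, q):
        model = SlabModel()
        curves = make_curves(model, q, noise=0.01, seed=1)
        fit = fitting.co_refine(model, curves, seed=1)
        with pytest.raises(fitting.FitError):
            fitting.monte_carlo_errors(fit, curves, n=10, seed=1)


class TestMonteCarlo:
    def _linear_curves(self, slope=2.0, sigma=0.05, n=25, seed=0):
        x = np.linspace(0.1, 1.0, n)
        rng = np.random.default_rng(seed)
        y = slope * x + rng.normal(0, sigma, n)
        return {"x": ReflectivityCurve(x, np.maximum(y, 0), dr=np.full(n, sigma))}, x

    def test_replicate_count_validated(self):
        curves, _ = self._linear_curves()
        model = LinearModel()
        fit = fitting.co_refine(model, curves, seed=1)
        with pytest.raises(fitting.FitError):
            fitting.monte_carlo_errors(fit, curves, n=1, seed=1)

    def test_near_degenerate_for_tiny_errors(self):
        x = np.linspace(0.1, 1.0, 25)
        curves = {
            "x": ReflectivityCurve(x, 2.0 * x, dr=np.full(x.size, 1e-9))
        }
        model = LinearModel(slope=1.5)
        fit = fitting.co_refine(model, curves, seed=1)
        mc = fitting.monte_carlo_errors(fit, curves, n=50, seed=2)
        lo, hi = mc.confidence_intervals["slope"]
        assert hi - lo < 1e-7

    def test_ci_matches_analytic_standard_error(self):
        sigma, n = 0.05, 25
        curves, x = self._linear_curves(sigma=sigma, n=n, seed=42)
        model = LinearModel(slope=1.0)
        fit = fitting.co_refine(model, curves, seed=3)
        mc = fitting.monte_carlo_errors(fit, curves, n=200, seed=7)
        lo, hi = mc.confidence_intervals["slope"]
        analytic_se = sigma / np.sqrt(np.sum(x**2))
        assert (hi - lo) / 2 == pytest.approx(1.96 * analytic_se, rel=0.15)

    def test_ci_widens_with_doubled_errors(self):
        curves, x = self._linear_curves(sigma=0.05, seed=8)
        wide = {
            "x": ReflectivityCurve(x, curves["x"].r, dr=2 * curves["x"].dr)
        }
        model = LinearModel()
        fit1 = fitting.co_refine(model, curves, seed=1)
        fit2 = fitting.co_refine(model, wide, seed=1)
        mc1 = fitting.monte_carlo_errors(fit1, curves, n=150, seed=5)
        mc2 = fitting.monte_carlo_errors(fit2, wide, n=150, seed=5)
        w1 = np.diff(mc1.confidence_intervals["slope"])[0]
        w2 = np.diff(mc2.confidence_intervals["slope"])[0]
        assert w2 > 1.5 * w1

    def test_coverage_near_nominal(self):
        # 95% CI should contain the generating slope in ~95% of simulations
        slope, sigma = 2.0, 0.05
        hits = 0
        n_sim = 50
        for i in range(n_sim):
            curves, _ = self._linear_curves(slope=slope, sigma=sigma, seed=100 + i)
            model = LinearModel(slope=1.0)
            fit = fitting.co_refine(model, curves, seed=i)
            mc = fitting.monte_carlo_errors(fit, curves, n=100, seed=1000 + i)
            lo, hi = mc.confidence_intervals["slope"]
            hits += lo <= slope <= hi
        assert 0.84 <= hits / n_sim <= 1.0
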
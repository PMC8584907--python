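"""Model permittivity, fitting criterion, fits, and the free-water statistic."""

import numpy as np
import pytest

from thzhyd import (ComplexSpectrum, DielectricParams, FitConfig,
                    FrequencyGrid, NoiseModel, PURE_WATER, eval_model,
                    fit_model, free_water_fraction, make_water_phase,
                    objective_s)
from thzhyd.model import EPS0, aggregate_replicates
from thzhyd.spectra import C_CM_PER_S
from thzhyd.synth import PRESETS

# replicate-mean fitted parameters of the seven studied samples:
# (d_eps1, d_eps2, tau2_ps, w0_cm, gamma_cm, a_over_w0sq, n_free_pct)
SAMPLE_ROWS = {
    "water": (68.86, 2.691, 0.316, 207.2, 196.5, 1.702, 3.78),
    "glucose": (62.45, 2.939, 0.326, 215.9, 202.6, 1.807, 3.91),
    "galactose": (62.23, 2.931, 0.327, 221.3, 217.3, 1.844, 3.86),
    "galacturonic": (63.20, 3.006, 0.334, 221.7, 223.1, 1.867, 3.91),
    "dextran": (63.81, 2.728, 0.321, 210.6, 200.0, 1.719, 3.80),
    "amylopectin": (65.97, 2.688, 0.319, 209.7, 197.4, 1.737, 3.74),
    "polygalacturonic": (63.75, 2.729, 0.312, 219.1, 208.2, 1.801, 3.72),
}


def term_by_term(nu_cm, d1, t1_ps, d2, t2_ps, aw, w0_cm, g_cm, einf, s0):
    """Independent scalar evaluation of the model, one term at a time."""
    w = 2 * np.pi * C_CM_PER_S * nu_cm
    w0 = 2 * np.pi * C_CM_PER_S * w0_cm
    g = 2 * np.pi * C_CM_PER_S * g_cm
    debye1 = d1 / complex(1, -w * t1_ps * 1e-12)
    debye2 = d2 / complex(1, -w * t2_ps * 1e-12)
    osc = (aw * w0**2) / complex(w0**2 - w**2, -w * g)
    cond = complex(0, s0 / (EPS0 * w))
    return debye1 + debye2 + osc + einf + cond


class TestEvalModel:
    def test_static_limit(self):
        # at nu -> 0 (sigma0 = 0) the permittivity tends to the sum of all
        # static contributions and the loss vanishes
        grid = FrequencyGrid(np.array([0.001, 0.002]))
        eps = eval_model(PURE_WATER, grid).values[0]
        static = 68.86 + 2.691 + 1.702 + 2.5
        assert eps.real == pytest.approx(static, rel=1e-3)
        assert abs(eps.imag) < 0.5

    def test_conductivity_term_is_purely_imaginary_additive(self, grid):
        base = eval_model(PURE_WATER, grid)
        from dataclasses import replace
        withcond = eval_model(replace(PURE_WATER, sigma0=1.3), grid)
        np.testing.assert_allclose(withcond.real, base.real, rtol=1e-14)
        expected = 1.3 / (EPS0 * grid.angular)
        np.testing.assert_allclose(withcond.imag - base.imag, expected,
                                   rtol=1e-12)

    @pytest.mark.parametrize("nu, expected", [
        (10.0, 6.471308489247394 + 5.657809429494916j),
        (110.0, 4.152665527751741 + 1.9169553700717297j),
    ])
    def test_pure_water_band_edges_frozen(self, grid, nu, expected):
        """Band-edge values frozen from a term-by-term hand computation."""
        idx = 0 if nu == 10.0 else len(grid) - 1
        value = eval_model(PURE_WATER, grid).values[idx]
        assert value == pytest.approx(expected, rel=1e-12)
        oracle = term_by_term(nu, 68.86, 8.28, 2.691, 0.316, 1.702,
                              207.2, 196.5, 2.5, 0.0)
        assert value == pytest.approx(oracle, rel=1e-12)

    def test_component_losses_nonnegative(self, grid):
        # each Debye and oscillator building block is separately passive
        w = grid.angular
        for tau in (8.28e-12, 0.316e-12):
            assert np.all((1 / (1 - 1j * w * tau)).imag >= 0)
        w0 = 2 * np.pi * C_CM_PER_S * 207.2
        g = 2 * np.pi * C_CM_PER_S * 196.5
        assert np.all((1 / (w0**2 - w**2 - 1j * w * g)).imag >= 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DielectricParams.from_oscillator_strength(
                d_eps1=-1, d_eps2=2.7, tau2_ps=0.3, a_over_w0sq=1.7,
                w0_cm=207, gamma_cm=196)


class TestObjective:
    def test_identity_gives_zero(self, water_spectrum):
        assert objective_s(water_spectrum, water_spectrum) == 0.0

    def test_uniform_ten_percent_offset(self, grid, water_spectrum):
        # experiment = 1.1 x model on both parts: each squared relative
        # residual is 0.1^2, so s = 0.02 exactly
        exp = ComplexSpectrum(grid, 1.1 * water_spectrum.values)
        assert objective_s(water_spectrum, exp) == pytest.approx(0.02, rel=1e-12)

    def test_matches_naive_loop(self, grid, water_spectrum, rng):
        exp_vals = water_spectrum.values * (
            1 + 0.05 * rng.standard_normal(len(grid))
            + 0.05j * rng.standard_normal(len(grid)))
        exp = ComplexSpectrum(grid, exp_vals)
        acc = 0.0
        for m, e in zip(water_spectrum.values, exp.values):
            acc += ((m.real - e.real) / m.real) ** 2
            acc += ((m.imag - e.imag) / m.imag) ** 2
        naive = acc / len(grid)
        assert objective_s(water_spectrum, exp) == pytest.approx(naive, abs=1e-14)

    def test_zero_model_part_rejected(self, grid):
        model = ComplexSpectrum(grid, np.full(len(grid), 2.0 + 0.0j))
        with pytest.raises(ZeroDivisionError):
            objective_s(model, model)


class TestFit:
    def test_noiseless_self_consistency(self, water_spectrum):
        result = fit_model(water_spectrum, FitConfig())
        assert result.s <= 1e-8
        p = result.params
        assert p.d_eps1 == pytest.approx(68.86, rel=1e-3)
        assert p.d_eps2 == pytest.approx(2.691, rel=1e-3)
        assert p.tau2_ps == pytest.approx(0.316, rel=1e-3)
        assert p.w0_cm == pytest.approx(207.2, rel=1e-3)
        assert p.gamma_cm == pytest.approx(196.5, rel=1e-3)
        assert p.a_over_w0sq == pytest.approx(1.702, rel=1e-3)

    @pytest.mark.parametrize("sample", sorted(SAMPLE_ROWS))
    def test_all_sample_parameter_sets_fit_below_worst_observed(self, grid,
                                                                sample):
        """Noiseless spectra from every reported parameter set refit with
        s well under 0.0021, the worst value seen in repeated analyses."""
        preset = PRESETS[sample]
        spec = eval_model(preset.water_params, grid)
        result = fit_model(spec, FitConfig(sigma0=preset.sigma0, multistart=2))
        assert result.s <= 0.0021
        assert result.s <= 1e-8

    def test_refit_is_idempotent(self, grid, water_spectrum):
        first = fit_model(water_spectrum, FitConfig(multistart=2))
        refit = fit_model(eval_model(first.params, grid),
                          FitConfig(multistart=2))
        assert refit.params.d_eps1 == pytest.approx(first.params.d_eps1,
                                                    rel=1e-6)
        assert refit.params.a_over_w0sq == pytest.approx(
            first.params.a_over_w0sq, rel=1e-6)

    def test_noisy_replicates_recover_mean_within_ci(self, grid):
        noise = NoiseModel(seed=0)
        results = [
            fit_model(make_water_phase(PURE_WATER, grid, noise, replicate=r),
                      FitConfig(multistart=2))
            for r in range(20)
        ]
        agg = aggregate_replicates(results)
        assert abs(agg.loc["d_eps1", "mean"] - 68.86) <= agg.loc["d_eps1", "ci95"]


class TestFreeWaterFraction:
    @pytest.mark.parametrize("sample", sorted(SAMPLE_ROWS))
    def test_reported_rows_reproduced(self, sample):
        """The n column follows from d_eps2 and A/w0^2 of the same row to
        within +-0.05 (inputs are rounded replicate means)."""
        d1, d2, t2, w0, g, aw, n_ref = SAMPLE_ROWS[sample]
        params = DielectricParams.from_oscillator_strength(
            d_eps1=d1, d_eps2=d2, tau2_ps=t2, a_over_w0sq=aw, w0_cm=w0,
            gamma_cm=g)
        assert free_water_fraction(params) == pytest.approx(n_ref, abs=0.05)

    def test_vanishing_strength_gives_zero(self):
        params = DielectricParams.from_oscillator_strength(
            d_eps1=68.86, d_eps2=1e-12, tau2_ps=0.316, a_over_w0sq=1.702,
            w0_cm=207.2, gamma_cm=196.5)
        assert free_water_fraction(params) < 1e-10

    def test_monotone_in_strength_and_oscillator(self):
        from dataclasses import replace

        def build(d2, aw):
            return DielectricParams.from_oscillator_strength(
                d_eps1=68.86, d_eps2=d2, tau2_ps=0.316, a_over_w0sq=aw,
                w0_cm=207.2, gamma_cm=196.5)

        d2_grid = np.linspace(1.0, 5.0, 9)
        n_vs_d2 = [free_water_fraction(build(d2, 1.702)) for d2 in d2_grid]
        assert np.all(np.diff(n_vs_d2) > 0)
        aw_grid = np.linspace(0.5, 4.0, 9)
        n_vs_aw = [free_water_fraction(build(2.691, aw)) for aw in aw_grid]
        assert np.all(np.diff(n_vs_aw) < 0)


class TestAggregation:
    def test_identical_replicates_zero_halfwidth(self, water_spectrum):
        results = [fit_model(water_spectrum, FitConfig(multistart=1))
                   for _ in range(3)]
        agg = aggregate_replicates(results)
        assert np.all(agg["ci95"].to_numpy() < 1e-6)

    def test_single_replicate_rejected(self, water_spectrum):
        result = fit_model(water_spectrum, FitConfig(multistart=1))
        with pytest.raises(ValueError):
            aggregate_replicates([result])

    def test_halfwidth_matches_t_formula(self, rng):
        # 1000 trials of 20 normal draws: the mean CI half-width equals
        # t_0.975,19 * sigma / sqrt(20) up to the small-sample std bias
        from scipy import stats
        sigma, n, trials = 3.0, 20, 1000
        draws = rng.normal(0.0, sigma, size=(trials, n))
        tcrit = stats.t.ppf(0.975, n - 1)
        halfwidths = tcrit * draws.std(axis=1, ddof=1) / np.sqrt(n)
        assert halfwidths.mean() == pytest.approx(tcrit * sigma / np.sqrt(n),
                                                  rel=0.05)

    def test_row_order_matches_report(self, water_spectrum):
        results = [fit_model(water_spectrum, FitConfig(multistart=1))
                   for _ in range(2)]
        agg = aggregate_replicates(results)
        assert list(agg.index) == ["d_eps1", "d_eps2", "tau2_ps", "w0_cm",
                                   "gamma_cm", "a_over_w0sq", "n_free_pct"]
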
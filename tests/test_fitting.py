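"""Weighted NLS fitting, residual bootstrap, prediction intervals."""

import numpy as np
import pytest

import bombpulse as bp


def weighted_rss(params, points):
    arr = np.asarray(points, dtype=float)
    r = arr[:, 1] - bp.pmc_at(params, arr[:, 0])
    return float(np.sum(r**2 / arr[:, 2] ** 2))


def curve_points(params, years, sd=0.3):
    return [(y, float(bp.pmc_at(params, y)), sd) for y in years]


class TestFitPulse:
    def test_narwhal_four_param_matches_published_estimates(self, narwhal_fit):
        p = narwhal_fit.params
        assert narwhal_fit.converged
        assert narwhal_fit.n_obs == 46
        assert p.a == pytest.approx(92.6, abs=0.95)
        assert p.b == pytest.approx(103.3, abs=0.75)
        assert p.c == pytest.approx(1960, abs=1.5)
        assert p.d1 == pytest.approx(4.5, abs=1.7)

    def test_noiseless_points_recovered_exactly(self):
        years = np.arange(1940, 2006, 3.0)
        truth = bp.ALL_SPECIES_PARAMS
        fit = bp.fit_pulse(curve_points(truth, years), variant=bp.FIVE_PARAM)
        assert fit.objective == pytest.approx(0.0, abs=1e-10)
        assert fit.params.a == pytest.approx(truth.a, abs=1e-4)
        assert fit.params.c == pytest.approx(truth.c, abs=1e-3)
        fit4 = bp.fit_pulse(curve_points(bp.NARWHAL_PARAMS, years),
                            variant=bp.FOUR_PARAM)
        assert fit4.objective == pytest.approx(0.0, abs=1e-10)

    def test_row_order_invariance(self, narwhal, narwhal_fit):
        pts = narwhal.radiocarbon_points()
        rng = np.random.default_rng(0)
        shuffled = [pts[i] for i in rng.permutation(len(pts))]
        refit = bp.fit_pulse(shuffled, variant=bp.FOUR_PARAM)
        assert refit.params == narwhal_fit.params

    def test_fit_beats_initial_guess(self, narwhal, narwhal_fit):
        init = bp.PulseParams.four(92.0, 104.0, 1962.0, 5.0)
        pts = narwhal.radiocarbon_points()
        refit = bp.fit_pulse(pts, variant=bp.FOUR_PARAM, init=init)
        assert refit.objective <= weighted_rss(init, pts) + 1e-9
        assert refit.objective <= narwhal_fit.objective + 1e-6

    def test_narwhal_five_param_reports_nonconvergence(self, narwhal):
        # rise-only data carry no information on the decay timescale
        fit5 = bp.fit_pulse(narwhal, variant=bp.FIVE_PARAM)
        assert not fit5.converged
        assert "four-parameter" in fit5.message

    def test_combined_synthetic_five_param_converges(self, synthetic_five_fit):
        assert synthetic_five_fit.converged
        assert synthetic_five_fit.params.d2 > synthetic_five_fit.params.d1

    def test_too_few_points_rejected(self):
        pts = curve_points(bp.ALL_SPECIES_PARAMS, [1950, 1960, 1970, 1980])
        with pytest.raises(ValueError, match="at least"):
            bp.fit_pulse(pts, variant=bp.FIVE_PARAM)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="pmc_sd"):
            bp.fit_pulse([(1950, 95, 0.3), (1960, 99, 0.0), (1970, 102, 0.3),
                          (1980, 103, 0.3), (1990, 103, 0.3)],
                         variant=bp.FOUR_PARAM)


class TestBootstrap:
    def test_param_intervals_bracket_estimates(self, narwhal_boot):
        for name in ("a", "b", "c", "d1"):
            lo, hi = narwhal_boot.param_ci[name]
            est = getattr(narwhal_boot.params, name)
            assert lo <= est <= hi

    def test_narwhal_baseline_interval_matches_published(self, narwhal_boot):
        lo, hi = narwhal_boot.param_ci["a"]
        # printed 95% interval is [91.6, 93.5]
        overlap = min(hi, 93.5) - max(lo, 91.6)
        assert overlap / (93.5 - 91.6) >= 0.5

    def test_deterministic_given_seed(self, narwhal_fit):
        b1 = bp.bootstrap_ci(narwhal_fit, n_boot=50, seed=42)
        b2 = bp.bootstrap_ci(narwhal_fit, n_boot=50, seed=42)
        assert b1.param_ci == b2.param_ci
        assert np.array_equal(b1.curve_ci[0], b2.curve_ci[0])

    def test_single_replicate_gives_degenerate_interval(self, narwhal_fit):
        b = bp.bootstrap_ci(narwhal_fit, n_boot=1, seed=0)
        lo, hi = b.param_ci["a"]
        assert lo == pytest.approx(hi)

    def test_requires_converged_fit(self, narwhal):
        fit5 = bp.fit_pulse(narwhal, variant=bp.FIVE_PARAM)
        with pytest.raises(ValueError, match="converged"):
            bp.bootstrap_ci(fit5)

    def test_curve_band_brackets_fit(self, narwhal_boot):
        lo, hi = narwhal_boot.curve_ci
        assert np.all(lo <= narwhal_boot.curve + 1e-9)
        assert np.all(narwhal_boot.curve <= hi + 1e-9)


class TestPredictionInterval:
    def test_band_contains_confidence_band(self, narwhal_boot):
        fp = bp.prediction_interval(narwhal_boot, seed=2)
        assert np.all(fp.curve_pi[0] <= fp.curve_ci[0] + 1e-9)
        assert np.all(fp.curve_ci[1] <= fp.curve_pi[1] + 1e-9)

    def test_zero_noise_collapses_onto_curve(self, narwhal_fit):
        fp = bp.prediction_interval(narwhal_fit, noise_sd=0.0, seed=3)
        assert np.allclose(fp.curve_pi[0], fp.curve)
        assert np.allclose(fp.curve_pi[1], fp.curve)

    def test_custom_year_grid_returns_band(self, narwhal_boot):
        years = np.array([1955.0, 1965.0, 1975.0])
        g, lo, hi = bp.prediction_interval(narwhal_boot, years=years, seed=4)
        assert np.array_equal(g, years)
        assert np.all(lo < hi)

    def test_invalid_level_rejected(self, narwhal_fit):
        with pytest.raises(ValueError, match="level"):
            bp.prediction_interval(narwhal_fit, level=1.2)


def test_fitresult_json_and_band_export(narwhal_boot, tmp_path):
    fp = bp.prediction_interval(narwhal_boot, seed=5)
    out = tmp_path / "fit.json"
    fp.to_json(out)
    import json

    payload = json.loads(out.read_text())
    assert payload["params"]["variant"] == "four_param"
    assert payload["param_ci"]["a"][0] < payload["params"]["a"]
    band = tmp_path / "band.csv"
    fp.band_to_csv(band, which="pi")
    header = band.read_text().splitlines()[0]
    assert header == "year,lower,fit,upper"
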
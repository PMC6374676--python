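"""Driver regression, variation partitioning, and the attribution rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from elevrange import driver_attribution as drv

YEARS = np.arange(1990, 2018, dtype=float)


def brute_force_partition(y, tn, sf, w):
    """Independent three-model oracle via sqrt-weight least squares."""

    def r2(cols):
        X = np.column_stack([np.ones_like(y), *cols])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        ybar = (w * y).sum() / w.sum()
        return 1 - (w * (y - X @ beta) ** 2).sum() / (w * (y - ybar) ** 2).sum()

    r2_t, r2_s, r2_ts = r2([tn]), r2([sf]), r2([tn, sf])
    return r2_ts - r2_s, r2_t + r2_s - r2_ts, r2_ts - r2_t, 1 - r2_ts


def _instance(seed, n=28):
    rng = np.random.default_rng(seed)
    tn = 5 + 0.05 * np.arange(n) + rng.normal(0, 0.4, n)
    sf = 100 + 0.8 * np.arange(n) + rng.normal(0, 3, n)
    y = 1000 + rng.uniform(-40, 40) * tn + rng.uniform(-3, 3) * sf + rng.normal(0, 60, n)
    w = rng.integers(67, 783, n).astype(float)
    return y, tn, sf, w


class TestDriverRegression:
    def test_pure_temperature_signal(self):
        rng = np.random.default_rng(1)
        tn = 5 + 0.05 * np.arange(28)
        sf = rng.normal(100, 5, 28)  # independent of y
        y = 2.0 * tn
        reg = drv.fit_driver_regression(y, tn, sf)
        assert reg.beta_tn == pytest.approx(2.0, abs=1e-8)
        assert reg.beta_sf == pytest.approx(0.0, abs=1e-8)
        assert reg.r2_adj == pytest.approx(1.0, abs=1e-8)

    def test_simulation_recovers_coefficients(self):
        """Mean estimates over 200 replicates land within 2 MC standard
        errors of the generating coefficients."""
        rng = np.random.default_rng(2)
        b_tn = np.empty(200)
        b_sf = np.empty(200)
        for k in range(200):
            tn = 5 + 0.046 * np.arange(28) + rng.normal(0, 0.35, 28)
            sf = 4140 + 6.4 * np.arange(28) + rng.normal(0, 8, 28)
            y = 1000 + 10.0 * tn + 50.0 * sf + rng.normal(0, 80, 28)
            reg = drv.fit_driver_regression(y, tn, sf, np.full(28, 300.0))
            b_tn[k], b_sf[k] = reg.beta_tn, reg.beta_sf
        for est, truth in ((b_tn, 10.0), (b_sf, 50.0)):
            mc_se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - truth) < 2 * mc_se + 1e-9

    def test_zero_variance_predictor_is_error(self):
        y, tn, sf, w = _instance(0)
        with pytest.raises(ValueError, match="zero-variance predictor: SF"):
            drv.fit_driver_regression(y, tn, np.full_like(sf, 7.0), w)

    def test_misaligned_years_is_error(self):
        y, tn, sf, w = _instance(0)
        with pytest.raises(ValueError, match="misaligned"):
            drv.fit_driver_regression(y[:-1], tn, sf, w)

    def test_collinearity_flagged_but_fit_kept(self):
        y, tn, sf, w = _instance(0)
        reg = drv.fit_driver_regression(y, tn, 3.0 * tn + 1.0, w)
        assert reg.collinear


class TestVariationPartition:
    def test_orthogonal_predictors_have_no_shared_part(self):
        rng = np.random.default_rng(3)
        tn = rng.normal(size=64)
        sf = rng.normal(size=64)
        tn -= tn.mean()
        sf -= sf.mean()
        sf -= sf @ tn / (tn @ tn) * tn  # exact orthogonalization (keeps mean 0)
        y = 2 * tn + 3 * sf + rng.normal(0, 1, 64)
        part = drv.variation_partition(y, tn, sf)
        ptn, shared, psf, _ = brute_force_partition(y, tn, sf, np.ones(64))
        assert abs(shared) < 1e-9
        # each partial equals its marginal one-predictor R^2
        assert part.partial_tn == pytest.approx(ptn, abs=1e-9)
        assert part.partial_sf == pytest.approx(psf, abs=1e-9)

    def test_duplicated_predictor_is_all_shared(self):
        y, tn, _, w = _instance(4)
        part = drv.variation_partition(y, tn, tn.copy(), w)
        assert part.partial_tn == pytest.approx(0.0, abs=1e-9)
        assert part.partial_sf == pytest.approx(0.0, abs=1e-9)
        assert part.shared == pytest.approx(1 - part.unexplained, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        y, tn, sf, w = _instance(seed)
        part = drv.variation_partition(y, tn, sf, w)
        ptn, shared, psf, unexpl = brute_force_partition(y, tn, sf, w)
        if min(ptn, shared, psf, unexpl) >= 0:  # no flooring engaged
            assert part.partial_tn == pytest.approx(ptn, abs=1e-10)
            assert part.shared == pytest.approx(shared, abs=1e-10)
            assert part.partial_sf == pytest.approx(psf, abs=1e-10)
            assert part.unexplained == pytest.approx(unexpl, abs=1e-10)

    @given(st.integers(0, 10_000))
    def test_partition_is_a_probability_vector(self, seed):
        y, tn, sf, w = _instance(seed)
        part = drv.variation_partition(y, tn, sf, w)
        t = part.as_tuple()
        assert all(0.0 <= v <= 1.0 for v in t)
        assert sum(t) == pytest.approx(1.0, abs=1e-9)

    def test_independent_effects_sum_to_model_r2(self):
        y, tn, sf, w = _instance(5)
        ind = drv.independent_effects(y, tn, sf, w)
        part = drv.variation_partition(y, tn, sf, w)
        assert ind["independent_tn"] + ind["independent_sf"] == pytest.approx(
            1 - part.unexplained, abs=1e-9
        )


def _part(ptn, shared, psf, unexpl):
    return drv.DeviancePartition(ptn, shared, psf, unexpl)


class TestDriverRules:
    @pytest.mark.parametrize(
        "partition,expected,fallback",
        [
            ((0.042, 0.414, 0.307, 0.237), "SF", False),
            ((0.0, 0.946, 0.049, 0.003), "nd", False),
            ((0.109, 0.182, 0.526, 0.183), "tn+SF", False),
            ((0.253, 0.484, 0.048, 0.215), "tn", False),
            ((0.099, 0.783, 0.040, 0.078), "nd", True),
            ((0.02, 0.03, 0.02, 0.93), "none", False),
        ],
    )
    def test_threshold_rules(self, partition, expected, fallback):
        raw = drv.classify_driver(_part(*partition))
        assert raw.cls == expected and raw.fallback is fallback

    def test_collinear_nd_override_needs_lone_significant_temperature(self):
        """Under a dominant shared fraction only a temperature-specific signal
        (significant tn, non-significant SF) is separable."""
        raw = drv.classify_driver(_part(0.038, 0.954, 0.003, 0.004))
        stats_ = drv.DriverStats(102.4, 0.005, -50.28, 0.131)
        call = drv.finalize_driver_call(raw, stats_, "OBR")
        assert call.final == "tn" and not call.dde
        # a significant habitat coefficient under collinearity stays nd
        raw2 = drv.classify_driver(_part(0.002, 0.946, 0.049, 0.003))
        stats2 = drv.DriverStats(43.68, 0.116, 103.8, 0.001)
        call2 = drv.finalize_driver_call(raw2, stats2, "OBL")
        assert call2.final == "nd" and not call2.dde

    def test_fallback_goes_to_significant_covariate_with_larger_net(self):
        # both significant, temperature net larger
        raw = drv.classify_driver(_part(0.094, 0.823, 0.038, 0.045))
        call = drv.finalize_driver_call(raw, drv.DriverStats(66.13, 0.001, 47.46, 0.009), "CBR")
        assert call.final == "tn"
        # both significant, habitat net larger
        raw = drv.classify_driver(_part(0.038, 0.824, 0.089, 0.048))
        call = drv.finalize_driver_call(raw, drv.DriverStats(48.13, 0.035, 68.61, 0.006), "OBR")
        assert call.final == "SF" and not call.dde  # positive habitat slope
        # neither significant: stays nd
        raw = drv.classify_driver(_part(0.099, 0.783, 0.040, 0.078))
        call = drv.finalize_driver_call(raw, drv.DriverStats(59.64, 0.089, 44.40, 0.221), "CBR")
        assert call.final == "nd"

    def test_density_dependent_effect_flags(self):
        """Negative habitat slope at an upper landmark with an SF or nd call
        is flagged dde; temperature calls and lower landmarks never are."""
        raw_sf = drv.classify_driver(_part(0.0, 0.541, 0.439, 0.020))
        call = drv.finalize_driver_call(raw_sf, drv.DriverStats(-3.198, 0.912, -112.1, 0.0005), "OBR")
        assert call.final == "SF" and call.dde and call.label == "dde (SF)"
        raw_nd = drv.classify_driver(_part(0.0, 0.993, 0.007, 0.0))
        call2 = drv.finalize_driver_call(raw_nd, drv.DriverStats(33.45, 0.506, -153.9, 0.006), "OBR")
        assert call2.final == "nd" and call2.dde and call2.label == "dde (nd)"
        # lower landmark with positive habitat slope: plain SF
        call3 = drv.finalize_driver_call(raw_sf, drv.DriverStats(8.9, 0.58, 121.4, 0.0005), "OBL")
        assert call3.label == "SF" and not call3.dde
        assert call3.level == "SF"

    def test_temperature_only_world_never_calls_habitat(self):
        """When the landmark is driven by temperature alone (habitat flat),
        the final call is tn or nd in at least 95% of simulations."""
        rng = np.random.default_rng(11)
        ok = 0
        n_rep = 200
        for _ in range(n_rep):
            tn = 5 + 0.046 * np.arange(28) + rng.normal(0, 0.35, 28)
            sf = rng.normal(4200, 5, 28)  # no trend, small jitter
            y = 1000 + 60.0 * tn + rng.normal(0, 25, 28)
            w = rng.integers(67, 783, 28).astype(float)
            part = drv.variation_partition(y, tn, sf, w)
            reg = drv.fit_driver_regression(y, tn, sf, w)
            call = drv.finalize_driver_call(drv.classify_driver(part), reg, "OPT")
            ok += call.final in ("tn", "nd")
        assert ok / n_rep >= 0.95

    def test_partition_validation(self):
        with pytest.raises(ValueError):
            _part(0.5, 0.5, 0.5, -0.5).check()
        with pytest.raises(ValueError):
            _part(0.3, 0.3, 0.3, 0.3).check()
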
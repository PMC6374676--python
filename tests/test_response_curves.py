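"""Curve fitting, landmark extraction and bootstrap reliability."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import analytic_curve
from elevrange import response_curves as rc
from elevrange import synthetic_data as syn
from elevrange.trend_classification import fit_weighted_trend

FAST = rc.CurveSettings(n_boot=20)


def scan_landmarks(curve_fn, lo=600.0, hi=2700.0, step=0.1, ref_step=1.0):
    """Independent dense-grid scan oracle for the five landmarks."""
    g = np.arange(lo, hi + step / 2, step)
    p = curve_fn(g)
    i = int(np.argmax(p))
    out = {lm: None for lm in rc.LANDMARKS}
    at_lower = g[i] <= lo + ref_step
    at_upper = g[i] >= hi - ref_step
    if not (at_lower or at_upper):
        out["OPT"] = g[i]
    for lm, level, sgn in (
        ("CBL", p[i] * np.exp(-0.5), -1),
        ("OBL", p[i] * np.exp(-2.0), -1),
        ("CBR", p[i] * np.exp(-0.5), 1),
        ("OBR", p[i] * np.exp(-2.0), 1),
    ):
        if (sgn < 0 and at_lower) or (sgn > 0 and at_upper):
            continue
        j = i
        while 0 <= j + sgn < len(g):
            j += sgn
            if p[j] <= level:
                out[lm] = g[j]
                break
    return out


class TestExtraction:
    def test_analytic_gaussian_landmarks(self):
        """CB at mu -/+ sigma and OB at mu -/+ 2 sigma, within one grid step."""
        rp = rc.extract_reference_points(analytic_curve(1500.0, 200.0, 200.0))
        expected = {"OPT": 1500, "CBL": 1300, "CBR": 1700, "OBL": 1100, "OBR": 1900}
        for lm, val in expected.items():
            assert rp.points[lm] == pytest.approx(val, abs=1.0)

    def test_truncated_below_survey_window(self):
        """An optimum at 700 m leaves CBL (500 m) and OBL (300 m) unobservable."""
        rp = rc.extract_reference_points(analytic_curve(700.0, 200.0, 200.0))
        assert rp.points["OPT"] == pytest.approx(700, abs=1.0)
        assert rp.points["CBR"] == pytest.approx(900, abs=1.0)
        assert rp.points["OBR"] == pytest.approx(1100, abs=1.0)
        assert rp.points["CBL"] is None and rp.points["OBL"] is None

    def test_boundary_maximum_truncates_that_side(self):
        """A curve still rising at 2,700 m has no optimum or upper landmarks."""
        rp = rc.extract_reference_points(analytic_curve(3200.0, 600.0, 600.0))
        assert rp.points["OPT"] is None
        assert rp.points["CBR"] is None and rp.points["OBR"] is None
        assert rp.points["CBL"] is not None and rp.points["OBL"] is not None

    def test_matches_dense_scan_oracle_on_random_curves(self):
        """Extraction equals a 0.1-m brute-force scan within one grid step."""
        rng = np.random.default_rng(0)
        for _ in range(30):
            mu = rng.uniform(400, 2900)
            sl, su = rng.uniform(80, 500, size=2)
            pm = rng.uniform(0.05, 1.0)
            curve = analytic_curve(mu, sl, su, pm)
            rp = rc.extract_reference_points(curve)
            oracle = scan_landmarks(
                lambda g: pm * np.exp(-((g - mu) ** 2) / (2 * np.where(g < mu, sl, su) ** 2))
            )
            for lm in rc.LANDMARKS:
                a, b = rp.points[lm], oracle[lm]
                assert (a is None) == (b is None), (lm, mu, sl, su, a, b)
                if a is not None:
                    assert a == pytest.approx(b, abs=1.1)

    @given(
        mu=st.floats(500, 2800),
        sl=st.floats(60, 600),
        su=st.floats(60, 600),
        pm=st.floats(0.05, 1.0),
    )
    def test_landmark_ordering_invariant(self, mu, sl, su, pm):
        """OBL <= CBL <= OPT <= CBR <= OBR among the present landmarks."""
        rp = rc.extract_reference_points(analytic_curve(mu, sl, su, pm))
        present = [rp.points[lm] for lm in rc.LANDMARKS if rp.points[lm] is not None]
        assert present == sorted(present)


class TestFit:
    def test_all_absent_is_degenerate(self):
        rows = pd.DataFrame(
            {
                "species": "s",
                "year": 2000,
                "elevation": np.linspace(600, 2700, 100),
                "easting": np.arange(100.0),
                "northing": np.arange(100.0),
                "presence": 0,
            }
        )
        curve = rc.fit_year_curve(rows)
        assert curve.degenerate and not curve.ok
        rp = rc.extract_reference_points(curve)
        assert all(v is None for v in rp.points.values())

    def test_recovers_true_optimum(self, gaussian_survey):
        curve = rc.fit_year_curve(gaussian_survey)
        assert curve.ok
        assert (curve.probability >= 0).all() and (curve.probability <= 1).all()
        opt = curve.grid[np.argmax(curve.probability)]
        assert opt == pytest.approx(1500.0, abs=50.0)

    def test_flat_truth_yields_flat_curve(self, rugged_grid):
        flat = syn.SpeciesTruth.from_linear_drift(
            "flat", [2000], p_max=0.5, sigma_l0=1e7, sigma_u0=1e7
        )
        sv = syn.simulate_surveys(rugged_grid, [flat], {2000: 5000}, seed=3)
        curve = rc.fit_year_curve(sv)
        assert np.ptp(curve.probability) < 0.1

    def test_agrees_with_mgcv_gam(self, gaussian_survey, tmp_path):
        """Independent engine check: an mgcv binomial GAM with the same df
        ceilings locates the same optimum on a strong-signal fixture."""
        csv = tmp_path / "sv.csv"
        gaussian_survey.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(mgcv))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- gam(presence ~ s(elevation, k=4) + s(easting, northing, k=15),\n"
            "         family=binomial, data=d)\n"
            "grid <- seq(600, 2700, by=1)\n"
            "nd <- data.frame(elevation=grid, easting=mean(d$easting),\n"
            "                 northing=mean(d$northing))\n"
            "cat(grid[which.max(predict(m, nd, type='response'))], '\\n')\n"
        )
        try:
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, timeout=600
            )
        except FileNotFoundError:
            pytest.skip("Rscript unavailable")
        assert out.returncode == 0, out.stderr
        opt_r = float(out.stdout.strip().split()[-1])
        curve = rc.fit_year_curve(gaussian_survey)
        opt_py = curve.grid[np.argmax(curve.probability)]
        assert opt_py == pytest.approx(opt_r, abs=60.0)


class TestBootstrap:
    def test_seed_required_and_deterministic(self, gaussian_survey):
        with pytest.raises(ValueError):
            rc.bootstrap_reliability(gaussian_survey.head(200), FAST)
        a = rc.bootstrap_reliability(gaussian_survey.head(300), FAST, seed=9)
        b = rc.bootstrap_reliability(gaussian_survey.head(300), FAST, seed=9)
        assert a.points == b.points and a.success == b.success

    def test_absent_species_all_unreliable(self):
        rows = pd.DataFrame(
            {
                "species": "s",
                "year": 2000,
                "elevation": np.linspace(600, 2700, 80),
                "easting": np.arange(80.0),
                "northing": np.arange(80.0) % 9,
                "presence": 0,
            }
        )
        rp = rc.bootstrap_reliability(rows, FAST, seed=1)
        assert all(v == 0.0 for v in rp.success.values())
        assert not any(rp.reliable.values())

    def test_half_success_is_reliable(self, gaussian_survey, monkeypatch):
        """Success in exactly 50% of replicates meets the 'at least 50%' rule."""
        calls = {"n": 0}
        orig = rc._CurveDesign.fit

        def alternating(self, idx=None, start_params=None):
            if idx is None:  # full-data fit untouched
                return orig(self, idx, start_params)
            calls["n"] += 1
            return orig(self, idx, start_params) if calls["n"] % 2 else None

        monkeypatch.setattr(rc._CurveDesign, "fit", alternating)
        rp = rc.bootstrap_reliability(gaussian_survey.head(1000), FAST, seed=3)
        assert rp.success["OPT"] == pytest.approx(0.5)
        assert rp.reliable["OPT"]

    def test_strong_signal_high_success(self, rugged_grid, gaussian_truth):
        sv = syn.simulate_surveys(rugged_grid, [gaussian_truth], {2000: 500}, seed=11)
        rp = rc.bootstrap_reliability(sv, rc.CurveSettings(n_boot=50), seed=12)
        assert rp.success["OPT"] >= 0.9
        assert rp.n_y == 500


class TestSeries:
    @staticmethod
    def _refpoints(n_reliable: int) -> list[rc.ReferencePoints]:
        out = []
        for k in range(max(n_reliable, 12)):
            rp = rc.ReferencePoints("s", 2000 + k, n_y=100)
            good = k < n_reliable
            rp.points = {lm: 1500.0 + k if good else None for lm in rc.LANDMARKS}
            rp.success = {lm: 1.0 if good else 0.0 for lm in rc.LANDMARKS}
            rp.reliable = {lm: good for lm in rc.LANDMARKS}
            out.append(rp)
        return out

    @pytest.mark.parametrize("n,informative", [(10, True), (9, False), (0, False)])
    def test_informative_threshold(self, n, informative):
        series = rc.build_series(self._refpoints(n))
        assert series["OPT"].informative is informative
        assert len(series["OPT"]) == n

    def test_weights_are_sampling_effort(self):
        series = rc.build_series(self._refpoints(11))
        assert (series["OPT"].weights == 100).all()

    def test_opt_drift_recovery(self, rugged_grid):
        """28 simulated years with the optimum rising 5 m/yr: the recovered
        trend's 95% CI covers the truth (full-data fits, n = 300/yr)."""
        years = syn.DEFAULT_SURVEY_YEARS
        truth = syn.SpeciesTruth.from_linear_drift(
            "drift", years, p_max=0.6, mu0=1400.0, mu_trend=5.0, sigma_l0=250.0, sigma_u0=250.0
        )
        sv = syn.simulate_surveys(rugged_grid, [truth], {y: 300 for y in years}, seed=6)
        pts = []
        for y in years:
            curve = rc.fit_year_curve(sv[sv.year == y])
            rp = rc.extract_reference_points(curve)
            if rp.points["OPT"] is not None:
                pts.append((y, rp.points["OPT"]))
        assert len(pts) >= 25
        yrs, vals = map(np.asarray, zip(*pts))
        fit = fit_weighted_trend((yrs, vals, np.full(len(yrs), 300.0)))
        lo, hi = fit.ci()
        assert lo <= 5.0 <= hi
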
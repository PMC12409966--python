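"""Beer-Lambert and two-component model fitting, and the linearity ceiling."""

import numpy as np
import pytest

from ledspec.fitters import (
    NO_CEILING,
    BeerLambertRegression,
    ConcentrationSeries,
    TwoComponentRegression,
    fit_beer_lambert,
    fit_two_component,
    linearity_bound,
)
from ledspec.optics import (
    Sample,
    TwoComponentParams,
    apparent_absorbance,
    pnitroaniline_extinction,
    two_component_absorbance,
)
from ledspec.spectra import GaussianPeak, gaussian_emission
from ledspec.synthdata import make_dilution_series


def _series(conc, absorb, l=1.0):
    return ConcentrationSeries(np.asarray(conc), np.asarray(absorb), path_length=l)


class TestBeerLambert:
    def test_noiseless_identity(self):
        conc = np.linspace(1e-5, 2e-4, 8)
        res = fit_beer_lambert(_series(conc, conc * 1.0e4))
        assert res.estimates["epsilon"] == pytest.approx(1.0e4, rel=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert res.standard_errors["epsilon"] == pytest.approx(0.0, abs=1e-6)

    def test_curved_data_biases_epsilon_downward(self):
        """Beer-Lambert fitted to two-component data underestimates the
        generating extinction coefficient (the curvature pulls it down)."""
        series = make_dilution_series(epsilon=9.43e3, f_na=0.0097, noise_sd=0.0)
        res = fit_beer_lambert(series)
        assert res.estimates["epsilon"] < 9.43e3

    def test_high_r_squared_on_linear_series(self):
        series = make_dilution_series(epsilon=1.0e4, f_na=0.0, noise_sd=1e-3, seed=4)
        assert fit_beer_lambert(series).r_squared > 0.99

    def test_all_zero_concentrations_rejected(self):
        with pytest.raises(ValueError):
            BeerLambertRegression().fit([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])

    def test_sklearn_interface(self):
        est = BeerLambertRegression(path_length=1.0)
        assert est.get_params() == {"path_length": 1.0, "fit_intercept": False}
        conc = np.linspace(1e-5, 2e-4, 8)
        est.fit(conc[:, None], conc * 1.0e4)
        np.testing.assert_allclose(est.predict([[1e-4]]), [1.0])
        assert est.score(conc[:, None], conc * 1.0e4) == pytest.approx(1.0)


class TestTwoComponent:
    def test_noiseless_exact_recovery(self):
        """The fit recovers the generating (epsilon, f_na) exactly on clean
        model data, including the channel-1-like parameter regime."""
        series = make_dilution_series(epsilon=9.43e3, f_na=0.0097, noise_sd=0.0)
        res = fit_two_component(series)
        assert res.estimates["epsilon"] == pytest.approx(9.43e3, rel=1e-6)
        assert res.estimates["f_na"] == pytest.approx(0.0097, abs=1e-6)
        assert res.r_squared == pytest.approx(1.0)

    def test_flat_band_forward_model_gives_zero_f_na(self):
        """Data from the wavelength-resolved model with a flat extinction
        band (a monochromator-like measurement) fit with f_na ~ 0, and the
        extinction matches the Beer-Lambert fit."""
        conc = np.logspace(np.log10(6.5e-6), np.log10(1.9e-4), 12)
        src = gaussian_emission(GaussianPeak(405.0, 15.0))
        a = np.array([apparent_absorbance(src, Sample(c, 1.0e4)) for c in conc])
        series = _series(conc, a)
        two = fit_two_component(series)
        # consistent with zero: far below both the quoted uncertainty scale
        # (3e-4) and anything the noiseless data could support
        assert two.estimates["f_na"] == pytest.approx(0.0, abs=1e-4)
        bl = fit_beer_lambert(series)
        assert two.estimates["epsilon"] == pytest.approx(bl.estimates["epsilon"], rel=1e-4)

    def test_sloped_band_forward_model_gives_positive_f_na(self):
        """When the extinction varies across the LED band, the reduced model
        absorbs the curvature into f_na > 0."""
        conc = np.logspace(np.log10(6.5e-6), np.log10(1.9e-4), 12)
        src = gaussian_emission(GaussianPeak(405.0, 15.0))
        eps = pnitroaniline_extinction()  # sloped through the 405 nm band
        a = np.array([apparent_absorbance(src, Sample(c, eps)) for c in conc])
        res = fit_two_component(_series(conc, a))
        assert res.estimates["f_na"] > 3.0 * res.standard_errors["f_na"]

    def test_nested_models_rss_ordering(self, rng):
        """The two-parameter model never fits worse (in RSS) than the
        one-parameter Beer-Lambert line on the same data."""
        for seed in range(10):
            series = make_dilution_series(
                epsilon=rng.uniform(8e3, 1.1e4),
                f_na=rng.uniform(0.0, 0.02),
                noise_sd=1e-3,
                seed=seed,
            )
            bl = BeerLambertRegression().fit(series.concentrations, series.absorbances)
            tc = TwoComponentRegression().fit(series.concentrations, series.absorbances)
            rss_bl = np.sum((series.absorbances - bl.predict(series.concentrations)) ** 2)
            rss_tc = np.sum((series.absorbances - tc.predict(series.concentrations)) ** 2)
            assert rss_tc <= rss_bl + 1e-12

    def test_agrees_with_grid_search_oracle(self, rng):
        """The nonlinear fit lands within one cell of a brute-force 400x400
        (epsilon, f_na) grid search on random instances."""
        for seed in range(10):
            true_eps = rng.uniform(8.5e3, 1.05e4)
            true_f = rng.uniform(0.003, 0.02)
            series = make_dilution_series(epsilon=true_eps, f_na=true_f, noise_sd=1e-3, seed=100 + seed)
            res = fit_two_component(series)
            eps_grid = np.linspace(0.9 * true_eps, 1.1 * true_eps, 400)
            f_grid = np.linspace(0.0, 0.04, 400)
            cle = series.concentrations[:, None, None] * eps_grid[None, :, None]
            pred = -np.log10((1.0 - f_grid) * 10.0 ** (-cle) + f_grid)  # broadcast (n, e, f)
            rss = np.sum((pred - series.absorbances[:, None, None]) ** 2, axis=0)
            i, j = np.unravel_index(np.argmin(rss), rss.shape)
            i_fit = int(np.argmin(np.abs(eps_grid - res.estimates["epsilon"])))
            j_fit = int(np.argmin(np.abs(f_grid - res.estimates["f_na"])))
            assert abs(i - i_fit) <= 1  # within one grid cell in epsilon
            assert abs(j - j_fit) <= 1  # within one grid cell in f_na

    def test_parameter_recovery_at_noise_level(self):
        """Across 200 simulated series at the instrument noise level, the
        median errors are <= 0.001 on f_na and <= 1% on epsilon."""
        f_errors, eps_rel_errors = [], []
        rng = np.random.default_rng(2024)
        for seed in range(200):
            true_f = rng.uniform(0.005, 0.02)
            true_eps = rng.uniform(9.0e3, 1.0e4)
            series = make_dilution_series(epsilon=true_eps, f_na=true_f, noise_sd=1e-3, seed=seed)
            res = fit_two_component(series)
            f_errors.append(abs(res.estimates["f_na"] - true_f))
            eps_rel_errors.append(abs(res.estimates["epsilon"] / true_eps - 1.0))
        assert np.median(f_errors) <= 1e-3
        assert np.median(eps_rel_errors) <= 0.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            TwoComponentRegression().fit([1e-5, 2e-5], [0.1, 0.2])  # < 3 points
        with pytest.raises(ValueError):
            _series([1e-5, 1e-5, 1e-5], [0.1, 0.1, 0.1])  # single concentration


class TestLinearityBound:
    def test_no_ceiling_without_unabsorbable_light(self):
        assert linearity_bound(TwoComponentParams(1e4, 0.0), 0.05) == NO_CEILING

    def test_matches_dense_grid_scan(self):
        """Bisection ceiling agrees with a dense scan of the deviation curve."""
        params = TwoComponentParams(9.43e3, 0.0097)
        ceiling = linearity_bound(params, 0.05)
        cle = np.linspace(1e-6, 10.0, 2_000_001)
        a = two_component_absorbance(cle, params.f_na)
        ok = (cle - a) / cle <= 0.05
        scan_ceiling = a[ok].max()
        assert ceiling == pytest.approx(scan_ceiling, rel=1e-4)
        # and it lands near 1, the practical working limit for ~1% stray light
        assert 0.5 < ceiling < 2.0

    def test_larger_f_na_gives_smaller_ceiling(self):
        ceilings = [
            linearity_bound(TwoComponentParams(1e4, f), 0.05)
            for f in (0.002, 0.005, 0.01, 0.02)
        ]
        assert all(a > b for a, b in zip(ceilings, ceilings[1:]))


class TestSeriesIO:
    def test_csv_round_trip(self, tmp_path):
        series = make_dilution_series(seed=5)
        path = tmp_path / "series.csv"
        series.to_csv(path)
        back = ConcentrationSeries.from_csv(path)
        np.testing.assert_allclose(back.concentrations, series.concentrations)
        np.testing.assert_allclose(back.absorbances, series.absorbances)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("conc,abs\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            ConcentrationSeries.from_csv(path)

    def test_fit_report_json(self):
        series = make_dilution_series(seed=6)
        report = fit_two_component(series).to_json()
        import json

        d = json.loads(report)
        assert d["model"] == "two_component"
        assert set(d["estimates"]) == {"epsilon", "f_na"}
        assert d["schema_version"] == 1
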
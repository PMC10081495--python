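"""Tests of the GLS/IRLS fitting stages against known synthetic truths."""

import numpy as np
import pandas as pd
import pytest

from canopylight import canopy, fitting
from canopylight.exceptions import (
    DomainError,
    FitError,
    MissingDataError,
    UnidentifiableError,
)
from canopylight.leaf import shape_phi, shape_theta

from conftest import TRUTH


def gas_records(cv=0.0, seed=0, **kw):
    kw.setdefault("dark_sd", 0.0 if cv == 0.0 else 0.1)
    return canopy.generate_gas_exchange(TRUTH, cv=cv, seed=seed, **kw)


class TestFitRd:
    def test_mean_of_dark_records(self):
        df = pd.DataFrame({"E": [0.0, 0.0, 100.0], "pn": [-1.2, -1.8, 5.0]})
        assert fitting.fit_rd(df) == pytest.approx(-1.5)

    def test_single_record(self):
        df = pd.DataFrame({"E": [0.0], "pn": [-2.0]})
        assert fitting.fit_rd(df) == pytest.approx(-2.0)

    def test_noisy_records_close_to_truth(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"E": np.zeros(5), "pn": -1.7 + rng.normal(0, 0.1, 5)})
        assert fitting.fit_rd(df) == pytest.approx(-1.7, abs=0.15)

    def test_empty_raises(self):
        with pytest.raises(MissingDataError):
            fitting.fit_rd(pd.DataFrame({"E": [100.0], "pn": [5.0]}))


class TestStandardize:
    def test_unit_spaced_values(self):
        np.testing.assert_allclose(fitting.standardize([1, 2, 3]), [-1, 0, 1])

    def test_two_values_sample_sd(self):
        np.testing.assert_allclose(
            fitting.standardize([-0.5, 0.5]), [-0.70710678, 0.70710678], rtol=1e-6
        )

    def test_affine_invariance(self):
        x = np.array([0.3, 1.1, 2.9, 0.7])
        np.testing.assert_allclose(
            fitting.standardize(3.0 * x - 7.0), fitting.standardize(x), atol=1e-12
        )

    def test_degenerate(self):
        with pytest.raises(DomainError):
            fitting.standardize([2.0, 2.0, 2.0])


class TestGroupFit:
    def test_noise_free_recovery(self):
        rec = gas_records()
        fit = fitting.fit_lrc_group(rec, TRUTH.rd)
        assert fit.converged
        assert fit.p_max == pytest.approx(TRUTH.p_max, rel=1e-4)
        # the per-p_ad truths follow from the bilateral model's interpolation
        for p_ad in (1.0, 50.0, 100.0):
            sub = TRUTH.params_at(p_ad)
            assert fit.phi[p_ad] == pytest.approx(sub.phi, rel=1e-4)
            assert fit.theta[p_ad] == pytest.approx(sub.theta, rel=1e-3)

    def test_shared_p_max_recovery_under_noise(self):
        errs = []
        for seed in range(10):
            fit = fitting.fit_lrc_group(gas_records(cv=0.05, seed=seed), TRUTH.rd)
            errs.append(abs(fit.p_max - TRUTH.p_max) / TRUTH.p_max)
        assert np.median(errs) < 0.05

    def test_degenerate_all_zero_rates(self):
        df = pd.DataFrame(
            {
                "E": np.tile([30.0, 150.0, 700.0], 2),
                "p_ad": np.repeat([0.0, 100.0], 3),
                "pn": np.full(6, TRUTH.rd),
            }
        )
        with pytest.raises(FitError):
            fitting.fit_lrc_group(df, TRUTH.rd)

    def test_too_few_e_levels(self):
        df = pd.DataFrame(
            {"E": [30.0, 150.0], "p_ad": [50.0, 50.0], "pn": [1.0, 5.0]}
        )
        with pytest.raises(UnidentifiableError):
            fitting.fit_lrc_group(df, TRUTH.rd)


class TestShapeFit:
    PADS = np.array([1.0, 17.0, 33.0, 50.0, 67.0, 83.0, 100.0])

    def test_exact_data_interpolation(self):
        phi_pts = np.column_stack([self.PADS, shape_phi(self.PADS)])
        th_pts = np.column_stack([self.PADS, shape_theta(self.PADS)])
        res = fitting.fit_shape_params(phi_pts, th_pts, seed=0)
        np.testing.assert_allclose(res.shape.a, (-0.87, -0.026, 0.00028), atol=1e-8)
        # the 7-parameter form is not identifiable from 7 points; fitted values are
        np.testing.assert_allclose(
            shape_theta(self.PADS, res.shape), th_pts[:, 1], atol=1e-6
        )

    def test_noisy_quadratic_within_three_se(self):
        rng = np.random.default_rng(11)
        z = shape_phi(self.PADS) + rng.normal(0.0, 0.01, self.PADS.size)
        phi_pts = np.column_stack([self.PADS, z])
        th_pts = np.column_stack([self.PADS, shape_theta(self.PADS)])
        res = fitting.fit_shape_params(phi_pts, th_pts, seed=0)
        A = np.column_stack([np.ones_like(self.PADS), self.PADS, self.PADS**2])
        cov = 0.01**2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        for est, true, s in zip(res.shape.a, (-0.87, -0.026, 0.00028), se):
            assert abs(est - true) < 3.0 * s

    def test_constant_convexity_degenerate(self):
        phi_pts = np.column_stack([self.PADS, shape_phi(self.PADS)])
        th_pts = np.column_stack([self.PADS, np.zeros_like(self.PADS)])
        with pytest.raises(DomainError):
            fitting.fit_shape_params(phi_pts, th_pts, seed=0)

    def test_underdetermined(self):
        pts = np.array([[0.0, 1.0], [50.0, 2.0], [100.0, 3.0]])
        with pytest.raises(UnidentifiableError):
            fitting.fit_shape_params(pts, pts, seed=0)


class TestBilateralFit:
    def test_noise_free_recovery(self):
        fit = fitting.fit_bilateral(gas_records(), TRUTH.rd)
        assert fit.converged
        for name in ("phi_ad", "phi_ab", "p_max", "theta_ad", "theta_ab"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(TRUTH, name), rel=1e-4
            )

    def test_single_p_ad_level_unidentifiable(self):
        df = pd.DataFrame(
            {
                "E": [30.0, 150.0, 700.0, 1900.0],
                "p_ad": 50.0,
                "pn": [1.0, 6.0, 20.0, 35.0],
            }
        )
        with pytest.raises(UnidentifiableError):
            fitting.fit_bilateral(df, -1.7)

    def test_p_max_recovery_under_heteroscedastic_noise(self):
        """Median |relative error| of the shared maximum < 5% over 50 repeats."""
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            reps = int(rng.integers(2, 6))  # n = 2-5 replicates per cell
            rec = gas_records(cv=0.05, seed=seed, replicates=reps)
            fit = fitting.fit_bilateral(rec, TRUTH.rd)
            errs.append(abs(fit.params.p_max - TRUTH.p_max) / TRUTH.p_max)
        assert np.median(errs) < 0.05


class TestETR:
    CAL_AD = fitting.ETRCalibration(k1=0.30, k2=-0.0002, surface="adaxial")
    CAL_AB = fitting.ETRCalibration(k1=0.25, k2=-0.00015, surface="abaxial")

    def test_exact_line_gives_zero_quadratic_term(self):
        j = np.array([10.0, 40.0, 90.0, 160.0])
        cal = fitting.fit_etr_calibration(j, 0.25 * j, "adaxial")
        assert cal.k1 == pytest.approx(0.25, rel=1e-10)
        assert abs(cal.k2) < 1e-10

    def test_noisy_quadratic_within_three_se(self):
        rng = np.random.default_rng(3)
        j = np.linspace(5.0, 250.0, 40)
        pg = 0.3 * j - 0.0005 * j * j + rng.normal(0.0, 0.2, j.size)
        cal = fitting.fit_etr_calibration(j, pg, "adaxial")
        A = np.column_stack([j, j * j])
        cov = 0.2**2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        assert abs(cal.k1 - 0.3) < 3 * se[0]
        assert abs(cal.k2 + 0.0005) < 3 * se[1]

    def test_too_few_pairs(self):
        with pytest.raises(MissingDataError):
            fitting.fit_etr_calibration([10.0], [2.5], "adaxial")

    def test_linear_inverse_is_exact(self):
        cal = fitting.ETRCalibration(k1=0.25, k2=0.0, surface="adaxial")
        etr = canopy.generate_etr(TRUTH, cal, cal, cv=0.0, seed=0)
        ad = etr[etr["surface"] == "adaxial"]
        pg_back = cal.predict(ad["J"].to_numpy())
        from canopylight.leaf import gross_rate

        pg_true = gross_rate(
            ad["E"].to_numpy(), TRUTH.phi_ad, TRUTH.p_max, TRUTH.theta_ad
        )
        np.testing.assert_allclose(pg_back, pg_true, rtol=1e-12)

    def test_beyond_vertex_raises(self):
        cal = fitting.ETRCalibration(k1=0.30, k2=-0.0005, surface="adaxial")
        with pytest.raises(DomainError):
            cal.invert(60.0)  # quadratic tops out at 45

    def test_noise_free_roundtrip(self):
        etr = canopy.generate_etr(TRUTH, self.CAL_AD, self.CAL_AB, cv=0.0, seed=0)
        fit = fitting.lrc_from_etr(etr, self.CAL_AD, self.CAL_AB, TRUTH.rd)
        for name in ("phi_ad", "phi_ab", "p_max", "theta_ad", "theta_ab"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(TRUTH, name), rel=1e-3
            )

    def test_noisy_roundtrip_p_max_within_ten_percent(self):
        etr = canopy.generate_etr(TRUTH, self.CAL_AD, self.CAL_AB, cv=0.05, seed=4)
        fit = fitting.lrc_from_etr(etr, self.CAL_AD, self.CAL_AB, TRUTH.rd)
        assert fit.params.p_max == pytest.approx(TRUTH.p_max, rel=0.10)

    def test_missing_surface_raises(self):
        etr = canopy.generate_etr(TRUTH, self.CAL_AD, self.CAL_AB, cv=0.0, seed=0)
        only_ad = etr[etr["surface"] == "adaxial"]
        with pytest.raises(UnidentifiableError):
            fitting.lrc_from_etr(only_ad, self.CAL_AD, self.CAL_AB, TRUTH.rd)

    def test_rd_from_neighbours(self):
        rd = fitting.rd_from_neighbours(
            {(18, 2): -1.2, (18, 3): -1.8, (16, 2): -9.0}, das=18
        )
        assert rd == pytest.approx(-1.5)
        with pytest.raises(MissingDataError):
            fitting.rd_from_neighbours({(16, 2): -1.0}, das=18)
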
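"""Two-step estimator: k_obs fits, Michaelis-Menten fits, consistency."""

import numpy as np
import pandas as pd
import pytest

from kinact import (
    CovalentKineticsModel,
    KineticParams,
    OccupancyPoint,
    RatePoint,
    fit_kobs,
    fit_lineweaver_burk_origin,
    fit_mm,
    kobs_from_params,
    occupancy_closed_form,
)


def occ_points(k_obs, conc, times, rep=""):
    return [
        OccupancyPoint(conc=conc, time=t, occupancy=float(-np.expm1(-k_obs * t)),
                       replicate=rep)
        for t in times
    ]


class TestFitKobs:
    def test_noise_free_recovery(self):
        fit = fit_kobs(occ_points(0.005, 1e-7, [120.0, 240.0, 360.0]))
        assert fit.k_obs == pytest.approx(0.005, rel=1e-3)
        assert fit.n_points == 3

    def test_single_point_closed_form(self):
        fit = fit_kobs([OccupancyPoint(conc=1e-7, time=7200.0, occupancy=0.5)])
        assert fit.k_obs == pytest.approx(np.log(2) / 7200.0, rel=1e-9)
        assert fit.k_obs == pytest.approx(9.63e-5, rel=1e-2)

    def test_all_zero_occupancy_is_flagged(self):
        pts = [OccupancyPoint(conc=1e-7, time=t, occupancy=0.0) for t in (60, 120)]
        fit = fit_kobs(pts)
        assert fit.k_obs == 0.0
        assert fit.flag == "no_signal"

    def test_saturated_occupancy_is_clamped_not_fatal(self):
        pts = [OccupancyPoint(conc=1e-5, time=t, occupancy=1.0) for t in (120, 240)]
        fit = fit_kobs(pts)
        assert np.isfinite(fit.k_obs) and fit.k_obs > 0

    def test_mixed_concentrations_rejected(self):
        pts = [OccupancyPoint(conc=1e-7, time=60, occupancy=0.1),
               OccupancyPoint(conc=2e-7, time=60, occupancy=0.2)]
        with pytest.raises(ValueError):
            fit_kobs(pts)


class TestFitMM:
    def test_noise_free_recovery(self):
        true = KineticParams(0.01, 1e-6)
        concs = np.geomspace(0.1e-6, 10e-6, 5)
        pts = [RatePoint(conc=c, k_obs=kobs_from_params(true, c)) for c in concs]
        fit = fit_mm(pts)
        assert fit.status == "ok"
        assert fit.params.k_inact == pytest.approx(0.01, rel=5e-3)
        assert fit.params.K_I == pytest.approx(1e-6, rel=5e-3)
        assert fit.k_eff == pytest.approx(1e4, rel=5e-3)

    def test_flat_rates_are_plateau_degenerate(self):
        # all k_obs equal: K_I collapses toward zero and the fit is demoted
        pts = [RatePoint(conc=c, k_obs=0.01) for c in (1e-7, 3e-7, 1e-6)]
        fit = fit_mm(pts)
        assert fit.status in ("kinact-only", "failed")
        if fit.params is not None:
            assert fit.params.K_I < 1e-7 / 10

    def test_linear_regime_is_demoted_to_keff_only(self):
        true = KineticParams(0.01, 1e-3)  # K_I 1000x above the top dose
        concs = np.geomspace(1e-8, 1e-6, 5)
        pts = [RatePoint(conc=c, k_obs=kobs_from_params(true, c)) for c in concs]
        fit = fit_mm(pts)
        assert fit.status == "keff-only"
        assert fit.k_eff == pytest.approx(true.k_eff, rel=0.02)

    def test_needs_two_distinct_concentrations(self):
        pts = [RatePoint(conc=1e-7, k_obs=1e-4), RatePoint(conc=1e-7, k_obs=1.1e-4)]
        with pytest.raises(ValueError):
            fit_mm(pts)

    def test_standard_errors_shrink_with_less_noise(self):
        true = KineticParams(0.02, 2e-7)
        concs = np.geomspace(2e-8, 2e-6, 6)
        rng = np.random.default_rng(0)
        fits = []
        for sigma in (0.2, 0.02):
            pts = [
                RatePoint(conc=c, k_obs=float(kobs_from_params(true, c) * (1 + sigma * e)))
                for c, e in zip(concs, rng.standard_normal(len(concs)))
            ]
            fits.append(fit_mm(pts))
        assert fits[1].stderr_KI < fits[0].stderr_KI
        assert fits[1].stderr_keff < fits[0].stderr_keff


class TestLineweaverBurk:
    def test_single_point_ratio(self):
        assert fit_lineweaver_burk_origin(
            [RatePoint(conc=1e-6, k_obs=1e-4)]
        ) == pytest.approx(100.0)

    def test_exact_linear_points(self):
        pts = [RatePoint(conc=c, k_obs=250.0 * c) for c in (1e-8, 5e-8, 2e-7)]
        assert fit_lineweaver_burk_origin(pts) == pytest.approx(250.0, rel=1e-12)

    def test_low_concentration_limit_matches_keff(self):
        true = KineticParams(0.01, 1e-5)
        concs = np.geomspace(1e-9, 1e-7, 5)  # all <= K_I/100
        pts = [RatePoint(conc=c, k_obs=kobs_from_params(true, c)) for c in concs]
        assert fit_lineweaver_burk_origin(pts) == pytest.approx(true.k_eff, rel=0.02)

    def test_zero_concentration_is_domain_error(self):
        with pytest.raises(ValueError):
            fit_lineweaver_burk_origin([RatePoint(conc=0.0, k_obs=0.0)])


def test_two_step_identity_on_noise_free_data():
    # fit_kobs followed by fit_mm inverts the closed-form generator exactly
    # (up to optimizer tolerance)
    true = KineticParams(0.02, 1.5e-7)
    concs = [25e-9, 50e-9, 100e-9, 200e-9, 400e-9]
    times = [120.0, 240.0, 360.0]
    rate_pts = []
    for c in concs:
        pts = [OccupancyPoint(conc=c, time=t,
                              occupancy=occupancy_closed_form(true, c, t))
               for t in times]
        rate_pts.append(fit_kobs(pts).as_rate_point())
    fit = fit_mm(rate_pts)
    assert fit.params.k_inact == pytest.approx(true.k_inact, rel=5e-3)
    assert fit.params.K_I == pytest.approx(true.K_I, rel=5e-3)


def test_keff_recovery_under_additive_occupancy_noise():
    # 200 seeded replicate experiments at sigma = 0.03 on occupancy,
    # 5 doses x 3 times: the efficiency estimate stays within 15% (median)
    true = KineticParams(0.01, 1e-7)
    concs = [25e-9, 50e-9, 100e-9, 200e-9, 400e-9]
    times = [120.0, 240.0, 360.0]
    rng = np.random.default_rng(2024)
    errors = []
    for _ in range(200):
        rate_pts = []
        for c in concs:
            pts = [
                OccupancyPoint(
                    conc=c, time=t,
                    occupancy=float(np.clip(
                        occupancy_closed_form(true, c, t) + 0.03 * rng.standard_normal(),
                        0.0, 1.0,
                    )),
                )
                for t in times
            ]
            kf = fit_kobs(pts)
            if kf.flag != "no_signal":
                rate_pts.append(kf.as_rate_point())
        fit = fit_mm(rate_pts)
        errors.append(abs(fit.k_eff / true.k_eff - 1.0))
    assert float(np.median(errors)) < 0.15


class TestModelInterface:
    def test_model_from_dataframe_and_summary(self):
        true = KineticParams(0.03, 1e-7)
        rows = []
        for rep in ("a", "b"):
            for c in (5e-8, 1e-7, 2e-7, 4e-7):
                for t in (120.0, 240.0, 360.0):
                    rows.append({"conc": c, "time": t,
                                 "occupancy": occupancy_closed_form(true, c, t),
                                 "replicate": rep})
        res = CovalentKineticsModel(pd.DataFrame(rows)).fit()
        assert res.status == "ok"
        assert res.params.K_I == pytest.approx(1e-7, rel=0.01)
        # replicates produce separate k_obs points at each concentration
        assert res.mm.n_points == 8
        text = res.summary()
        assert "k_inact" in text and "K_I" in text and "k_eff" in text
        assert len(res.kobs_table()) == 8

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            CovalentKineticsModel(pd.DataFrame({"conc": [1e-7], "time": [60.0]}))
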
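"""Two-point triage: conversions, information criteria, model recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from kinact import (
    CRRecord,
    KineticParams,
    RatePoint,
    TwoPointScreenModel,
    classify_zero,
    fit_candidate_models,
    kobs_from_cr,
    occupancy_closed_form,
    scenario_outputs,
    select_model,
)
from kinact.triage import RSS_FLOOR, ModelFit, _aic_bic


def records(cr_by_conc, time=3600.0, reps=1):
    out = []
    for conc, crs in cr_by_conc.items():
        crs = crs if isinstance(crs, (list, tuple)) else [crs]
        for i, cr in enumerate(crs * reps if reps > 1 else crs):
            out.append(CRRecord(analyte="A", fragment="F", conc=conc, cr=cr,
                                replicate=f"r{i}", time=time))
    return out


class TestZeroClassification:
    def test_no_competition_at_both_concentrations(self):
        # CR >= 1 (treated/DMSO) at both doses: occupancy <= 0 everywhere
        assert classify_zero(records({2e-5: 1.05, 5e-5: 1.2}))

    def test_half_occupancy_is_not_zero(self):
        assert not classify_zero(records({2e-5: 0.5, 5e-5: 0.5}))

    def test_mixed_sides_is_not_zero(self):
        assert not classify_zero(records({2e-5: 1.1, 5e-5: 0.5}))

    def test_requires_two_concentrations(self):
        with pytest.raises(ValueError):
            classify_zero(records({2e-5: 0.5}))


class TestKobsFromCR:
    def test_half_occupancy_inversion(self):
        rec = CRRecord(analyte="A", fragment="F", conc=2e-5, cr=0.5, time=3600.0)
        pt = kobs_from_cr(rec)
        assert pt.k_obs == pytest.approx(math.log(2) / 3600.0, rel=1e-12)
        assert pt.k_obs == pytest.approx(1.925e-4, rel=1e-3)

    def test_no_competition_clamps_to_zero(self):
        rec = CRRecord(analyte="A", fragment="F", conc=2e-5, cr=1.2, time=3600.0)
        pt = kobs_from_cr(rec)
        assert pt.k_obs == 0.0
        assert pt.flag == "clamped_low"

    def test_full_occupancy_clamps_high(self):
        # CR so small it rounds occupancy to exactly 1.0 in floats
        rec = CRRecord(analyte="A", fragment="F", conc=2e-5, cr=1e-320, time=3600.0)
        pt = kobs_from_cr(rec, "treated_over_dmso")
        assert pt.flag == "clamped_high"
        assert np.isfinite(pt.k_obs) and pt.k_obs > 0

    def test_roundtrip_through_closed_form(self):
        # CR built from the closed form returns the generating k_obs exactly
        p = KineticParams(1e-3, 3e-5)
        for conc in (2e-5, 5e-5):
            occ = occupancy_closed_form(p, conc, 3600.0)
            rec = CRRecord(analyte="A", fragment="F", conc=conc, cr=1.0 - occ,
                           time=3600.0)
            expected = -math.log1p(-occ) / 3600.0
            assert kobs_from_cr(rec).k_obs == pytest.approx(expected, rel=1e-12)

    def test_dmso_over_treated_convention(self):
        rec = CRRecord(analyte="A", fragment="F", conc=2e-5, cr=2.0, time=3600.0)
        pt = kobs_from_cr(rec, "dmso_over_treated")  # occupancy = 1 - 1/2
        assert pt.k_obs == pytest.approx(math.log(2) / 3600.0, rel=1e-12)


class TestCandidateModels:
    def test_exact_linear_points(self):
        pts = [RatePoint(conc=c, k_obs=100.0 * c) for c in (2e-5, 5e-5)]
        fits = {f.model: f for f in fit_candidate_models(pts)}
        assert fits["linear"].params["k_eff"] == pytest.approx(100.0)
        assert fits["linear"].rss == pytest.approx(0.0, abs=1e-30)
        # exactly proportional through the origin: the hyperbola is not
        # identifiable and must never win
        best = select_model(list(fits.values()))
        assert best.model != "hyperbolic"

    def test_constant_model_is_the_mean(self):
        pts = [RatePoint(conc=2e-5, k_obs=9.0e-4), RatePoint(conc=5e-5, k_obs=9.1e-4)]
        fits = {f.model: f for f in fit_candidate_models(pts)}
        assert fits["constant"].params["k_inact"] == pytest.approx(9.05e-4)

    def test_information_criteria_recompute_from_rss_n_k(self):
        pts = [RatePoint(conc=c, k_obs=k)
               for c, k in [(2e-5, 3.1e-4), (2e-5, 2.9e-4), (5e-5, 5.2e-4), (5e-5, 4.8e-4)]]
        for f in fit_candidate_models(pts):
            if f.status != "ok":
                continue
            r = max(f.rss / f.n, RSS_FLOOR)
            assert f.aic == pytest.approx(f.n * math.log(r) + 2 * f.K, rel=1e-12)
            assert f.bic == pytest.approx(f.n * math.log(r) + f.K * math.log(f.n), rel=1e-12)

    def test_penalty_arithmetic_at_equal_rss(self):
        # same RSS and n: the extra hyperbolic parameter costs exactly
        # Delta-AIC = 2 and Delta-BIC = ln n
        for n in (2, 4, 8):
            aic1, bic1 = _aic_bic(1e-9, n, 1)
            aic2, bic2 = _aic_bic(1e-9, n, 2)
            assert aic2 - aic1 == pytest.approx(2.0)
            assert bic2 - bic1 == pytest.approx(math.log(n))

    def test_nonincreasing_rates_route_to_constant_only(self):
        pts = [RatePoint(conc=2e-5, k_obs=9e-4), RatePoint(conc=5e-5, k_obs=8e-4)]
        fits = {f.model: f for f in fit_candidate_models(pts)}
        assert fits["constant"].status == "ok"
        assert fits["linear"].status == "skipped_nonincreasing"
        assert fits["hyperbolic"].status == "skipped_nonincreasing"

    def test_hyperbolic_exact_interpolation_with_replicates(self):
        p = KineticParams(1e-3, 3e-5)
        pts = []
        for conc in (2e-5, 5e-5):
            k = float(p.k_inact * conc / (p.K_I + conc))
            pts += [RatePoint(conc=conc, k_obs=k, replicate=r) for r in ("a", "b")]
        fits = {f.model: f for f in fit_candidate_models(pts)}
        hyp = fits["hyperbolic"]
        assert hyp.n == 4
        assert hyp.params["k_inact"] == pytest.approx(1e-3, rel=1e-9)
        assert hyp.params["K_I"] == pytest.approx(3e-5, rel=1e-9)


class TestSelection:
    def test_zero_flag_overrides_everything(self):
        fits = [ModelFit("linear", {"k_eff": 1.0}, 0.0, 2, 1, -10.0, -10.0)]
        assert select_model(fits, zero_flag=True).model == "zero"

    def test_lowest_aic_wins(self):
        fits = [
            ModelFit("constant", {}, 1.0, 4, 1, -10.0, -10.0),
            ModelFit("hyperbolic", {}, 1.0, 4, 2, -12.0, -11.0),
            ModelFit("linear", {}, 1.0, 4, 1, -11.0, -11.5),
        ]
        assert select_model(fits).model == "hyperbolic"
        assert select_model(fits, criterion="bic").model == "linear"

    def test_ties_break_toward_fewer_parameters(self):
        fits = [
            ModelFit("hyperbolic", {}, 0.0, 2, 2, -134.0, -134.0),
            ModelFit("linear", {}, 0.0, 2, 1, -134.0, -134.0),
        ]
        assert select_model(fits).model == "linear"

    def test_all_failed_is_unclassified(self):
        fits = [ModelFit("hyperbolic", {}, float("nan"), 2, 2,
                         float("inf"), float("inf"), status="failed")]
        assert select_model(fits).model == "unclassified"


class TestScenarioOutputs:
    def test_constant_gives_bounds(self):
        fit = ModelFit("constant", {"k_inact": 1e-3}, 0.0, 4, 1, -10, -10)
        out = scenario_outputs(fit, [2e-5, 5e-5])
        assert out["k_inact"] == pytest.approx(1e-3)
        assert out["K_I_upper"] == pytest.approx(1e-5)       # min(conc)/2
        assert out["k_eff_lower"] == pytest.approx(100.0)    # k_inact/(min/2)
        assert out["K_I"] is None and out["k_eff"] is None

    def test_linear_gives_keff_only(self):
        fit = ModelFit("linear", {"k_eff": 50.0}, 0.0, 4, 1, -10, -10)
        out = scenario_outputs(fit, [2e-5, 5e-5])
        assert out["k_eff"] == pytest.approx(50.0)
        assert out["k_inact"] is None and out["K_I"] is None

    def test_hyperbolic_gives_everything(self):
        fit = ModelFit("hyperbolic",
                       {"k_inact": 1e-3, "K_I": 3e-5, "k_eff": 1e-3 / 3e-5},
                       0.0, 4, 2, -10, -10)
        out = scenario_outputs(fit, [2e-5, 5e-5])
        assert out["k_eff"] == pytest.approx(33.33, rel=1e-3)

    def test_zero_gives_nulls(self):
        fit = ModelFit("zero", {}, float("nan"), 0, 0, float("nan"), float("nan"))
        out = scenario_outputs(fit, [2e-5, 5e-5])
        assert all(v is None for v in out.values())


def _screen_from_truth(param_sets, concs=(2e-5, 5e-5), time=3600.0, cv=0.05,
                       seed=0, reps=2):
    """CR table for pairs generated under known kinetic regimes."""
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv**2))
    rows = []
    for i, params in enumerate(param_sets):
        for conc in concs:
            occ = 0.0 if params is None else occupancy_closed_form(params, conc, time)
            for r in range(reps):
                eps = rng.lognormal(-0.5 * sigma**2, sigma) if cv else 1.0
                rows.append({"analyte": f"A{i:03d}", "fragment": "F", "conc": conc,
                             "cr": max((1.0 - occ) * eps, 1e-12), "replicate": f"r{r}"})
    return pd.DataFrame(rows)


class TestModelRecovery:
    # generating regimes chosen relative to the 20/50 uM doses:
    # plateau (K_I = dose/100), middle (K_I between doses), linear (K_I = 100x dose)
    REGIMES = {
        "constant": KineticParams(5e-4, 2e-7),
        "hyperbolic": KineticParams(1e-3, 3e-5),
        "linear": KineticParams(1e-2, 5e-3),
    }

    @pytest.mark.parametrize("expected", sorted(REGIMES))
    def test_generating_model_recovered_in_majority(self, expected):
        n_pairs = 200
        table = _screen_from_truth([self.REGIMES[expected]] * n_pairs,
                                   cv=0.05, seed=hash(expected) % 2**31)
        res = TwoPointScreenModel(table, time=3600.0).fit()
        frac = float((res.table["model"] == expected).mean())
        assert frac > 0.5, f"{expected} recovered in only {frac:.0%} of pairs"

    def test_true_nonbinders_are_zero_noise_free(self):
        table = _screen_from_truth([None] * 20, cv=0.0)
        res = TwoPointScreenModel(table, time=3600.0).fit()
        assert (res.table["model"] == "zero").all()

    def test_aic_bic_agreement_reported(self):
        table = _screen_from_truth(
            [self.REGIMES["constant"], self.REGIMES["linear"], None] * 10,
            cv=0.05, seed=5,
        )
        res = TwoPointScreenModel(table, time=3600.0).fit()
        agreement = res.aic_bic_agreement()
        assert 0.0 <= agreement <= 1.0
        assert "pairs" in res.summary()
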
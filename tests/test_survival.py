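import io
import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.optimize import brentq

from palbocea import (
    CensoredSample,
    ParametricSurvivalModel,
    SimulationSpec,
    fit_parametric,
    select_model,
    simulate_ipd,
    survival_at,
    transition_prob,
    weibull_median,
)
from palbocea.simulate import DEFAULT_FOLLOWUP_CYCLES
from palbocea.survival import (
    FAMILIES,
    FitReport,
    NonIdentifiableError,
    SurvivalValidationError,
    fit_report_from_text,
    fit_report_to_text,
    read_censored_csv,
    write_censored_csv,
)


def make_model(family, lam, gam, a=1.5):
    if family == "generalized_gamma":
        return ParametricSurvivalModel(family, lam, gam, a)
    if family == "exponential":
        return ParametricSurvivalModel(family, lam)
    return ParametricSurvivalModel(family, lam, gam)


class TestSurvivalFunction:
    def test_starts_at_one(self, palbo_pfs):
        assert survival_at(palbo_pfs, 0.0) == 1.0

    def test_gamma_one_is_exponential(self):
        m = ParametricSurvivalModel("weibull", 0.1, 1.0)
        assert survival_at(m, 1.0) == pytest.approx(math.exp(-0.1), rel=1e-12)

    def test_weibull_median_closed_form(self, palbo_pfs):
        """Median solves S(t)=0.5; root-finding is the independent oracle."""
        med = weibull_median(palbo_pfs)
        root = brentq(lambda t: survival_at(palbo_pfs, t) - 0.5, 1e-6, 1e3)
        assert med == pytest.approx(root, rel=1e-9)
        assert med == pytest.approx(11.927, abs=5e-3)
        # ~11.0 months at 28 days/cycle, near the trial's 11.2-month median PFS
        assert med * 28.0 / (365.25 / 12) == pytest.approx(11.0, abs=0.1)

    def test_negative_time_rejected(self, palbo_pfs):
        with pytest.raises(SurvivalValidationError):
            survival_at(palbo_pfs, -0.5)

    @pytest.mark.parametrize("bad", [dict(scale=-1.0), dict(scale=0.0), dict(shape=0.0)])
    def test_invalid_parameters_rejected(self, bad):
        kw = dict(scale=0.1, shape=1.0) | bad
        with pytest.raises(SurvivalValidationError):
            ParametricSurvivalModel("weibull", **kw)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_proper_and_monotone(self, family):
        m = make_model(family, 0.05, 0.9)
        t = np.linspace(0.0, 400.0, 300)
        s = survival_at(m, t)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-14)
        assert np.all((s >= 0) & (s <= 1))
        # proper distribution: the tail keeps shrinking towards 0 (the
        # log-logistic decays only polynomially, so no fixed small cutoff)
        assert s[-1] < 0.1
        assert survival_at(m, 1e6) < 1e-3


class TestTransitionProbability:
    def test_printed_formula_placebo_first_cycle(self, placebo_pfs):
        # 1 - exp(lam*(t-1)^gam - lam*t^gam) at t=1 reduces to 1 - exp(-lam)
        assert transition_prob(placebo_pfs, 1) == pytest.approx(
            1.0 - math.exp(-0.1405), rel=1e-12
        )

    def test_exponential_is_memoryless(self):
        m = ParametricSurvivalModel("weibull", 0.07, 1.0)
        p = [transition_prob(m, t) for t in (1, 5, 50, 130)]
        assert np.allclose(p, 1.0 - math.exp(-0.07), atol=1e-14)

    def test_cycle_index_below_one_rejected(self, palbo_pfs):
        with pytest.raises(SurvivalValidationError):
            transition_prob(palbo_pfs, 0)

    @hyp_settings(max_examples=150, derandomize=True)
    @given(
        family=st.sampled_from(FAMILIES),
        lam=st.floats(1e-3, 0.5),
        gam=st.floats(0.4, 2.5),
        a=st.floats(0.4, 2.5),
        t=st.integers(1, 60),
    )
    def test_identity_with_survival_ratio(self, family, lam, gam, a, t):
        """Discrete hazard == 1 - S(t)/S(t-1) for every family (1e-12)."""
        m = make_model(family, lam, gam, a)
        s_prev = survival_at(m, float(t - 1))
        s_now = survival_at(m, float(t))
        if s_prev < 1e-12:
            return
        expected = 1.0 - s_now / s_prev
        assert transition_prob(m, t) == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= transition_prob(m, t) <= 1.0


class TestFitting:
    def test_weibull_parameter_recovery(self):
        """MLE recovers the placebo-arm PFS parameters from censored data."""
        true = ParametricSurvivalModel("weibull", 0.1405, 0.8904)
        data = simulate_ipd(
            SimulationSpec(true, n=2000, censoring="uniform", t_max=35, seed=7)
        )
        rep = fit_parametric(data, "weibull")
        assert rep.model.scale == pytest.approx(true.scale, rel=0.10)
        assert rep.model.shape == pytest.approx(true.shape, rel=0.10)
        assert rep.n == 2000

    def test_bias_shrinks_with_sample_size(self):
        true = ParametricSurvivalModel("weibull", 0.065, 0.955)
        errs = {}
        for n in (200, 2000):
            rel = []
            for rep in range(8):
                data = simulate_ipd(
                    SimulationSpec(true, n=n, censoring="uniform", t_max=60, seed=50 + rep)
                )
                m = fit_parametric(data, "weibull").model
                rel.append(abs(m.scale / true.scale - 1) + abs(m.shape / true.shape - 1))
            errs[n] = float(np.mean(rel))
        assert errs[2000] < errs[200]

    def test_exponential_nesting(self):
        """Weibull fit to exponential data should find shape near 1."""
        hits = 0
        for rep in range(100):
            data = simulate_ipd(
                SimulationSpec(
                    ParametricSurvivalModel("exponential", 0.1),
                    n=300,
                    censoring="none",
                    seed=2000 + rep,
                )
            )
            g = fit_parametric(data, "weibull").model.shape
            hits += 0.9 <= g <= 1.1
        assert hits >= 90

    def test_all_censored_not_identifiable(self):
        data = [CensoredSample(float(t), False) for t in range(1, 13)]
        with pytest.raises(NonIdentifiableError):
            fit_parametric(data, "weibull")

    def test_too_few_records_rejected(self):
        data = [CensoredSample(1.0, True)] * 5
        with pytest.raises(SurvivalValidationError):
            fit_parametric(data, "weibull")

    def test_deterministic_given_data(self):
        data = simulate_ipd(
            SimulationSpec(ParametricSurvivalModel("weibull", 0.1, 1.2), n=200, seed=3)
        )
        r1 = fit_parametric(data, "gompertz")
        r2 = fit_parametric(data, "gompertz")
        assert r1 == r2

    @pytest.mark.parametrize("family", FAMILIES)
    def test_information_criteria_recompute(self, family):
        data = simulate_ipd(
            SimulationSpec(
                ParametricSurvivalModel("weibull", 0.08, 1.1),
                n=400,
                censoring="administrative",
                t_max=40,
                seed=11,
            )
        )
        rep = fit_parametric(data, family)
        assert rep.aic == pytest.approx(2 * rep.k - 2 * rep.log_likelihood, abs=1e-9)
        assert rep.bic == pytest.approx(
            rep.k * math.log(rep.n) - 2 * rep.log_likelihood, abs=1e-9
        )


class TestModelSelection:
    def _rep(self, aic, bic, k=2, family="weibull"):
        ll = (2 * k - aic) / 2
        m = make_model(family, 0.1, 1.0)
        return FitReport(model=m, log_likelihood=ll, aic=aic, bic=bic, n=100)

    def test_argmin_aic(self):
        reps = [self._rep(100.0, 210.0), self._rep(98.5, 212.0), self._rep(103.2, 205.0)]
        assert select_model(reps).aic == 98.5

    def test_tie_broken_by_bic(self):
        reps = [self._rep(100.0, 210.0), self._rep(100.0, 205.0)]
        assert select_model(reps).bic == 205.0

    def test_empty_rejected(self):
        with pytest.raises(SurvivalValidationError):
            select_model([])

    def test_selection_recovers_weibull_family(self):
        """On Weibull data the chosen family is Weibull (or the generalized
        gamma that nests it) in at least 80% of replicates."""
        true = ParametricSurvivalModel("weibull", 0.065, 0.955)
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            data = simulate_ipd(
                SimulationSpec(
                    true,
                    n=2000,
                    censoring="administrative",
                    t_max=DEFAULT_FOLLOWUP_CYCLES,
                    seed=1000 + rep,
                )
            )
            reports = [fit_parametric(data, fam) for fam in FAMILIES]
            best = select_model(reports).model.family
            hits += best in ("weibull", "generalized_gamma")
        assert hits >= 0.8 * n_rep


class TestSerialization:
    def test_censored_csv_round_trip(self, tmp_path):
        data = [CensoredSample(1.5, True), CensoredSample(3.25, False)]
        path = tmp_path / "ipd.csv"
        write_censored_csv(data, path)
        assert read_censored_csv(path) == data

    def test_fit_report_text_round_trip(self):
        rep = FitReport(
            model=ParametricSurvivalModel("generalized_gamma", 0.07, 1.1, 1.4),
            log_likelihood=-123.456,
            aic=252.912,
            bic=263.1,
            n=500,
        )
        assert fit_report_from_text(fit_report_to_text(rep)) == rep

    def test_csv_requires_columns(self):
        with pytest.raises(SurvivalValidationError):
            read_censored_csv(io.StringIO("a,b\n1,2\n"))
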
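import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breath2plasma import (
    ConcentrationSeries,
    DoseEvent,
    MacroParams,
    MicroParams,
    derived_params,
    fit_compartment_model,
    macro_to_micro,
    micro_to_macro,
    observed_metrics,
    predict_concentration,
    select_model,
)
from breath2plasma.errors import (
    DataError,
    InconsistentMacroError,
    MetricsUnavailableError,
)
from breath2plasma.pk_core import PKFitResult

from conftest import PLASMA_TIMES, ode_concentration

# independently re-derived constants for the medium-dose plasma parameter set
# (quadratic-root formula evaluated by hand: s=0.41, p=0.0075)
_S, _P = 0.41, 0.0075
_ALPHA = (_S + math.sqrt(_S * _S - 4 * _P)) / 2
_BETA = (_S - math.sqrt(_S * _S - 4 * _P)) / 2


def _micro_strategy():
    pos = st.floats(min_value=0.01, max_value=1.0, allow_nan=False)
    return st.builds(
        lambda v1, k10, k12, k21: MicroParams(2, V1=v1, K10=k10, K12=k12, K21=k21),
        st.floats(min_value=0.05, max_value=2.0),
        pos,
        pos,
        st.floats(min_value=0.005, max_value=0.5),
    )


def _series(times, values, matrix="plasma", unit="μg/mL", **kw):
    return ConcentrationSeries("s1", matrix, np.asarray(times), np.asarray(values), unit, **kw)


class TestMicroToMacro:
    def test_bm_example_values(self, bm_micro, bm_dose):
        macro = micro_to_macro(bm_micro, bm_dose)
        (A, B), (alpha, beta) = macro.coefficients, macro.exponents
        assert alpha == pytest.approx(_ALPHA, rel=1e-12)
        assert beta == pytest.approx(_BETA, rel=1e-12)
        assert alpha == pytest.approx(0.3908, rel=1e-3)
        assert beta == pytest.approx(0.01919, rel=1e-3)
        assert A == pytest.approx(22.01, rel=1e-3)
        assert B == pytest.approx(0.659, rel=1e-3)

    def test_one_compartment(self):
        micro = MicroParams(1, V1=0.5, K10=0.2)
        macro = micro_to_macro(micro, DoseEvent(2.0))
        assert macro.coefficients == (4.0,)
        assert macro.exponents == (0.2,)

    def test_near_one_compartment_limit(self):
        # tiny exchange rates: fast exponent approaches K10
        micro = MicroParams(2, V1=0.5, K10=0.2, K12=1e-4, K21=1e-4)
        macro = micro_to_macro(micro, DoseEvent(2.0))
        assert macro.exponents[0] == pytest.approx(0.2, rel=1e-2)
        assert sum(macro.coefficients) == pytest.approx(4.0, rel=1e-12)

    @given(_micro_strategy())
    @settings(max_examples=100, deadline=None)
    def test_mass_identity(self, micro):
        dose = DoseEvent(3.0)
        macro = micro_to_macro(micro, dose)
        assert sum(macro.coefficients) == pytest.approx(dose.amount / micro.V1, rel=1e-9)

    def test_three_compartment_roots_satisfy_cubic(self):
        micro = MicroParams(3, V1=0.3, K10=0.2, K12=0.1, K21=0.05, K13=0.08, K31=0.01)
        macro = micro_to_macro(micro, DoseEvent(1.0))
        assert len(macro.exponents) == 3
        prod = np.prod(macro.exponents)
        assert prod == pytest.approx(0.2 * 0.05 * 0.01, rel=1e-9)
        assert sum(macro.exponents) == pytest.approx(0.2 + 0.1 + 0.05 + 0.08 + 0.01, rel=1e-9)

    def test_three_compartment_equal_return_rates_collapse(self):
        # equal peripheral return rates: one exponent equals that rate and its
        # coefficient vanishes, collapsing the observable curve to biexponential
        micro = MicroParams(3, V1=0.3, K10=0.2, K12=0.1, K21=0.05, K13=0.1, K31=0.05)
        macro = micro_to_macro(micro, DoseEvent(1.0))
        i = int(np.argmin(np.abs(np.asarray(macro.exponents) - 0.05)))
        assert macro.exponents[i] == pytest.approx(0.05, rel=1e-9)
        assert macro.coefficients[i] == pytest.approx(0.0, abs=1e-9)

    def test_rejects_infusion(self, bm_micro):
        with pytest.raises(ValueError):
            micro_to_macro(bm_micro, DoseEvent(1.0, duration=5.0))


class TestMacroToMicro:
    def test_bm_round_trip(self, bm_micro, bm_dose, bm_macro):
        rec = macro_to_micro(bm_macro, bm_dose)
        for name in ("V1", "K10", "K12", "K21"):
            assert getattr(rec, name) == pytest.approx(getattr(bm_micro, name), rel=1e-9)

    def test_single_exponent(self):
        macro = MacroParams((4.0,), (0.2,))
        micro = macro_to_micro(macro, DoseEvent(2.0))
        assert micro.K10 == 0.2 and micro.V1 == 0.5
        assert micro.K12 is None and micro.K21 is None

    @given(_micro_strategy())
    @settings(max_examples=100, deadline=None)
    def test_round_trip_property(self, micro):
        dose = DoseEvent(3.0)
        rec = macro_to_micro(micro_to_macro(micro, dose), dose)
        for name in ("V1", "K10", "K12", "K21"):
            assert getattr(rec, name) == pytest.approx(getattr(micro, name), rel=1e-9)

    def test_inconsistent_macro(self):
        with pytest.raises(InconsistentMacroError):
            macro_to_micro(MacroParams((1.0, -0.5), (0.4, 0.01)), DoseEvent(1.0))


class TestPredictConcentration:
    def test_initial_value(self, bm_macro, bm_dose):
        assert predict_concentration(bm_macro, bm_dose, [0.0])[0] == pytest.approx(
            4.76 / 0.21, rel=1e-12
        )

    def test_value_at_one_minute(self, bm_macro, bm_dose):
        # independent evaluation of the biexponential at t=1
        c0 = 4.76 / 0.21
        A = c0 * (_ALPHA - 0.03) / (_ALPHA - _BETA)
        B = c0 * (0.03 - _BETA) / (_ALPHA - _BETA)
        expected = A * math.exp(-_ALPHA) + B * math.exp(-_BETA)
        got = predict_concentration(bm_macro, bm_dose, [1.0])[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(15.53, rel=1e-3)

    def test_strictly_decreasing(self, bm_macro, bm_dose):
        t = np.linspace(0, 120, 721)
        c = predict_concentration(bm_macro, bm_dose, t)
        assert np.all(np.diff(c) < 0)

    def test_matches_ode_oracle_bolus(self, bm_micro, bm_dose, bm_macro):
        t = np.linspace(0.5, 120, 60)
        closed = predict_concentration(bm_macro, bm_dose, t)
        numeric = ode_concentration(bm_micro, bm_dose, t)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_matches_ode_oracle_infusion(self, bm_micro):
        dose = DoseEvent(4.76, duration=0.5)
        macro = micro_to_macro(bm_micro, DoseEvent(4.76))
        t = np.linspace(0.25, 120, 50)
        closed = predict_concentration(macro, dose, t)
        numeric = ode_concentration(bm_micro, dose, t)
        np.testing.assert_allclose(closed, numeric, rtol=1e-5)

    def test_zero_before_dose_start(self, bm_macro):
        dose = DoseEvent(4.76, start_time=5.0)
        c = predict_concentration(bm_macro, dose, [0.0, 4.9, 5.0])
        assert c[0] == 0.0 and c[1] == 0.0 and c[2] > 0


class TestFitCompartmentModel:
    def test_recovers_bm_plasma_params(self, bm_micro, bm_dose, bm_macro):
        values = predict_concentration(bm_macro, bm_dose, PLASMA_TIMES)
        fit = fit_compartment_model(_series(PLASMA_TIMES, values), bm_dose, 2)
        for name in ("V1", "K10", "K12", "K21"):
            assert getattr(fit.micro, name) == pytest.approx(
                getattr(bm_micro, name), rel=0.01
            )

    def test_recovers_bh_breath_k21(self, bh_breath_micro):
        dose = DoseEvent(7.63)
        macro = micro_to_macro(bh_breath_micro, dose)
        t = np.arange(1, 361) / 3.0
        values = predict_concentration(macro, dose, t)
        fit = fit_compartment_model(_series(t, values, matrix="breath", unit="ppbv"), dose, 2)
        assert fit.micro.K21 == pytest.approx(0.10, rel=0.01)

    def test_monoexponential_one_compartment(self):
        dose = DoseEvent(2.0)
        t = PLASMA_TIMES
        values = 4.0 * np.exp(-0.05 * t)
        fit = fit_compartment_model(_series(t, values), dose, 1)
        assert fit.micro.K10 == pytest.approx(0.05, rel=1e-6)
        assert fit.ssr < 1e-12

    def test_noisy_recovery_median_error(self, bm_micro, bm_dose, bm_macro):
        clean = predict_concentration(bm_macro, bm_dose, PLASMA_TIMES)
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            noisy = clean * np.exp(rng.normal(0, 0.05, clean.shape))
            fit = fit_compartment_model(_series(PLASMA_TIMES, noisy), bm_dose, 2)
            errs.append(abs(fit.micro.K10 - bm_micro.K10) / bm_micro.K10)
        assert np.median(errs) <= 0.15

    def test_insufficient_points(self, bm_dose):
        with pytest.raises(DataError):
            fit_compartment_model(_series([1, 2, 3], [3.0, 2.0, 1.0]), bm_dose, 2)

    def test_excluded_points_ignored(self, bm_micro, bm_dose, bm_macro):
        values = predict_concentration(bm_macro, bm_dose, PLASMA_TIMES)
        corrupted = values.copy()
        corrupted[-1] = 99.0  # flagged excluded, so must not disturb the fit
        flags = np.array(["observed"] * 8 + ["excluded"], dtype=object)
        fit = fit_compartment_model(
            _series(PLASMA_TIMES, corrupted, flags=flags), bm_dose, 2
        )
        assert fit.n_points == 8
        assert fit.micro.K10 == pytest.approx(bm_micro.K10, rel=0.01)

    def test_weighted_fit_runs(self, bm_dose, bm_macro):
        values = predict_concentration(bm_macro, bm_dose, PLASMA_TIMES)
        fit = fit_compartment_model(_series(PLASMA_TIMES, values), bm_dose, 2,
                                    weighting="inverse_y2")
        assert fit.micro.K10 == pytest.approx(0.25, rel=0.01)


class TestSelectModel:
    def test_selects_two_compartments(self, bm_dose, bm_macro):
        values = predict_concentration(bm_macro, bm_dose, PLASMA_TIMES)
        best = select_model(_series(PLASMA_TIMES, values), bm_dose)
        assert best.n_compartments == 2
        assert set(best.aic_by_model) == {1, 2, 3}

    def test_selects_one_compartment(self):
        dose = DoseEvent(2.0)
        values = 4.0 * np.exp(-0.05 * PLASMA_TIMES)
        best = select_model(_series(PLASMA_TIMES, values), dose)
        assert best.n_compartments == 1

    def test_two_compartment_fit_always_available(self, bm_dose, bm_macro):
        # even when AIC picks another structure, the 2-compartment fit exists
        values = predict_concentration(bm_macro, bm_dose, PLASMA_TIMES)
        fixed2 = fit_compartment_model(_series(PLASMA_TIMES, values), bm_dose, 2)
        assert fixed2.n_compartments == 2


class TestDerivedParams:
    def test_bm_values(self, bm_micro, bm_dose, bm_macro):
        fit = PKFitResult(bm_micro, bm_macro, 0.0, 9, 0.0)
        d = derived_params(fit, 120.0)
        assert d.auc_inf == pytest.approx(4.76 / (0.21 * 0.25), rel=1e-9)
        assert d.auc_inf == pytest.approx(90.67, rel=1e-3)
        assert d.t_half_alpha == pytest.approx(math.log(2) / _ALPHA, rel=1e-12)
        assert d.t_half_alpha == pytest.approx(1.774, rel=1e-3)
        assert d.t_half_beta == pytest.approx(36.1, rel=2e-3)
        assert d.cl == pytest.approx(0.25 * 0.21, rel=1e-12)

    def test_auc_0_120_vs_trapezoid(self, bm_micro, bm_dose, bm_macro):
        fit = PKFitResult(bm_micro, bm_macro, 0.0, 9, 0.0)
        d = derived_params(fit, 120.0)
        t = np.linspace(0, 120, 2_000_001)
        c = predict_concentration(bm_macro, bm_dose, t)
        assert d.auc_0_T == pytest.approx(np.trapezoid(c, t), rel=1e-8)
        assert d.auc_0_T == pytest.approx(87.2, rel=1e-3)
        assert d.auc_0_T <= d.auc_inf

    @given(_micro_strategy())
    @settings(max_examples=100, deadline=None)
    def test_auc_inf_conservation(self, micro):
        dose = DoseEvent(3.0)
        macro = micro_to_macro(micro, dose)
        fit = PKFitResult(micro, macro, 0.0, 9, 0.0)
        d = derived_params(fit, 120.0)
        assert d.auc_inf == pytest.approx(dose.amount / (micro.V1 * micro.K10), rel=1e-9)
        assert d.t_half_alpha < d.t_half_beta

    def test_requires_two_compartments(self):
        micro = MicroParams(1, V1=0.5, K10=0.2)
        macro = micro_to_macro(micro, DoseEvent(2.0))
        fit = PKFitResult(micro, macro, 0.0, 9, 0.0)
        with pytest.raises(ValueError):
            derived_params(fit, 120.0)


class TestObservedMetrics:
    def test_plasma_schedule_tmax_is_first_sample(self, bm_dose, bm_macro):
        values = predict_concentration(bm_macro, bm_dose, PLASMA_TIMES)
        m = observed_metrics(_series(PLASMA_TIMES, values))
        assert m.t_max == 1.0
        assert m.c_max == pytest.approx(values[0])

    def test_earliest_tie(self):
        m = observed_metrics(_series([1.0, 3.0, 5.0], [5.0, 5.0, 2.0]))
        assert m.t_max == 1.0 and m.c_max == 5.0

    def test_breath_grid_membership(self):
        t = np.arange(1, 20) / 3.0
        values = np.exp(-0.3 * t) * 10
        m = observed_metrics(_series(t, values, matrix="breath", unit="ppbv"))
        assert (3 * m.t_max) == pytest.approx(round(3 * m.t_max))

    def test_all_censored_raises(self):
        flags = np.array(["excluded", "excluded"], dtype=object)
        with pytest.raises(MetricsUnavailableError):
            observed_metrics(_series([1.0, 2.0], [0.0, 0.0], flags=flags))


class TestValidation:
    def test_dose_event_invariants(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0)
        with pytest.raises(ValueError):
            DoseEvent(1.0, duration=-1.0)

    def test_micro_params_invariants(self):
        with pytest.raises(ValueError):
            MicroParams(2, V1=0.2, K10=0.1)  # missing exchange rates
        with pytest.raises(ValueError):
            MicroParams(1, V1=-0.2, K10=0.1)

    def test_macro_params_sorted_descending(self):
        with pytest.raises(ValueError):
            MacroParams((1.0, 2.0), (0.01, 0.4))
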
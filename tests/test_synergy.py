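"""Combination-index calculus, dose-response fitting and DRI recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopsyn import synthetic_data
from coopsyn.errors import (
    InsufficientDataError,
    NotReachedError,
    UndefinedCombinationEffectError,
    ValidationError,
)
from coopsyn.synergy import (
    DRIResult,
    EffectTriple,
    ci_bliss,
    ci_hsa,
    dri50,
    fit_dose_response,
    grid_ci,
    inhibition_from_viability,
)

effects = st.floats(0.0, 1.0, allow_nan=False)
positive_effects = st.floats(0.01, 1.0, allow_nan=False)


class TestEffects:
    @pytest.mark.parametrize(
        "viability,clamp,expected",
        [(1.0, True, 0.0), (0.25, True, 0.75), (1.2, True, 0.0), (1.2, False, pytest.approx(-0.2))],
    )
    def test_inhibition_complement_and_clamp(self, viability, clamp, expected):
        assert inhibition_from_viability(viability, clamp=clamp) == expected

    def test_non_finite_viability_rejected(self):
        with pytest.raises(ValidationError):
            inhibition_from_viability(float("nan"))

    def test_effects_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            EffectTriple(e_cur=1.2, e_opc=0.1, e_combo=0.5)


class TestCombinationIndices:
    @pytest.mark.parametrize(
        "triple,expected_ci,cooperative",
        [
            ((0.6, 0.4, 0.6), 1.0, False),   # combo equals the best single agent
            ((0.5, 0.2, 0.8), 0.625, True),
            ((0.0, 0.0, 0.5), 0.0, True),
        ],
    )
    def test_hsa_formula(self, triple, expected_ci, cooperative):
        res = ci_hsa(EffectTriple(*triple))
        assert res.ci == pytest.approx(expected_ci, abs=1e-12)
        assert res.cooperative is cooperative

    @pytest.mark.parametrize(
        "triple,expected_ci",
        [
            ((0.5, 0.5, 0.75), 1.0),   # 0.5 + 0.5 - 0.25 = 0.75 exactly
            ((0.4, 0.3, 0.8), 0.725),  # (0.7 - 0.12) / 0.8
            ((0.0, 0.0, 0.5), 0.0),
        ],
    )
    def test_bliss_formula(self, triple, expected_ci):
        assert ci_bliss(EffectTriple(*triple)).ci == pytest.approx(expected_ci, abs=1e-12)

    def test_zero_combination_effect_raises(self):
        with pytest.raises(UndefinedCombinationEffectError):
            ci_hsa(EffectTriple(0.3, 0.3, 0.0))

    @settings(derandomize=True, max_examples=200)
    @given(e_cur=effects, e_opc=effects, e_combo=positive_effects)
    def test_bliss_ci_dominates_hsa_ci(self, e_cur, e_opc, e_combo):
        """Bliss predicted effect >= max single effect, so Bliss CI >= HSA CI."""
        t = EffectTriple(e_cur, e_opc, e_combo)
        assert ci_bliss(t).ci >= ci_hsa(t).ci - 1e-12

    @settings(derandomize=True, max_examples=100)
    @given(e_cur=effects, e_opc=effects, lo=positive_effects, hi=positive_effects)
    def test_both_cis_decrease_in_combination_effect(self, e_cur, e_opc, lo, hi):
        lo, hi = sorted((lo, hi))
        if lo == hi:
            return
        for ci in (ci_hsa, ci_bliss):
            assert ci(EffectTriple(e_cur, e_opc, hi)).ci <= ci(EffectTriple(e_cur, e_opc, lo)).ci

    @settings(derandomize=True, max_examples=100)
    @given(e_cur=effects, e_opc=effects)
    def test_bliss_predicted_effect_stays_in_unit_interval(self, e_cur, e_opc):
        predicted = e_cur + e_opc - e_cur * e_opc
        assert -1e-12 <= predicted <= 1.0 + 1e-12


class TestDoseResponseFit:
    def test_recovers_noise_free_hill_curve(self):
        doses = np.array([2, 5, 12.5, 25, 50, 100, 250, 500], dtype=float)
        viab = 1.0 / (1.0 + doses / 50.0)
        fit = fit_dose_response(doses, viab)
        assert fit.fit_method == "four_parameter_logistic"
        assert 49.5 <= fit.ic50 <= 50.5
        assert fit.hill == pytest.approx(1.0, abs=0.01)

    def test_two_point_log_linear_interpolation(self):
        """Crossing between (10, 0.6) and (100, 0.4) sits at 10^1.5 on the log axis."""
        fit = fit_dose_response([10.0, 100.0], [0.6, 0.4])
        assert fit.fit_method == "interpolation"
        assert fit.ic50 == pytest.approx(10 ** 1.5, rel=1e-12)

    def test_ic50_not_reached(self):
        with pytest.raises(NotReachedError):
            fit_dose_response([1.0, 10.0, 100.0], [0.9, 0.8, 0.7])

    def test_single_dose_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_dose_response([10.0, 10.0], [0.6, 0.4])

    def test_replicates_averaged_before_fitting(self):
        fit = fit_dose_response([10, 10, 100, 100], [0.7, 0.5, 0.5, 0.3])
        assert fit.ic50 == pytest.approx(10 ** 1.5, rel=1e-12)


class TestDRI:
    def test_formula_and_beneficial_rule(self):
        res = DRIResult(agent="OPC", ic50_single=100.0, conc_in_combo_50=25.0)
        assert res.dri == pytest.approx(4.0)
        assert res.beneficial
        boundary = DRIResult(agent="OPC", ic50_single=100.0, conc_in_combo_50=100.0)
        assert boundary.dri == pytest.approx(1.0)
        assert not boundary.beneficial  # rule is strictly DRI > 1

    def test_recovers_planted_potency_shift(self):
        single, combo = synthetic_data.generate_dri_pair(
            ic50=100.0, shift=4.0, noise_sd=0.01, seed=12
        )
        fit = fit_dose_response(single["dose"], single["viability"])
        res = dri50(fit, combo["dose"], combo["viability"], agent="OPC")
        assert res.dri == pytest.approx(4.0, abs=0.2)

    def test_combo_never_reaching_50_raises(self):
        single, _ = synthetic_data.generate_dri_pair(ic50=100.0, noise_sd=0.0)
        fit = fit_dose_response(single["dose"], single["viability"])
        flat = [1.0, 10.0, 100.0], [0.95, 0.9, 0.85]
        with pytest.raises(NotReachedError):
            dri50(fit, *flat)


class TestGridCI:
    def test_bliss_identity_on_independent_grid(self, bliss_grid_noise_free):
        observed, _ = bliss_grid_noise_free
        ci = grid_ci(observed, method="bliss")
        assert len(ci) == 28  # 7 curcumin x 4 OPC doses
        assert np.max(np.abs(ci["ci"] - 1.0)) < 1e-9

    def test_planted_synergy_detected(self):
        cfg = synthetic_data.DoseResponseConfig(synergy_factor=1.3, noise_sd=0.02, seed=4)
        observed, _ = synthetic_data.generate_dose_response(cfg)
        ci = grid_ci(observed, method="bliss")
        assert ci["ci"].median() < 1.0

    def test_missing_single_agent_anchor_skipped_with_warning(self, bliss_grid_noise_free, caplog):
        observed, _ = bliss_grid_noise_free
        drop = (observed["dose_cur"] == 0) & (observed["dose_opc"] == 1000.0)
        with caplog.at_level("WARNING", logger="coopsyn.synergy"):
            ci = grid_ci(observed[~drop], method="bliss")
        assert (ci["dose_opc"] == 1000.0).sum() == 0
        assert len(ci) == 21
        assert any("no single-agent anchor" in r.message for r in caplog.records)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            grid_ci(pd.DataFrame())

    def test_both_methods_emitted(self, bliss_grid_noise_free):
        observed, _ = bliss_grid_noise_free
        ci = grid_ci(observed, method="both")
        assert set(ci["method"]) == {"hsa", "bliss"}
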
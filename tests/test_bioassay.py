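"""Bioassay math: inhibition rate, IC50 fit, ddCt, flow statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.bioassay import (
    DoseResponseDataset,
    FlowEventTable,
    QpcrAssay,
    QuadrantSummary,
    apoptotic_fraction,
    classify_quadrants,
    compare_groups,
    dose_trend_test,
    fit_dose_response,
    fit_dose_response_points,
    fold_change_ddct,
    four_parameter_logistic,
    inhibition_rate,
    jc1_depolarized_fraction,
    jc1_excluded_events,
)
from netpharm.errors import UndefinedRatioError, ValidationError
from netpharm.synthetic import SimulationConfig, simulate_dose_response


class TestInhibitionRate:
    @pytest.mark.parametrize("a0,a,expected", [
        (0.8, 0.8, 0.0), (0.8, 0.0, 100.0), (0.8, 0.6, 25.0), (0.8, 1.0, -25.0),
    ])
    def test_arithmetic(self, a0, a, expected):
        assert inhibition_rate(a0, a) == pytest.approx(expected)

    @given(a0=st.floats(0.01, 10), a=st.floats(0, 10), c=st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, a0, a, c):
        assert inhibition_rate(c * a0, c * a) == pytest.approx(
            inhibition_rate(a0, a), abs=1e-9
        )

    def test_nonpositive_control_rejected(self):
        with pytest.raises(UndefinedRatioError):
            inhibition_rate(0.0, 0.5)


class TestDoseResponseFit:
    def _dataset(self, ic50=13.61, hill=1.5, noise_sd=0.0, seed=0):
        return simulate_dose_response(
            SimulationConfig(seed=seed, ic50=ic50, hill=hill, noise_sd=noise_sd)
        )

    def test_noiseless_recovery_within_one_percent(self):
        sim = self._dataset()
        fit = fit_dose_response(sim.data)
        assert fit.converged
        assert abs(fit.ic50 - 13.61) / 13.61 < 0.01
        assert fit.hill == pytest.approx(1.5, rel=0.02)
        assert fit.bottom <= fit.top

    def test_constant_response_is_non_identifiable(self):
        dataset = DoseResponseDataset(
            readings={0.0: (0.8,), 1.0: (0.6,), 2.0: (0.6,), 4.0: (0.6,)}
        )
        assert fit_dose_response(dataset).converged is False

    def test_too_few_positive_doses_rejected(self):
        dataset = DoseResponseDataset(readings={0.0: (0.8,), 1.0: (0.6,)})
        with pytest.raises(ValidationError):
            fit_dose_response(dataset)

    def test_inhibition_and_viability_give_same_ic50(self):
        """y and 100 - y describe the same transition dose."""
        sim = self._dataset(noise_sd=2.0, seed=5)
        doses, responses = [], []
        from netpharm.bioassay import inhibition_profile

        profile = inhibition_profile(sim.data, per_replicate=True)
        for d, reps in profile.items():
            doses.extend([d] * len(reps))
            responses.extend(reps)
        fit_inh = fit_dose_response_points(doses, responses)
        fit_via = fit_dose_response_points(doses, [100 - y for y in responses])
        assert fit_inh.ic50 == pytest.approx(fit_via.ic50, abs=1e-6)

    def test_bias_vanishes_as_noise_vanishes(self):
        errors = []
        for sd in (4.0, 1.0, 0.0):
            fits = [
                fit_dose_response(self._dataset(noise_sd=sd, seed=s).data)
                for s in range(5)
            ]
            errors.append(np.median([abs(f.ic50 - 13.61) for f in fits]))
        assert errors[2] < errors[0]
        assert errors[2] / 13.61 < 1e-4


class TestFoldChange:
    def _assay(self, cts):
        return QpcrAssay(ct=cts, reference_gene="GAPDH", control_group="control")

    def test_all_means_equal_gives_unity(self):
        cts = {}
        for gene in ("Bad", "GAPDH"):
            for grp in ("control", "treated"):
                cts[(gene, grp, 1)] = 20.0
        assert fold_change_ddct(self._assay(cts), "Bad", "treated") == 1.0

    def test_ddct_of_one_halves_expression(self):
        cts = {("GAPDH", "control", 1): 18.0, ("GAPDH", "treated", 1): 18.0,
               ("Bad", "control", 1): 24.0, ("Bad", "treated", 1): 25.0}
        assert fold_change_ddct(self._assay(cts), "Bad", "treated") == 0.5

    def test_replicate_means_are_used(self):
        cts = {("GAPDH", "control", 1): 18.0, ("GAPDH", "treated", 1): 18.0,
               ("Bad", "control", 1): 24.0, ("Bad", "control", 2): 26.0,
               ("Bad", "treated", 1): 24.0, ("Bad", "treated", 2): 24.0}
        # control mean 25, treated mean 24 -> ddCt = -1 -> fold 2
        assert fold_change_ddct(self._assay(cts), "Bad", "treated") == 2.0

    @given(shift=st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_plate_shift(self, shift):
        base = {("GAPDH", "control", 1): 18.0, ("GAPDH", "treated", 1): 18.4,
                ("Bad", "control", 1): 24.0, ("Bad", "treated", 1): 22.7}
        shifted = {k: v + shift for k, v in base.items()}
        assert fold_change_ddct(self._assay(shifted), "Bad", "treated") == \
            pytest.approx(fold_change_ddct(self._assay(base), "Bad", "treated"))

    def test_missing_reference_rejected(self):
        cts = {("Bad", "control", 1): 24.0, ("Bad", "treated", 1): 23.0,
               ("GAPDH", "control", 1): 18.0}
        with pytest.raises(ValidationError):
            fold_change_ddct(self._assay(cts), "Bad", "treated")


class TestQuadrants:
    def test_all_double_negative(self):
        table = FlowEventTable(events=np.full((50, 2), 10.0), thresholds=(100, 100))
        assert classify_quadrants(table).fractions["Q3"] == 1.0

    def test_one_event_per_quadrant(self):
        events = np.array([[200, 200], [10, 200], [10, 10], [200, 10]], float)
        summary = classify_quadrants(FlowEventTable(events, thresholds=(100, 100)))
        assert all(f == 0.25 for f in summary.fractions.values())

    def test_intensity_at_gate_counts_negative(self):
        events = np.array([[100.0, 100.0]])
        summary = classify_quadrants(FlowEventTable(events, thresholds=(100, 100)))
        assert summary.fractions["Q3"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        events = rng.lognormal(4.5, 1.0, size=(5000, 2))
        summary = classify_quadrants(FlowEventTable(events, thresholds=(100, 100)))
        assert math.fsum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_events_rejected(self):
        table = FlowEventTable(events=np.empty((0, 2)), thresholds=(100, 100))
        with pytest.raises(UndefinedRatioError):
            classify_quadrants(table)


class TestApoptoticFraction:
    def test_modes(self):
        summary = QuadrantSummary(
            fractions={"Q1": 0.25, "Q2": 0.25, "Q3": 0.25, "Q4": 0.25}
        )
        assert apoptotic_fraction(summary, "early") == 0.25
        assert apoptotic_fraction(summary, "total") == 0.5
        viable = QuadrantSummary(fractions={"Q1": 0, "Q2": 0, "Q3": 1.0, "Q4": 0})
        assert apoptotic_fraction(viable, "total") == 0.0

    def test_unknown_mode_rejected(self):
        summary = QuadrantSummary(fractions={"Q1": 1.0, "Q2": 0, "Q3": 0, "Q4": 0})
        with pytest.raises(ValidationError):
            apoptotic_fraction(summary, "late")


class TestJc1:
    def test_all_polarized_gives_zero(self):
        monomer = np.full(100, 50.0)
        events = np.column_stack([monomer, monomer * 5.0])
        table = FlowEventTable(events, thresholds=(100, 100))
        assert jc1_depolarized_fraction(table, ratio_threshold=1.0) == 0.0

    def test_all_monomeric_gives_one(self):
        monomer = np.full(100, 500.0)
        events = np.column_stack([monomer, monomer * 0.01])
        table = FlowEventTable(events, thresholds=(100, 100))
        assert jc1_depolarized_fraction(table, ratio_threshold=1.0) == 1.0

    def test_zero_monomer_events_excluded(self):
        events = np.array([[0.0, 5.0], [100.0, 10.0]])
        table = FlowEventTable(events, thresholds=(100, 100))
        assert jc1_excluded_events(table) == 1
        assert jc1_depolarized_fraction(table) == 1.0

    def test_no_usable_events_rejected(self):
        table = FlowEventTable(np.array([[0.0, 5.0]]), thresholds=(100, 100))
        with pytest.raises(UndefinedRatioError):
            jc1_depolarized_fraction(table)


class TestDoseTrend:
    def test_clean_decreasing_trend_is_significant(self):
        values = {d: [100 - 10 * i + r for r in (0.0, 0.1, -0.1)]
                  for i, d in enumerate((1.0, 2.0, 4.0, 8.0))}
        result = dose_trend_test(values, n_permutations=10_000, seed=1)
        assert result.statistic < -0.9
        assert result.p_value < 0.05

    def test_constant_responses_give_zero_statistic(self):
        values = {d: [5.0, 5.0] for d in (1.0, 2.0, 4.0)}
        result = dose_trend_test(values)
        assert result.statistic == 0.0 and result.p_value == 1.0

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValidationError):
            dose_trend_test({1.0: [1, 2], 2.0: [3, 4]})

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError):
            dose_trend_test({1.0: [1], 2.0: [3, 4], 4.0: [5, 6]})

    def test_same_seed_same_p_value(self):
        rng = np.random.default_rng(2)
        values = {d: list(rng.normal(size=3)) for d in (1.0, 2.0, 4.0, 8.0)}
        a = dose_trend_test(values, n_permutations=500, seed=7)
        b = dose_trend_test(values, n_permutations=500, seed=7)
        assert a.p_value == b.p_value and a.statistic == b.statistic


def test_welch_comparison_flags_separated_groups():
    t, p = compare_groups([1.0, 1.1, 0.9], [3.0, 3.2, 2.8])
    assert p < 0.01 and t < 0


def test_4pl_midpoint_is_half_maximal():
    y = four_parameter_logistic(13.61, 13.61, 1.5, 100.0, 0.0)
    assert y == pytest.approx(50.0)
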
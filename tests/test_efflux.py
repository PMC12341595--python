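"""Efflux statistic, background corrections, WT testing and categorization."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from abca1func.config import CalibrationConfig
from abca1func.efflux import (
    LOSS_OF_FUNCTION,
    NORMAL,
    UNCERTAIN,
    EffluxMeasurement,
    categorize,
    compare_to_wt,
    corrected_efflux,
    normalize_to_wt,
    raw_efflux,
    run_efflux_pipeline,
    specific_efflux,
)
from abca1func.errors import (
    ConfigurationError,
    InsufficientReplicatesError,
    NormalizationError,
    PairingError,
    UndefinedEffluxError,
)
from abca1func.simulate import GeneratorSpec, generate_plates
from abca1func.stats import f_test_equal_variances, gated_ttest


def wellset(construct, exp, condition, medium, lysate, treatment="mock_treatment"):
    return EffluxMeasurement(
        construct_id=construct, experiment_id=exp, condition=condition,
        treatment=treatment, medium_signals=tuple(medium),
        lysate_signals=tuple(lysate),
    )


class TestRawEfflux:
    def test_stated_formula(self):
        assert raw_efflux((300, 300, 300), (700, 700, 700)) == pytest.approx(0.30)

    def test_zero_medium_gives_zero(self):
        assert raw_efflux((0, 0, 0), (700, 700, 700)) == 0.0

    def test_matches_direct_evaluation_on_noisy_triplicates(self):
        medium, lysate = (250, 310, 340), (720, 690, 710)
        expected = (sum(medium) / 3) / (sum(medium) / 3 + sum(lysate) / 3)
        assert raw_efflux(medium, lysate) == pytest.approx(expected, abs=1e-15)

    def test_all_zero_signals_is_undefined(self):
        with pytest.raises(UndefinedEffluxError):
            raw_efflux((0, 0, 0), (0, 0, 0))

    @given(
        medium=st.lists(st.floats(0, 1e6), min_size=1, max_size=3),
        lysate=st.lists(st.floats(0, 1e6), min_size=1, max_size=3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_fraction_stays_in_unit_interval(self, medium, lysate):
        if sum(medium) + sum(lysate) == 0:
            return
        assert 0.0 <= raw_efflux(medium, lysate) <= 1.0


class TestCorrections:
    def test_leakage_subtraction(self):
        acc = wellset("v", "E1", "acceptor", (300, 300, 300), (700, 700, 700))
        na = wellset("v", "E1", "no_acceptor", (50, 50, 50), (950, 950, 950))
        assert corrected_efflux(acc, na) == pytest.approx(0.25)

    def test_self_subtraction_is_zero(self):
        acc = wellset("v", "E1", "acceptor", (300, 310, 290), (700, 690, 710))
        na = wellset("v", "E1", "no_acceptor", (300, 310, 290), (700, 690, 710))
        assert corrected_efflux(acc, na) == pytest.approx(0.0)

    def test_stepwise_oracle_on_random_triplicates(self):
        rng = np.random.default_rng(11)
        m1, l1 = rng.uniform(100, 900, 3), rng.uniform(100, 900, 3)
        m2, l2 = rng.uniform(10, 200, 3), rng.uniform(500, 900, 3)
        acc = wellset("v", "E1", "acceptor", m1, l1)
        na = wellset("v", "E1", "no_acceptor", m2, l2)
        expected = raw_efflux(m1, l1) - raw_efflux(m2, l2)
        assert corrected_efflux(acc, na) == pytest.approx(expected, abs=1e-15)

    def test_construct_mismatch_raises(self):
        acc = wellset("v1", "E1", "acceptor", (1, 1, 1), (9, 9, 9))
        na = wellset("v2", "E1", "no_acceptor", (1, 1, 1), (9, 9, 9))
        with pytest.raises(PairingError):
            corrected_efflux(acc, na)

    def test_specific_efflux_subtracts_mock(self):
        assert specific_efflux(0.25, 0.03) == pytest.approx(0.22)
        assert specific_efflux(0.03, 0.03) == 0.0


class TestNormalizeToWt:
    def test_ratio_times_100(self):
        rel = normalize_to_wt({"E1": 0.11}, {"E1": 0.22})
        assert rel == {"E1": pytest.approx(50.0)}

    def test_wt_normalizes_to_100_per_experiment(self):
        wt = {"E1": 0.2, "E2": 0.31, "E3": 0.18}
        rel = normalize_to_wt(wt, wt)
        assert all(v == pytest.approx(100.0) for v in rel.values())

    def test_mean_sd_match_two_pass_oracle(self):
        construct = {"E1": 0.10, "E2": 0.12, "E3": 0.09, "E4": 0.11}
        wt = {"E1": 0.20, "E2": 0.21, "E3": 0.22, "E4": 0.19}
        rel = list(normalize_to_wt(construct, wt).values())
        ratios = [100 * construct[e] / wt[e] for e in ("E1", "E2", "E3", "E4")]
        assert statistics.mean(rel) == pytest.approx(statistics.mean(ratios))
        assert statistics.stdev(rel) == pytest.approx(statistics.stdev(ratios))

    def test_nonpositive_wt_experiments_are_dropped(self, caplog):
        rel = normalize_to_wt({"E1": 0.1, "E2": 0.1}, {"E1": 0.2, "E2": -0.01})
        assert list(rel) == ["E1"]

    def test_all_experiments_excluded_raises(self):
        with pytest.raises(NormalizationError):
            normalize_to_wt({"E1": 0.1}, {"E1": 0.0})


class TestCompareToWt:
    def test_identical_groups_give_p_one(self):
        vals = [10.0, 11.0, 12.0, 13.0]
        assert compare_to_wt(vals, vals) == pytest.approx(1.0)

    def test_pooled_branch_matches_reference_implementation(self):
        a, b = [10.0, 11.0, 12.0, 13.0], [20.0, 21.0, 22.0, 23.0]
        assert f_test_equal_variances(a, b) == pytest.approx(1.0)
        expected = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert compare_to_wt(a, b) == pytest.approx(expected, rel=1e-12)

    def test_unequal_variances_take_welch_branch(self):
        rng = np.random.default_rng(5)
        a = list(10 + 0.1 * rng.standard_normal(6))
        b = list(10 + 10.0 * rng.standard_normal(6))
        # independent check that the variance gate trips
        f = np.var(a, ddof=1) / np.var(b, ddof=1)
        p_f = 2 * min(sps.f.cdf(f, 5, 5), sps.f.sf(f, 5, 5))
        assert p_f < 0.05
        expected = sps.ttest_ind(a, b, equal_var=False).pvalue
        assert compare_to_wt(a, b) == pytest.approx(expected, rel=1e-12)

    def test_one_tailed_direction(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        p_less = compare_to_wt(a, b, tails="one", direction="less")
        p_greater = compare_to_wt(a, b, tails="one", direction="greater")
        assert p_less < 0.01 and p_greater > 0.99

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            compare_to_wt([1.0], [1.0, 2.0])

    def test_zero_variance_wt_group_is_handled(self):
        # normalized WT reference: exactly 100 in every experiment
        p, equal = gated_ttest([80.0, 82.0, 79.0, 81.0], [100.0] * 4,
                               alternative="less")
        assert 0.0 < p < 0.01 and equal is False


class TestCategorize:
    @pytest.mark.parametrize(
        ("mean", "category"),
        [
            (84.0, NORMAL),
            (9.0, LOSS_OF_FUNCTION),
            (58.0, UNCERTAIN),
            (41.0, UNCERTAIN),   # boundary stays uncertain
            (80.0, UNCERTAIN),   # boundary stays uncertain
            (40.99, LOSS_OF_FUNCTION),
            (80.01, NORMAL),
        ],
    )
    def test_default_thresholds(self, mean, category, config):
        assert categorize(mean, config) == category

    def test_alternative_cutoff_boundary(self, config):
        assert categorize(58.0, config, use_alternative=True) == UNCERTAIN
        assert categorize(57.9, config, use_alternative=True) == LOSS_OF_FUNCTION
        assert categorize(58.0, config) == UNCERTAIN

    @given(
        lo=st.floats(0, 120, allow_nan=False),
        delta=st.floats(0, 50, allow_nan=False),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_the_mean(self, lo, delta):
        config = CalibrationConfig()
        rank = {LOSS_OF_FUNCTION: 0, UNCERTAIN: 1, NORMAL: 2}
        assert rank[categorize(lo + delta, config)] >= rank[categorize(lo, config)]


class TestPipeline:
    def test_zero_noise_recovers_truth_exactly(self, config):
        spec = GeneratorSpec(
            seed=0, well_sigma=0.0, experiment_jitter_sigma=0.0,
            activities={"p.V1A": 50.0},
        )
        (result,) = run_efflux_pipeline(generate_plates(spec), config)
        assert result.mean_relative_efflux == pytest.approx(50.0, abs=1e-9)
        assert result.sd == pytest.approx(0.0, abs=1e-9)
        assert result.category == UNCERTAIN

    def test_invariant_to_row_order(self, config):
        spec = GeneratorSpec(seed=3)
        plates = generate_plates(spec)
        forward = run_efflux_pipeline(plates, config)
        backward = run_efflux_pipeline(list(reversed(plates)), config)
        for a, b in zip(forward, backward):
            assert a.construct_id == b.construct_id
            assert a.mean_relative_efflux == pytest.approx(b.mean_relative_efflux)

    def test_invariant_to_per_experiment_rescaling(self, config):
        spec = GeneratorSpec(seed=4)
        plates = generate_plates(spec)
        scale = {"E1": 3.0, "E2": 0.5, "E3": 10.0, "E4": 1.7}
        rescaled = [
            EffluxMeasurement(
                construct_id=m.construct_id, experiment_id=m.experiment_id,
                condition=m.condition, treatment=m.treatment,
                medium_signals=tuple(s * scale[m.experiment_id]
                                     for s in m.medium_signals),
                lysate_signals=tuple(s * scale[m.experiment_id]
                                     for s in m.lysate_signals),
            )
            for m in plates
        ]
        for a, b in zip(run_efflux_pipeline(plates, config),
                        run_efflux_pipeline(rescaled, config)):
            assert a.mean_relative_efflux == pytest.approx(
                b.mean_relative_efflux, rel=1e-12
            )
            assert a.category == b.category

    def test_noisy_estimate_is_near_truth(self, config):
        spec = GeneratorSpec(seed=8, activities={"p.V1A": 60.0}, well_sigma=0.10)
        (result,) = run_efflux_pipeline(generate_plates(spec), config)
        assert result.mean_relative_efflux == pytest.approx(60.0, abs=10.0)
        assert result.n_experiments == 4
        assert result.p_value is not None and 0.0 <= result.p_value <= 1.0

    def test_missing_mock_is_a_configuration_error(self, config):
        spec = GeneratorSpec(seed=0, activities={"p.V1A": 50.0})
        plates = [m for m in generate_plates(spec) if m.construct_id != "mock"]
        with pytest.raises(ConfigurationError, match="mock"):
            run_efflux_pipeline(plates, config)

    def test_missing_wt_is_a_configuration_error(self, config):
        spec = GeneratorSpec(seed=0, activities={"p.V1A": 50.0})
        plates = [m for m in generate_plates(spec) if m.construct_id != "WT"]
        with pytest.raises(ConfigurationError, match="WT"):
            run_efflux_pipeline(plates, config)
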
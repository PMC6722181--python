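import math

import numpy as np
import pytest

from fetcea import (
    ResponseStatus,
    classify_cohort,
    effectiveness,
    estimate_chance_nodes,
)
from fetcea.synthetic import (
    SurvivalStratum,
    SyntheticConfig,
    expected_chance_nodes,
    generate,
    table1_like_config,
)

NR = ResponseStatus.NON_RESPONDER


class TestDeterminismAndInvariants:
    def test_fixed_seed_reproduces_cohort(self):
        config = table1_like_config(n_patients=40, seed=123)
        assert generate(config) == generate(config)

    def test_different_seeds_differ(self):
        a = generate(table1_like_config(seed=1))
        b = generate(table1_like_config(seed=2))
        assert a != b

    def test_survival_ordering_and_record_validity(self):
        cohort = generate(table1_like_config(n_patients=300, seed=5))
        assert all(p.pfs_months <= p.os_months for p in cohort)
        assert all(p.os_months > 0 for p in cohort)

    def test_guard_band_keeps_measurements_off_the_boundaries(self):
        cohort = generate(table1_like_config(n_patients=500, seed=6))
        for p in cohort:
            if p.tbr_max_1 is not None and p.tbr_max_2 is not None:
                ratio = p.tbr_max_2 / p.tbr_max_1
                assert not 0.78 < ratio < 0.82

    def test_missingness_rates_applied(self):
        config = table1_like_config(n_patients=2_000, seed=7)
        cohort = generate(config)
        pet_missing = sum(p.tbr_max_2 is None for p in cohort) / len(cohort)
        mri_missing = sum(p.gd_vol_2 is None for p in cohort) / len(cohort)
        assert abs(pet_missing - 2 / 25) < 0.02
        assert abs(mri_missing - 4 / 25) < 0.03


class TestParameterRecovery:
    def test_configured_sensitivity_recovered_at_scale(self):
        """With a large cohort the empirical fraction of true
        non-responders flagged by PET converges to the configured
        sensitivity (law of large numbers)."""
        config = SyntheticConfig(
            n_patients=50_000,
            os_nonresponder_prevalence=0.4,
            pet_sensitivity=0.9,
            seed=11,
        )
        classified = classify_cohort(generate(config))
        true_nr = [c for c in classified if c.os_endpoint is NR]
        flagged = sum(c.pet is NR for c in true_nr)
        assert abs(flagged / len(true_nr) - 0.9) < 0.01

    def test_all_chance_nodes_converge_to_closed_form(self):
        config = SyntheticConfig(
            n_patients=50_000,
            os_nonresponder_prevalence=0.35,
            pet_sensitivity=0.88,
            pet_specificity=0.72,
            mri_sensitivity=0.55,
            mri_specificity=0.80,
            pet_missing_rate=0.05,
            mri_missing_rate=0.10,
            seed=12,
        )
        classified = classify_cohort(generate(config))
        nodes = estimate_chance_nodes(classified, "os")
        targets = expected_chance_nodes(config)
        for name, target in targets.items():
            node = getattr(nodes, name)
            se = math.sqrt(target * (1 - target) / node.denominator)
            assert abs(node.probability - target) <= 3 * se + 1e-12, name


class TestTable1LikeConfig:
    def test_large_sample_matches_reference_tree(self):
        classified = classify_cohort(
            generate(table1_like_config(n_patients=50_000, seed=13))
        )
        nodes = estimate_chance_nodes(classified, "os")
        assert abs(nodes.n1.probability - 0.4348) < 0.01
        assert abs(nodes.n2.probability - 2 / 3) < 0.01
        eff = effectiveness(nodes)
        assert abs(eff.delta_nr - 0.5714) < 0.03

    def test_small_draw_is_a_valid_pipeline_input(self):
        classified = classify_cohort(generate(table1_like_config(seed=14)))
        assert len(classified) == 25
        # all stages accept it (smoke through the tree)
        estimate_chance_nodes(classified, "pfs")


class TestConfigValidation:
    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="pet_sensitivity"):
            SyntheticConfig(pet_sensitivity=1.2)

    def test_bad_endpoint_rejected(self):
        with pytest.raises(ValueError, match="call_endpoint"):
            SyntheticConfig(call_endpoint="orr")

    def test_infeasible_survival_stratum_errors(self):
        strata = {
            "os_responder": SurvivalStratum(median=0.5, sigma=0.05),  # never > 10
            "os_non_responder": SurvivalStratum(median=7.0, sigma=0.35),
            "pfs_responder": SurvivalStratum(median=11.0, sigma=0.35),
            "pfs_non_responder": SurvivalStratum(median=4.5, sigma=0.35),
        }
        config = SyntheticConfig(n_patients=5, survival=strata, seed=15)
        with pytest.raises(ValueError, match="cut-off"):
            generate(config)

    def test_nonpositive_stratum_rejected(self):
        with pytest.raises(ValueError):
            SurvivalStratum(median=-1.0, sigma=0.3)


def test_expected_chance_nodes_oracle_is_bayes_consistent():
    """The closed-form targets are a coherent distribution: call
    probability times PPV plus complement times NPV recovers the
    marginal truth probabilities."""
    config = SyntheticConfig(
        os_nonresponder_prevalence=0.3,
        pet_sensitivity=0.8,
        pet_specificity=0.7,
        mri_sensitivity=0.6,
        mri_specificity=0.9,
    )
    t = expected_chance_nodes(config)
    # P(true R) reconstructed from the PET arm
    p_true_r = t["n1"] * t["n3"] + (1 - t["n1"]) * (1 - t["n4"])
    assert np.isclose(p_true_r, 0.7)
    p_true_r_mri = t["n2"] * t["n5"] + (1 - t["n2"]) * (1 - t["n6"])
    assert np.isclose(p_true_r_mri, 0.7)
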
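import math

import pytest
from hypothesis import given, strategies as st

from fetcea import (
    ClassifiedPatient,
    ResponseStatus,
    UndefinedEffectivenessError,
    UndefinedNodeError,
    effectiveness,
    effectiveness_by_count,
    estimate_chance_nodes,
    event_probabilities,
)
from fetcea.tree import nr_identification_rate
from fetcea.synthetic import SyntheticConfig, generate
from fetcea.classify import classify_cohort

R = ResponseStatus.RESPONDER
NR = ResponseStatus.NON_RESPONDER

# (node, numerator, denominator) per endpoint; probabilities round to
# the published 4-decimal node values (N1-N6 per decision tree)
EXPECTED_NODES = {
    "os": {
        "n1": (10, 23, 0.4348),
        "n2": (14, 21, 0.6667),
        "n3": (10, 10, 1.0000),
        "n4": (9, 13, 0.6923),
        "n5": (10, 14, 0.7143),
        "n6": (3, 7, 0.4286),
    },
    "pfs": {
        "n1": (10, 23, 0.4348),
        "n2": (14, 21, 0.6667),
        "n3": (7, 10, 0.7000),
        "n4": (7, 13, 0.5385),
        "n5": (7, 14, 0.5000),
        "n6": (1, 7, 0.1429),
    },
}


class TestChanceNodes:
    @pytest.mark.parametrize("endpoint", ["os", "pfs"])
    def test_counts_and_four_decimal_values(self, request, endpoint):
        nodes = request.getfixturevalue(f"nodes_{endpoint}")
        for name, (num, den, rounded) in EXPECTED_NODES[endpoint].items():
            node = getattr(nodes, name)
            assert (node.numerator, node.denominator) == (num, den), name
            assert round(node.probability, 4) == rounded, name

    def test_degenerate_stratum_raises(self):
        two_responders = (
            ClassifiedPatient(1, R, R, R, R),
            ClassifiedPatient(2, R, R, R, R),
        )
        with pytest.raises(UndefinedNodeError, match="N4"):
            estimate_chance_nodes(two_responders, "os")


class TestEventProbabilities:
    def test_outcomes_sum_to_one_per_modality(self, nodes_os, nodes_pfs):
        for nodes in (nodes_os, nodes_pfs):
            for outcome in event_probabilities(nodes).values():
                assert math.isclose(sum(outcome.values()), 1.0, rel_tol=1e-12)

    def test_joint_probabilities_match_direct_counts(self, nodes_os):
        ev = event_probabilities(nodes_os)
        # 9 of 23 PET-available patients are concordant non-responders
        assert math.isclose(ev["pet"]["call_nr_true_nr"], 9 / 23, rel_tol=1e-12)
        # 3 of 21 MRI-available patients are concordant non-responders
        assert math.isclose(ev["mri"]["call_nr_true_nr"], 1 / 7, rel_tol=1e-12)


class TestEffectiveness:
    def test_os_tree_identification_rates(self, nodes_os):
        eff = effectiveness(nodes_os)
        assert eff.pet_nr_identification == 1.0
        assert round(eff.mri_nr_identification, 4) == 0.4286
        assert round(eff.delta_nr, 4) == 0.5714

    def test_pfs_tree_identification_rates(self, nodes_pfs):
        eff = effectiveness(nodes_pfs)
        assert math.isclose(eff.pet_nr_identification, 0.70, rel_tol=1e-12)
        assert math.isclose(eff.mri_nr_identification, 0.125, rel_tol=1e-12)
        assert math.isclose(eff.delta_nr, 0.575, rel_tol=1e-12)

    def test_diagnostic_accuracy(self, nodes_os, nodes_pfs):
        eff = effectiveness(nodes_os)
        assert math.isclose(eff.pet_accuracy, 19 / 23, rel_tol=1e-12)
        assert math.isclose(eff.mri_accuracy, 13 / 21, rel_tol=1e-12)
        # PFS tree: 7 concordant responders + 7 concordant non-responders
        assert math.isclose(
            effectiveness(nodes_pfs).pet_accuracy, 14 / 23, rel_tol=1e-12
        )

    def test_zero_true_nonresponder_probability_raises(self):
        nodes = {"n1": 1.0, "n2": 0.5, "n3": 1.0, "n4": 0.5, "n5": 0.5, "n6": 0.5}
        with pytest.raises(UndefinedEffectivenessError):
            effectiveness(nodes, "os")


class TestCountVersusNodeRoute:
    """The direct-counting oracle must agree with the node algebra."""

    @pytest.mark.parametrize("endpoint", ["os", "pfs"])
    def test_exact_agreement_on_reference_cohort(self, classified, endpoint):
        nodes = estimate_chance_nodes(classified, endpoint)
        assert effectiveness(nodes) == effectiveness_by_count(classified, endpoint)

    @pytest.mark.parametrize("seed", range(25))
    def test_exact_agreement_on_synthetic_cohorts(self, seed):
        config = SyntheticConfig(
            n_patients=60,
            os_nonresponder_prevalence=0.45,
            pet_sensitivity=0.85,
            pet_specificity=0.75,
            mri_sensitivity=0.55,
            mri_specificity=0.65,
            pet_missing_rate=0.1,
            mri_missing_rate=0.1,
            seed=seed,
        )
        classified = classify_cohort(generate(config))
        nodes = estimate_chance_nodes(classified, "os")
        assert effectiveness(nodes) == effectiveness_by_count(classified, "os")


class TestIdentificationRateAlgebra:
    @given(
        R_=st.floats(0.05, 0.95),
        q=st.floats(0.05, 1.0),
        p=st.floats(0.0, 1.0),
    )
    def test_perfect_ppv_gives_perfect_identification(self, R_, q, p):
        """With p = 1 no true non-responder is ever called a responder."""
        assert nr_identification_rate(R_, 1.0, q) == 1.0

    @given(
        R_=st.floats(0.05, 0.95),
        p1=st.floats(0.0, 0.99),
        p2=st.floats(0.0, 0.99),
        q=st.floats(0.05, 1.0),
    )
    def test_monotone_nondecreasing_in_p(self, R_, p1, p2, q):
        """Raising the responder-call PPV shrinks the missed-NR term."""
        lo, hi = sorted((p1, p2))
        assert nr_identification_rate(R_, lo, q) <= nr_identification_rate(
            R_, hi, q
        ) + 1e-12

    @given(
        R_=st.floats(0.05, 0.95),
        p=st.floats(0.0, 0.95),
        q1=st.floats(0.01, 1.0),
        q2=st.floats(0.01, 1.0),
    )
    def test_monotone_nondecreasing_in_q(self, R_, p, q1, q2):
        lo, hi = sorted((q1, q2))
        assert nr_identification_rate(R_, p, lo) <= nr_identification_rate(
            R_, p, hi
        ) + 1e-12
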
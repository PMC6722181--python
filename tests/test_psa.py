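import math

import numpy as np
import pytest

from fetcea import (
    CostParameters,
    MCConfig,
    effectiveness,
    psa_convergence,
    relative_frequency_histogram,
    run_psa,
    sample_draws,
)

ZERO_SDS = {k: 0.0 for k in ("n1", "n2", "n3", "n4", "n5", "n6")}


def _config(nodes, **kwargs):
    return MCConfig.from_nodes(nodes, **kwargs)


class TestReproducibility:
    def test_fixed_seed_gives_identical_summaries(self, nodes_os):
        config = _config(nodes_os, draws=2_000, seed=42)
        assert run_psa(config, endpoint="os") == run_psa(config, endpoint="os")

    def test_different_seeds_differ(self, nodes_os):
        a = run_psa(_config(nodes_os, draws=2_000, seed=1), endpoint="os")
        b = run_psa(_config(nodes_os, draws=2_000, seed=2), endpoint="os")
        assert a.icer.mean != b.icer.mean


class TestZeroVariance:
    def test_degenerate_distribution_equals_deterministic_pipeline(self, nodes_os):
        config = _config(
            nodes_os, draws=500, seed=0, node_sds=ZERO_SDS, scans_sd=0.0
        )
        summary = run_psa(config, CostParameters(model="fixed"), endpoint="os")
        eff = effectiveness(nodes_os.probabilities(), "os")
        expected_icer = 780.50 / eff.delta_nr
        # every draw is the base case: extrema are bit-exact, mean and
        # sd only up to summation rounding over identical values
        assert summary.cost.minimum == summary.cost.maximum == 780.50
        assert summary.icer.minimum == summary.icer.maximum == expected_icer
        assert math.isclose(summary.icer.mean, expected_icer, rel_tol=1e-12)
        assert summary.icer.sd < 1e-9 and summary.delta_nr.sd < 1e-12


class TestSampling:
    def test_node_draws_stay_in_unit_interval(self, nodes_os):
        for bounding in ("clip", "resample"):
            frame = sample_draws(_config(nodes_os, draws=3_000, seed=3, bounding=bounding))
            for name in ("n1", "n2", "n3", "n4", "n5", "n6"):
                assert frame[name].between(0.0, 1.0).all(), (bounding, name)

    def test_clipping_leaves_mass_at_the_bound(self, nodes_os):
        """Tree 1's N3 sits exactly at 1, so clipping keeps about half
        of its draws at the bound while resampling keeps none."""
        clip = sample_draws(_config(nodes_os, draws=4_000, seed=4, bounding="clip"))
        resample = sample_draws(
            _config(nodes_os, draws=4_000, seed=4, bounding="resample")
        )
        assert 0.4 < (clip["n3"] == 1.0).mean() < 0.6
        assert (resample["n3"] < 1.0).all()

    def test_tree1_delta_bounded_and_pulled_below_base(self, nodes_os):
        frame = sample_draws(_config(nodes_os, draws=10_000, seed=5))
        delta = frame["delta_nr"].dropna()
        assert (delta <= 1.0).all()
        assert delta.mean() < 1.0 - 3 / 7  # asymmetric clipping of N3 at 1

    def test_mean_icer_exceeds_icer_at_means(self, nodes_os):
        """Jensen's inequality: 1/delta is convex, so averaging over
        draws inflates the mean ICER above the base-case ratio."""
        summary = run_psa(_config(nodes_os, draws=10_000, seed=6), endpoint="os")
        base = 780.50 / (1.0 - 3 / 7)
        assert summary.icer.mean > base

    def test_degenerate_draws_counted_and_excluded(self, nodes_os):
        # identical PET and MRI arms: the increment is ~symmetric
        # around zero, so roughly half the draws are excluded
        means = nodes_os.probabilities()
        means.update({"n2": means["n1"], "n5": means["n3"], "n6": means["n4"]})
        config = MCConfig(node_means=means, draws=2_000, seed=7)
        summary = run_psa(config, endpoint="os")
        assert 0 < summary.n_excluded < config.draws
        assert summary.icer.minimum > 0

    def test_all_degenerate_draws_is_an_error(self, nodes_os):
        means = {"n1": 0.0, "n2": 0.5, "n3": 0.5, "n4": 0.0, "n5": 1.0, "n6": 1.0}
        config = MCConfig(node_means=means, draws=50, seed=8, node_sds=ZERO_SDS)
        with pytest.raises(ValueError, match="degenerate"):
            run_psa(config, endpoint="os")


class TestConvergence:
    def test_standard_error_shrinks_like_root_n(self, nodes_os):
        table = psa_convergence(
            _config(nodes_os, seed=9), endpoint="os", batch_sizes=(100, 10_000)
        )
        ratio = table.se_mean_icer.iloc[0] / table.se_mean_icer.iloc[1]
        assert 6.0 < ratio < 16.0  # ~ sqrt(10000/100) = 10 up to MC noise

    def test_convergence_table_layout(self, nodes_os):
        table = psa_convergence(
            _config(nodes_os, seed=10), endpoint="os", batch_sizes=(50, 200)
        )
        assert list(table.columns) == ["draws", "mean_icer", "sd_icer", "se_mean_icer"]
        assert list(table.draws) == [50, 200]


class TestConfigValidation:
    def test_missing_node_mean_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            MCConfig(node_means={"n1": 0.4})

    def test_negative_sd_rejected(self, nodes_os):
        with pytest.raises(ValueError):
            _config(nodes_os, scans_sd=-1.0)

    def test_unknown_bounding_rejected(self, nodes_os):
        with pytest.raises(ValueError, match="bounding"):
            _config(nodes_os, bounding="fold")


def test_relative_frequency_histogram_sums_to_one(nodes_os):
    frame = sample_draws(_config(nodes_os, draws=2_000, seed=11))
    hist = relative_frequency_histogram(frame["icer"], bins=30)
    assert math.isclose(hist.relative_frequency.sum(), 1.0, rel_tol=1e-9)
    assert (np.diff(hist.bin_left) > 0).all()
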
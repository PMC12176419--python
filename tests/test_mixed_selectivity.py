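"""Pattern difference decoding, cross-decoding ratio, permutation test,
and hierarchical Bayesian posterior odds."""

import numpy as np
import pytest
from scipy import stats

from mixsel.datasets import znormalize_blocks
from mixsel.decoding import DecodingError, DecodingSpec
from mixsel.mixed_selectivity import (
    build_difference_vectors,
    cohort_cross_decoding_ratio,
    cross_decoding_ratio,
    direction_correlation,
    hierarchical_log_posterior,
    pattern_difference_decode,
    permutation_test,
    posterior_odds,
)

from conftest import make_tiny_dataset


class TestDifferenceVectors:
    def test_category_differencing_counts(self, full_dataset, spec):
        data = znormalize_blocks(full_dataset)
        dv = build_difference_vectors(data, "category", "task")
        # 28 pairs x 20 runs, half of them per task context
        assert dv.vectors.shape == (560, full_dataset.n_voxels)
        for task in full_dataset.tasks:
            assert (dv.context == task).sum() == 280

    def test_task_differencing_counts_and_pairing(self, full_dataset):
        data = znormalize_blocks(full_dataset)
        dv = build_difference_vectors(data, "task", "category")
        # 8 categories x 10 adjacent run pairs
        assert dv.vectors.shape == (80, full_dataset.n_voxels)
        assert sorted(set(dv.context)) == full_dataset.categories
        assert len(np.unique(dv.fold)) == 10

    def test_subtraction_order_is_lexicographic(self):
        betas = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0],
                 [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]
        ds = make_tiny_dataset(betas, [1, 1, 2, 2],
                               ["Oddball"] * 2 + ["Oneback"] * 2,
                               ["A", "B", "A", "B"])
        dv = build_difference_vectors(ds, "category", "task")
        np.testing.assert_array_equal(dv.vectors[0], [1.0, -1.0, 0.0])

    def test_identical_patterns_give_zero_vector(self):
        betas = [[0.3, 0.7], [0.3, 0.7]]
        ds = make_tiny_dataset(betas, [1, 1], ["Oddball"] * 2, ["A", "B"])
        dv = build_difference_vectors(ds, "category", "task")
        np.testing.assert_array_equal(dv.vectors[0], [0.0, 0.0])

    def test_missing_pair_member_is_skipped_with_warning(self, caplog):
        betas = [[0.1, 0.2], [0.3, 0.4], [0.5, 0.6]]
        ds = make_tiny_dataset(betas, [1, 1, 2],
                               ["Oddball", "Oddball", "Oneback"],
                               ["A", "B", "A"])
        with caplog.at_level("WARNING"):
            dv = build_difference_vectors(ds, "category", "task")
        assert dv.vectors.shape[0] == 1
        assert "skipped" in caplog.text


class TestPatternDifferenceDecoding:
    def test_reversed_difference_vector_toy_is_fully_decodable(
            self, toy_fixtures, toy_spec):
        res = pattern_difference_decode(toy_fixtures["interaction_reversed"],
                                        toy_spec)
        assert res.accuracy > 0.95

    def test_oblique_toy_shows_no_interaction(self, toy_fixtures, toy_spec):
        res = pattern_difference_decode(toy_fixtures["oblique_parallelogram"],
                                        toy_spec)
        assert abs(res.accuracy - 0.5) < 0.15

    def test_direction_average_invariant_to_task_relabeling(
            self, full_dataset, spec):
        res = pattern_difference_decode(full_dataset, spec)
        relabeled = full_dataset.labels.copy()
        swap = {"Oddball": "Oneback", "Oneback": "Oddball"}
        relabeled["task"] = relabeled["task"].map(swap)
        ds2 = make_tiny_dataset(full_dataset.betas, relabeled["run"].tolist(),
                                relabeled["task"].tolist(),
                                relabeled["category"].tolist())
        res2 = pattern_difference_decode(ds2, spec)
        assert res.accuracy == pytest.approx(res2.accuracy, abs=1e-12)

    def test_interaction_gain_increases_accuracy(self):
        """Monotone response to the interaction dial (additive -> strong)."""
        from mixsel.simulate import SimulationConfig, generate_dataset

        spec = DecodingSpec()
        means = []
        for mode, gain in (("additive", 0.0), ("rotation", 0.3),
                           ("rotation", 1.2)):
            cfg = SimulationConfig(n_participants=4, geometry_mode=mode,
                                   interaction_gain=gain, seed=77)
            datasets, _ = generate_dataset(cfg)
            means.append(np.mean([
                pattern_difference_decode(ds, spec).accuracy
                for ds in datasets
            ]))
        assert means[0] < means[1] + 0.02  # tolerate sampling error
        assert means[1] < means[2]
        assert means[2] > 0.55

    def test_counts_are_consistent_with_accuracy_granularity(
            self, toy_fixtures, toy_spec):
        res = pattern_difference_decode(toy_fixtures["additive_orthogonal"],
                                        toy_spec)
        assert 0 <= res.n_correct <= res.n_total
        assert res.n_total > 0


class TestDirectionCorrelation:
    def test_identical_vectors_give_r_one(self):
        acc = np.array([0.5, 0.6, 0.7, 0.8])
        assert direction_correlation(acc, acc) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            direction_correlation([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])


class TestCrossDecodingRatio:
    def test_subtract_half_arithmetic(self):
        assert cross_decoding_ratio(0.75, 0.625) == pytest.approx(0.5)

    def test_identity_when_between_equals_within(self):
        assert cross_decoding_ratio(0.8, 0.8) == pytest.approx(1.0)

    def test_probit_variant_against_normal_quantiles(self):
        expected = stats.norm.ppf(0.6) / stats.norm.ppf(0.75)
        got = cross_decoding_ratio(0.75, 0.6, transform="probit")
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.3756, abs=2e-4)

    def test_within_at_or_below_chance_is_flagged_not_dropped(self, caplog):
        with pytest.raises(ValueError, match="undefined"):
            cross_decoding_ratio(0.5, 0.6)
        with caplog.at_level("WARNING"):
            ratios, excluded = cohort_cross_decoding_ratio(
                [0.75, 0.45], [0.625, 0.5]
            )
        assert excluded == [1]
        assert np.isnan(ratios[1]) and ratios[0] == pytest.approx(0.5)
        assert "excluded" in caplog.text


class TestPermutationTest:
    def test_strong_interaction_yields_p_zero(self, toy_fixtures, toy_spec):
        res = permutation_test(toy_fixtures["interaction_reversed"], toy_spec,
                               n_perm=30, seed=0)
        assert res["p_value"] == 0.0

    def test_p_value_applies_the_strict_proportion_higher_rule(
            self, toy_fixtures, toy_spec):
        res = permutation_test(toy_fixtures["oblique_parallelogram"], toy_spec,
                               n_perm=40, seed=1)
        recomputed = np.mean(res["perm_accuracies"] > res["observed"])
        assert res["p_value"] == pytest.approx(recomputed)

    def test_bias_corrected_variant_never_returns_zero(
            self, toy_fixtures, toy_spec):
        res = permutation_test(toy_fixtures["interaction_reversed"], toy_spec,
                               n_perm=19, seed=0, bias_corrected=True)
        assert res["p_value"] == pytest.approx(1 / 20)

    def test_null_false_positive_rate_is_nominal(self):
        """Across many null participants the per-participant test rejects at
        about the nominal .05 rate (small design, reduced permutations)."""
        from mixsel.simulate import SimulationConfig, generate_dataset

        spec = DecodingSpec()
        hits = 0
        n_participants = 200
        for rep in range(n_participants):
            cfg = SimulationConfig(
                n_participants=1, n_categories=4, n_runs_per_task=6,
                n_voxels=16, category_gain=0.0, task_gain=0.11,
                seed=50_000 + rep,
            )
            ds = generate_dataset(cfg)[0][0]
            p = permutation_test(ds, spec, n_perm=40, seed=rep)["p_value"]
            hits += p < 0.05
        assert hits / n_participants == pytest.approx(0.05, abs=0.03)


class TestPosteriorOdds:
    def test_chance_counts_give_even_odds(self):
        res = posterior_odds([50] * 6, [100] * 6)
        assert 0.8 <= res.odds <= 1.25
        assert res.model_diagnostics["converged"]

    def test_complement_symmetry(self):
        k = [55, 60, 48, 62, 51]
        n = [100] * 5
        odds = posterior_odds(k, n).odds
        odds_c = posterior_odds([100 - x for x in k], n).odds
        assert odds * odds_c == pytest.approx(1.0, rel=0.05)

    def test_above_chance_cohort_gives_strong_odds(self):
        res = posterior_odds([60] * 13, [100] * 13)
        assert res.odds > 3.0
        assert res.posterior_mean_accuracy > 0.55

    def test_monotone_in_single_participant_count(self):
        base = [52, 55, 49, 58]
        n = [100] * 4
        odds = [posterior_odds([k0] + base[1:], n).odds
                for k0 in (45, 52, 60)]
        assert odds[0] < odds[1] < odds[2]

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError, match="0 <= k_j <= n_j"):
            posterior_odds([10, 120], [100, 100])
        with pytest.raises(ValueError, match="2 participants"):
            posterior_odds([10], [100])

    def test_log_posterior_matches_direct_quadrature_at_a_point(self):
        """The broadcast implementation agrees with a scalar reimplementation
        by direct numerical integration over one participant effect."""
        from scipy.integrate import quad
        from scipy.special import expit

        k, n = np.array([7.0]), np.array([10.0])
        mu, sigma = 0.3, 0.8

        def integrand(theta):
            return (stats.binom.pmf(7, 10, expit(theta))
                    * stats.norm.pdf(theta, mu, sigma))

        marg, _ = quad(integrand, -10, 10)
        expected = (np.log(marg) + stats.norm.logpdf(mu, 0, 10)
                    - stats.norm.logpdf(0, 0, 10)
                    - 0.5 * (sigma / 2.0) ** 2)
        got = hierarchical_log_posterior(
            np.array([mu]), np.array([sigma]), k, n
        )[0, 0]
        assert got == pytest.approx(expected, abs=1e-6)
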
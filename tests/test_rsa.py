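"""RDM construction, classical MDS, and between-task geometry comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial import procrustes
from scipy.spatial.distance import squareform

from mixsel.decoding import AccuracyTable, condition_pair_id
from mixsel.rsa import (
    GeometryError,
    RDM,
    build_condition_rdm,
    category_similarity_vector,
    geometry_variance_explained,
    mds_embed,
    pdd_geometry_correlation,
    rdm_to_mds_distances,
    second_order_rdm,
    within_participant_between_task_correlation,
)


def synthetic_accuracy_table(n_categories=8, tasks=("Oddball", "Oneback"),
                             seed=0, participant="p1", region="r1"):
    """Accuracy table with all condition-pair entries filled from a seeded
    draw (no decoding involved)."""
    rng = np.random.default_rng(seed)
    cats = [f"cat{i + 1:02d}" for i in range(n_categories)]
    conds = [(c, t) for c in cats for t in sorted(tasks)]
    table = AccuracyTable()
    for a, b in itertools.combinations(sorted(conds), 2):
        table.add(participant, region, "condition_pair",
                  condition_pair_id(a, b), rng.uniform(0.4, 1.0))
    return table, conds


class TestRDM:
    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(GeometryError, match="symmetric"):
            RDM(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(GeometryError, match="diagonal"):
            RDM(["a", "b"], np.array([[1.0, 0.5], [0.5, 0.0]]))

    def test_condition_rdm_has_16_conditions_and_120_pairs(self):
        table, conds = synthetic_accuracy_table()
        rdm = build_condition_rdm(table, "p1", "r1")
        assert rdm.n_conditions == 16
        assert rdm.off_diagonal().size == 120
        assert sorted(rdm.condition_labels) == sorted(conds)

    def test_missing_pair_error_names_the_pair(self):
        table, conds = synthetic_accuracy_table(n_categories=3)
        removed = table.records.pop(0)
        with pytest.raises(GeometryError, match=removed["pair"]):
            build_condition_rdm(table, "p1", "r1")

    def test_constant_chance_table_gives_constant_rdm(self):
        table = AccuracyTable()
        conds = [("catA", "t1"), ("catB", "t1"), ("catA", "t2"),
                 ("catB", "t2")]
        for a, b in itertools.combinations(sorted(conds), 2):
            table.add("p1", "r1", "condition_pair", condition_pair_id(a, b),
                      0.5)
        rdm = build_condition_rdm(table, "p1", "r1")
        assert np.all(rdm.off_diagonal() == 0.5)


class TestMdsDistances:
    @pytest.mark.parametrize("acc,expected", [(0.5, 0.0), (0.45, 0.0),
                                              (0.8, 0.3)])
    def test_subtract_and_clip(self, acc, expected):
        rdm = RDM(["a", "b"], np.array([[0.0, acc], [acc, 0.0]]))
        got = rdm_to_mds_distances(rdm).dissimilarity[0, 1]
        assert got == pytest.approx(expected)


class TestMdsEmbed:
    def test_exact_recovery_of_planar_configuration(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 2.0], [0.0, 2.0]])
        d = squareform(np.linalg.norm(pts[:, None] - pts[None], axis=-1),
                       checks=False)
        rdm = RDM(list("abcd"),
                  np.linalg.norm(pts[:, None] - pts[None], axis=-1))
        coords = mds_embed(rdm, n_dims=2)
        got = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        np.testing.assert_allclose(got, rdm.dissimilarity, atol=1e-9)

    def test_all_zero_rdm_embeds_at_origin_with_warning(self):
        rdm = RDM(list("abc"), np.zeros((3, 3)))
        with pytest.warns(UserWarning, match="degenerate"):
            coords = mds_embed(rdm)
        np.testing.assert_array_equal(coords, 0.0)

    def test_embedding_is_deterministic_and_canonical(self):
        table, _ = synthetic_accuracy_table(seed=3)
        rdm = rdm_to_mds_distances(build_condition_rdm(table, "p1", "r1"))
        a, b = mds_embed(rdm), mds_embed(rdm)
        np.testing.assert_array_equal(a, b)
        for axis in range(a.shape[1]):
            assert a[np.argmax(np.abs(a[:, axis])), axis] >= 0

    def test_rotation_mode_task_clouds_are_congruent(self):
        """Noiseless rotation-regime templates embed to clouds identical up
        to isometry (Procrustes residual ~ 0)."""
        from mixsel.simulate import SimulationConfig, generate_dataset

        cfg = SimulationConfig(n_participants=1, geometry_mode="rotation",
                               interaction_gain=0.9, noise_sd=0.0, seed=8)
        _, truth = generate_dataset(cfg)
        clouds = []
        for task in truth.tasks:
            d = truth.pairwise_distance_table[task]
            clouds.append(mds_embed(RDM(truth.category_labels, d), n_dims=2))
        _, _, disparity = procrustes(clouds[0], clouds[1])
        assert disparity < 1e-12


class TestSimilarityVectors:
    def test_length_28_and_matches_rdm_off_diagonal(self):
        table, _ = synthetic_accuracy_table()
        vec = category_similarity_vector(table, "p1", "r1", "Oddball")
        assert vec.shape == (28,)
        rdm = build_condition_rdm(table, "p1", "r1")
        idx = [i for i, c in enumerate(rdm.condition_labels)
               if c[1] == "Oddball"]
        sub = rdm.dissimilarity[np.ix_(idx, idx)]
        np.testing.assert_allclose(vec, sub[np.triu_indices(8, k=1)])

    def test_canonical_order_is_stable(self):
        table, _ = synthetic_accuracy_table(seed=5)
        a = category_similarity_vector(table, "p1", "r1", "Oneback")
        b = category_similarity_vector(table, "p1", "r1", "Oneback")
        np.testing.assert_array_equal(a, b)


class TestSecondOrder:
    def test_hand_computed_correlation_distances(self):
        vecs = {
            ("r1", "t1"): np.array([1.0, 2.0, 3.0, 4.0]),
            ("r1", "t2"): np.array([4.0, 3.0, 2.0, 1.0]),
            ("r2", "t1"): np.array([1.0, 2.0, 2.0, 5.0]),
        }
        rdm = second_order_rdm(vecs)
        keys = rdm.condition_labels
        for i, j in itertools.combinations(range(3), 2):
            expected = 1 - stats.pearsonr(vecs[keys[i]], vecs[keys[j]])[0]
            assert rdm.dissimilarity[i, j] == pytest.approx(expected)
        # identical vectors -> 0; anti-correlated -> 2
        i1 = keys.index(("r1", "t1"))
        i2 = keys.index(("r1", "t2"))
        assert rdm.dissimilarity[i1, i2] == pytest.approx(2.0)

    def test_zero_variance_vector_rejected(self):
        with pytest.raises(GeometryError, match="zero-variance"):
            second_order_rdm({("a", "t"): np.ones(4),
                              ("b", "t"): np.arange(4.0)})


class TestGeometryVarianceExplained:
    def test_shared_noiseless_geometry_gives_exactly_one(self):
        base = np.linspace(0.5, 0.9, 28)
        vecs = {f"p{i}": {"t1": base, "t2": base} for i in range(5)}
        res = geometry_variance_explained(vecs)
        assert res.mean_variance_explained == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.within_task_correlation, 1.0)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(10)
        base = rng.uniform(0.5, 1.0, 28)
        vecs = {
            f"p{i}": {
                "t1": base + rng.normal(0, 0.05, 28),
                "t2": base + rng.normal(0, 0.05, 28),
            }
            for i in range(4)
        }
        res = geometry_variance_explained(vecs)
        pids = sorted(vecs)
        within, between = [], []
        for pid in pids:
            others = [q for q in pids if q != pid]
            ref1 = np.mean([vecs[q]["t1"] for q in others], axis=0)
            ref2 = np.mean([vecs[q]["t2"] for q in others], axis=0)
            within.append(np.mean([
                stats.pearsonr(vecs[pid]["t1"], ref1)[0],
                stats.pearsonr(vecs[pid]["t2"], ref2)[0],
            ]))
            between.append(np.mean([
                stats.pearsonr(vecs[pid]["t1"], ref2)[0],
                stats.pearsonr(vecs[pid]["t2"], ref1)[0],
            ]))
        expected = (np.array(between) / np.mean(within)) ** 2
        np.testing.assert_allclose(res.variance_explained, expected,
                                   atol=1e-12)

    def test_own_data_never_enters_the_reference_average(self):
        """An outlier participant's noise ceiling reflects only the others."""
        base = np.linspace(0.5, 0.9, 28)
        vecs = {f"p{i}": {"t1": base, "t2": base} for i in range(4)}
        vecs["outlier"] = {"t1": base[::-1].copy(), "t2": base[::-1].copy()}
        res = geometry_variance_explained(vecs)
        pids = sorted(vecs)
        i = pids.index("outlier")
        # the outlier anti-correlates with the others' reference
        assert res.within_task_correlation[i] == pytest.approx(-1.0)
        others = [j for j in range(len(pids)) if j != i]
        np.testing.assert_allclose(res.within_task_correlation[others], 1.0)

    def test_too_few_participants_rejected(self):
        base = np.linspace(0.0, 1.0, 28)
        with pytest.raises(GeometryError, match="participants"):
            geometry_variance_explained(
                {"p1": {"t1": base, "t2": base},
                 "p2": {"t1": base, "t2": base}}
            )


class TestPddGeometryCorrelation:
    def test_perfect_inverse_relation(self):
        pdd = np.array([0.5, 0.55, 0.6, 0.65])
        r, p = pdd_geometry_correlation(pdd, 1.0 - pdd)
        assert r == pytest.approx(-1.0)
        assert p < 1e-6

    def test_constant_input_rejected(self):
        with pytest.raises(GeometryError, match="zero variance"):
            pdd_geometry_correlation([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])

    def test_between_task_correlation_helper(self):
        v = {"t1": np.array([1.0, 2.0, 3.0]), "t2": np.array([3.0, 2.0, 1.0])}
        assert within_participant_between_task_correlation(v) == pytest.approx(-1.0)
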
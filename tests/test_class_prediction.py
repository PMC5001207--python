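import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import crosslink as cl
from crosslink.class_prediction import (
    EPS_SIGMA,
    ClusterSplit,
    call_target_cluster,
    cluster_by_signature,
    confidence_score,
    resolve_labels,
    signature_summaries,
)
from crosslink.dataio import DataError


def _two_blob_matrix(n_per=10, n_genes=20, centers=(-2.0, 2.0), sigma=0.1, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    cols, blocks = [], []
    for b, c in enumerate(centers):
        cols += [f"b{b}_{j}" for j in range(n_per)]
        blocks.append(rng.normal(c, sigma, (n_genes, n_per)))
    return pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)


class TestClusterBySignature:
    def test_separated_blobs_recovered(self):
        mat = _two_blob_matrix()
        part = cluster_by_signature(mat, list(mat.index), seed=3)
        blob = pd.Series([c.split("_")[0] for c in mat.columns], index=mat.columns)
        agreement = max((part == 0).eq(blob == "b0").mean(),
                        (part == 1).eq(blob == "b0").mean())
        assert agreement == 1.0

    def test_two_samples_split_apart(self):
        mat = pd.DataFrame([[0.0, 5.0], [0.0, 5.0]], index=["g0", "g1"], columns=["s1", "s2"])
        part = cluster_by_signature(mat, ["g0", "g1"], seed=0)
        assert part["s1"] != part["s2"]

    def test_single_sample_rejected(self):
        mat = pd.DataFrame([[1.0]], index=["g0"], columns=["s1"])
        with pytest.raises(DataError, match="multiple samples"):
            cluster_by_signature(mat, ["g0"], seed=0)

    def test_disjoint_gene_set_rejected(self):
        mat = _two_blob_matrix(n_genes=3)
        with pytest.raises(DataError, match="no common genes"):
            cluster_by_signature(mat, ["absent1", "absent2"], seed=0)

    def test_partial_gene_overlap_warns(self):
        mat = _two_blob_matrix(n_genes=5)
        with pytest.warns(UserWarning, match="absent from the prediction"):
            cluster_by_signature(mat, ["g0", "g1", "nope"], seed=0)

    def test_translation_invariance_exact(self):
        mat = _two_blob_matrix(n_per=20, seed=5)
        offsets = np.random.default_rng(9).normal(0, 3, (mat.shape[0], 1))
        shifted = mat + offsets
        p0 = cluster_by_signature(mat, list(mat.index), seed=7)
        p1 = cluster_by_signature(shifted, list(mat.index), seed=7)
        # same seed: the partition (up to cluster id) must match exactly
        assert (p0 == p1).all() or (p0 == 1 - p1).all()

    def test_deterministic_given_seed(self):
        mat = _two_blob_matrix(seed=2)
        a = cluster_by_signature(mat, list(mat.index), seed=13)
        b = cluster_by_signature(mat, list(mat.index), seed=13)
        assert (a == b).all()


class TestCallTargetCluster:
    def _matrix_with_summaries(self, summaries):
        # one gene: the summary of a sample is just its expression value
        return pd.DataFrame([summaries], index=["g0"],
                            columns=[f"s{i}" for i in range(len(summaries))])

    def test_higher_absolute_mean_is_target(self):
        mat = self._matrix_with_summaries([2.4, 2.6, 0.2, 0.4])
        assignment = pd.Series([0, 0, 1, 1], index=mat.columns)
        split = call_target_cluster(assignment, mat, ["g0"])
        assert split.is_target.tolist() == [True, True, False, False]
        assert split.mu_t == pytest.approx(2.5)
        assert split.mu_nt == pytest.approx(0.3)

    def test_absolute_value_used_for_negative_cluster(self):
        mat = self._matrix_with_summaries([-3.1, -2.9, 0.9, 1.1])
        assignment = pd.Series([0, 0, 1, 1], index=mat.columns)
        split = call_target_cluster(assignment, mat, ["g0"])
        assert split.mu_t == pytest.approx(-3.0)

    def test_singleton_cluster_sigma_floor_flagged(self):
        mat = self._matrix_with_summaries([5.0, 0.1, 0.2, 0.3])
        assignment = pd.Series([0, 1, 1, 1], index=mat.columns)
        split = call_target_cluster(assignment, mat, ["g0"])
        assert split.n_t == 1
        assert split.sigma_t == EPS_SIGMA
        assert any("singleton" in f for f in split.flags)

    def test_exact_tie_flagged_lower_cluster(self):
        mat = self._matrix_with_summaries([1.0, 1.0, -1.0, -1.0])
        assignment = pd.Series([0, 0, 1, 1], index=mat.columns)
        split = call_target_cluster(assignment, mat, ["g0"])
        assert "target-call-tie" in split.flags
        assert split.is_target.tolist() == [True, True, False, False]

    def test_pooled_variance_formula(self):
        mat = self._matrix_with_summaries([2.0, 3.0, 4.0, 0.0, 0.5, 1.0, 1.5])
        assignment = pd.Series([0, 0, 0, 1, 1, 1, 1], index=mat.columns)
        split = call_target_cluster(assignment, mat, ["g0"])
        sp_oracle = np.sqrt(((split.n_t - 1) * split.sigma_t**2 +
                             (split.n_nt - 1) * split.sigma_nt**2) / split.df)
        assert split.s_p == pytest.approx(sp_oracle)
        assert split.df == 5
        assert split.n_t + split.n_nt == 7

    def test_sign_alignment_rescues_mixed_direction_signature(self):
        # two genes shifted in opposite directions: the plain mean cancels,
        # the reference-aligned mean does not
        mat = pd.DataFrame([[2.0, 2.1, 0.0, 0.1], [-2.0, -2.1, 0.0, -0.1]],
                           index=["up", "down"], columns=list("abcd"))
        assignment = pd.Series([0, 0, 1, 1], index=mat.columns)
        signs = pd.Series({"up": 1.0, "down": -1.0})
        aligned = call_target_cluster(assignment, mat, ["up", "down"], gene_signs=signs)
        assert aligned.mu_t == pytest.approx(2.05)
        plain = signature_summaries(mat, ["up", "down"])
        assert abs(plain["a"]) < 0.1  # cancellation without alignment


class TestConfidenceScore:
    def _split(self, **kw):
        base = dict(class_name="c", is_target=pd.Series(dtype=bool),
                    mu_t=2.0, sigma_t=1.0, n_t=10,
                    mu_nt=0.0, sigma_nt=1.0, n_nt=10, s_p=1.0, df=18)
        base.update(kw)
        return ClusterSplit(**base)

    def test_p1_at_nontarget_mode_is_half_log_two_pi(self):
        p1, _, _ = confidence_score(0.0, self._split())
        assert p1 == pytest.approx(0.5 * np.log(2 * np.pi), rel=1e-12)

    def test_no_separation_means_zero_confidence(self):
        split = self._split(mu_t=0.0, mu_nt=0.0)
        p1, p2, s = confidence_score(1.3, split)
        assert p2 == 0.0
        assert s == 0.0

    def test_p2_matches_numeric_t_cdf_integration(self):
        split = self._split()
        p1, p2, s = confidence_score(2.0, split)
        assert p1 == pytest.approx(2.0 + 0.5 * np.log(2 * np.pi), rel=1e-12)
        t_stat = 2.0 / np.sqrt(2.0 / 10.0)
        assert t_stat == pytest.approx(4.4721, abs=1e-4)
        # independent oracle: integrate the t density over the tails
        tail, _ = integrate.quad(lambda x: stats.t.pdf(x, 18), t_stat, np.inf,
                                 epsabs=0.0, epsrel=1e-10)
        p2_oracle = -np.log(2 * tail)
        assert p2 == pytest.approx(p2_oracle, rel=1e-6)
        assert s == pytest.approx(p1 * p2)

    def test_score_never_negative_even_with_tight_density(self):
        split = self._split(sigma_nt=1e-4)  # density at mode >> 1
        p1, p2, s = confidence_score(0.0, split)
        assert p1 == 0.0 and s == 0.0

    def test_non_finite_summary_rejected(self):
        with pytest.raises(ValueError):
            confidence_score(np.nan, self._split())


class TestResolveLabels:
    def _frames(self, cand_rows, score_rows, classes=("A", "B", "C")):
        idx = [f"s{i}" for i in range(len(cand_rows))]
        return (pd.DataFrame(cand_rows, index=idx, columns=classes),
                pd.DataFrame(score_rows, index=idx, columns=classes))

    def test_unique_candidate_kept(self):
        cand, score = self._frames([[True, False, False]], [[1.0, 9.0, 9.0]])
        labels, status = resolve_labels(cand, score)
        assert labels["s0"] == "A"
        assert status["s0"] == "unique-call"

    def test_multi_call_resolved_by_score(self):
        cand, score = self._frames([[True, True, False]], [[5.0, 7.0, 99.0]])
        labels, status = resolve_labels(cand, score)
        assert labels["s0"] == "B"
        assert status["s0"] == "multi-call-resolved"

    def test_zero_candidates_argmax_fallback(self):
        cand, score = self._frames([[False, False, False]], [[1.0, 2.0, 3.0]])
        labels, status = resolve_labels(cand, score)
        assert labels["s0"] == "C"
        assert status["s0"] == "fallback"

    def test_zero_candidates_unassigned_option(self):
        cand, score = self._frames([[False, False, False]], [[1.0, 2.0, 3.0]])
        labels, status = resolve_labels(cand, score, fallback="unassigned")
        assert labels["s0"] == "unassigned"
        assert status["s0"] == "unassigned"

    def test_score_tie_goes_to_lowest_class_index(self):
        cand, score = self._frames([[True, True, False]], [[4.0, 4.0, 0.0]])
        labels, _ = resolve_labels(cand, score)
        assert labels["s0"] == "A"


@pytest.fixture(scope="module")
def three_class():
    config = cl.SimulationConfig(n_classes=3, genes_total=300,
                                 signature_genes_per_class=20,
                                 samples_per_class=50, seed=31)
    dataset, _ = cl.simulate_reference(config)
    model = cl.build_signature_model(dataset, cl.SelectionConfig(t1=0.1, t2=0.5), seed=31)
    return dataset, model


class TestPredict:
    def test_planted_labels_recovered(self, three_class):
        dataset, model = three_class
        result = cl.predict(dataset.matrix, model, seed=31)
        assert (result.labels == dataset.labels).mean() >= 0.95

    def test_per_gene_offsets_leave_partitions_identical(self, three_class):
        dataset, model = three_class
        offsets = np.random.default_rng(1).normal(0, np.sqrt(0.5), (dataset.matrix.shape[0], 1))
        base = cl.predict(dataset.matrix, model, seed=31)
        shifted = cl.predict(dataset.matrix + offsets, model, seed=31)
        for c in model.class_names:
            a = base.splits[c].is_target
            b = shifted.splits[c].is_target
            assert (a == b).all() or (a == ~b).all()

    def test_clusters_partition_samples(self, three_class):
        dataset, model = three_class
        result = cl.predict(dataset.matrix, model, seed=31)
        for split in result.splits.values():
            assert split.n_t + split.n_nt == dataset.matrix.shape[1]
            assert split.n_t >= 1 and split.n_nt >= 1

    def test_scores_non_negative_and_p2_cluster_level(self, three_class):
        dataset, model = three_class
        result = cl.predict(dataset.matrix, model, seed=31)
        assert (result.scores.to_numpy() >= 0).all()
        long = result.scores_long()
        for c in model.class_names:
            assert long.loc[long["class"] == c, "p2"].nunique() == 1

    def test_single_class_prediction_set_flagged(self, three_class):
        dataset, model = three_class
        one_class = dataset.matrix[dataset.samples_of(dataset.class_names[0])]
        with pytest.warns(UserWarning, match="degenerate-splits"):
            result = cl.predict(one_class, model, seed=31)
        assert result.flags

    def test_all_empty_model_rejected(self, three_class):
        dataset, model = three_class
        hollow = cl.SignatureModel(
            class_names=model.class_names,
            gene_sets={c: [] for c in model.class_names},
            class_means={c: {} for c in model.class_names},
            fdr_level=0.05, t1=0.1, t2=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(DataError, match="no common genes"):
                cl.predict(dataset.matrix, hollow, seed=31)

    def test_deterministic_given_seed(self, three_class):
        dataset, model = three_class
        a = cl.predict(dataset.matrix, model, seed=99)
        b = cl.predict(dataset.matrix, model, seed=99)
        assert (a.labels == b.labels).all()
        pd.testing.assert_frame_equal(a.scores, b.scores)
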
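"""Factorization, consensus, validation metrics and signature extraction.

Brute-force oracles (explicit neighbor lists, pairwise silhouette terms,
direct dendrogram merge heights) are computed inside the tests and the
implementations are compared against them.
"""

import numpy as np
import pandas as pd
import pytest

import epistrat as es
from epistrat.errors import DataContractError
from epistrat.nmf import kim_park_scores

from conftest import SMALL


class TestFactorize:
    def test_recovers_exact_low_rank_matrix(self, rng):
        W0 = rng.uniform(0.5, 2.0, size=(40, 2))
        H0 = rng.uniform(0.5, 2.0, size=(2, 25))
        V = W0 @ H0
        fit = es.nmf_factorize(V, 2, seed=1, max_iter=2000, tol=0.0)
        const = np.full_like(V, V.mean())
        d_const = float(np.sum(V * np.log(V / const) - V + const))
        d_fit = fit.objective_trace[-1]
        assert d_fit < 1e-6 * d_const

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        V = rng.gamma(2.0, 1.0, size=(30, 12))
        fit = es.nmf_factorize(V, 3, seed=seed, max_iter=150)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs <= 1e-8 * np.abs(fit.objective_trace[:-1]) + 1e-8)

    def test_rejects_bad_inputs(self, rng):
        V = rng.uniform(size=(10, 5))
        V[0, 0] = -1e-9
        with pytest.raises(DataContractError):
            es.nmf_factorize(V, 2)
        with pytest.raises(DataContractError):
            es.nmf_factorize(np.abs(V), 5)


class TestConsensus:
    @staticmethod
    def _block_matrix(rng):
        """Two disjoint strongly expressed gene blocks over 12 samples."""
        V = rng.uniform(0.0, 0.05, size=(30, 12))
        V[:15, :6] += 10.0
        V[15:, 6:] += 10.0
        return V

    def test_separable_blocks_give_binary_consensus(self, rng):
        V = self._block_matrix(rng)
        res = es.consensus_cluster(V, 2, n_runs=8, seed=0)
        C = res.consensus.to_numpy()
        assert set(np.round(np.unique(C), 6)) <= {0.0, 1.0}
        first = res.labels.iloc[:6]
        second = res.labels.iloc[6:]
        assert first.nunique() == 1 and second.nunique() == 1
        assert first.iloc[0] != second.iloc[0]

    def test_duplicated_samples_always_cocluster(self, rng):
        V = self._block_matrix(rng)
        V = np.hstack([V, V[:, :1]])  # sample 12 duplicates sample 0
        res = es.consensus_cluster(V, 2, n_runs=8, seed=0)
        assert res.consensus.iloc[0, 12] == 1.0

    def test_consensus_is_symmetric_unit_diagonal(self, stratified):
        C = stratified["consensus"].consensus.to_numpy()
        assert np.array_equal(C, C.T)
        np.testing.assert_array_equal(np.diag(C), 1.0)
        assert C.min() >= 0.0 and C.max() <= 1.0


class TestCophenetic:
    def test_perfect_two_block_consensus_scores_one(self):
        C = np.kron(np.eye(2), np.ones((3, 3)))
        assert es.cophenetic_coefficient(C) == pytest.approx(1.0)

    def test_constant_offdiagonal_flagged(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        with pytest.warns(RuntimeWarning):
            assert np.isnan(es.cophenetic_coefficient(C))

    def test_matches_enumerated_dendrogram_on_noisy_pair(self):
        # four samples, one noisy pair; oracle = direct average-linkage
        # merge-height enumeration
        C = np.array([[1.0, 0.9, 0.1, 0.2],
                      [0.9, 1.0, 0.2, 0.1],
                      [0.1, 0.2, 1.0, 0.7],
                      [0.2, 0.1, 0.7, 1.0]])
        D = 1.0 - C
        # merges: (0,1) at 0.1; (2,3) at 0.3; clusters {0,1},{2,3} at
        # mean(d02,d03,d12,d13) = mean(.9,.8,.8,.9) = 0.85
        coph = np.array([0.1,  # d(0,1)
                         0.85, 0.85,  # d(0,2), d(0,3)
                         0.85, 0.85,  # d(1,2), d(1,3)
                         0.3])  # d(2,3)
        observed = np.array([D[0, 1], D[0, 2], D[0, 3], D[1, 2], D[1, 3],
                             D[2, 3]])
        expected = np.corrcoef(observed, coph)[0, 1]
        assert es.cophenetic_coefficient(C) == pytest.approx(expected, abs=1e-12)


class TestSilhouette:
    def test_far_apart_blobs_near_one(self, rng):
        data = np.vstack([rng.normal(0, 0.01, size=(20, 2)),
                          rng.normal(100, 0.01, size=(20, 2))])
        labels = np.repeat([1, 2], 20)
        assert es.silhouette_score(data, labels) > 0.95

    def test_matches_brute_force_on_line(self):
        data = np.array([[0.0], [1.0], [2.0], [3.0]])
        labels = np.array([1, 1, 2, 2])
        vals = []
        for i in range(4):
            same = [j for j in range(4) if labels[j] == labels[i] and j != i]
            other = [j for j in range(4) if labels[j] != labels[i]]
            a = np.mean([abs(data[i, 0] - data[j, 0]) for j in same])
            b = np.mean([abs(data[i, 0] - data[j, 0]) for j in other])
            vals.append((b - a) / max(a, b))
        assert es.silhouette_score(data, labels) == pytest.approx(np.mean(vals))

    def test_random_labels_score_near_zero(self, rng):
        data = rng.normal(size=(200, 5))
        labels = rng.integers(1, 3, size=200)
        assert abs(es.silhouette_score(data, labels)) < 0.1

    def test_single_cluster_errors(self):
        with pytest.raises(DataContractError):
            es.silhouette_score(np.zeros((5, 2)), np.ones(5))


class TestConnectivity:
    def test_pure_neighborhoods_score_zero(self, rng):
        data = np.vstack([rng.normal(0, 0.1, size=(10, 2)),
                          rng.normal(50, 0.1, size=(10, 2))])
        labels = np.repeat([1, 2], 10)
        assert es.connectivity(data, labels, 5) == 0.0

    def test_hand_worked_line_example(self):
        data = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([1, 2, 2, 2])
        # L=1: point 0's nearest neighbor (1) is cross-cluster -> 1;
        # point 1's nearest (0) is cross-cluster -> 1; others pure
        assert es.connectivity(data, labels, 1) == pytest.approx(2.0)

    def test_matches_brute_force_enumeration(self, rng):
        data = rng.normal(size=(10, 3))
        labels = rng.integers(1, 3, size=10)
        L = 4
        total = 0.0
        for i in range(10):
            d = np.linalg.norm(data - data[i], axis=1)
            d[i] = np.inf
            order = np.lexsort((np.arange(10), d))
            for j in range(L):
                if labels[order[j]] != labels[i]:
                    total += 1.0 / (j + 1)
        assert es.connectivity(data, labels, L) == pytest.approx(total)

    def test_identical_labels_score_zero(self, rng):
        data = rng.normal(size=(8, 2))
        assert es.connectivity(data, np.ones(8), 3) == 0.0


class TestSelectRank:
    @staticmethod
    def _table(coph, sil, conn):
        return {k: {"cophenetic": c, "silhouette": s, "connectivity": n}
                for k, c, s, n in zip((2, 3, 4), coph, sil, conn)}

    def test_unanimous_winner(self):
        t = self._table((0.99, 0.9, 0.8), (0.5, 0.3, 0.2), (1.0, 5.0, 9.0))
        assert es.select_rank(t) == 2

    def test_majority_beats_single_metric(self):
        t = self._table((0.9, 0.99, 0.8), (0.5, 0.3, 0.2), (1.0, 5.0, 9.0))
        assert es.select_rank(t) == 2

    def test_three_way_split_resolves_to_smallest(self):
        t = self._table((0.8, 0.9, 0.85), (0.2, 0.1, 0.3), (1.0, 5.0, 9.0))
        assert es.select_rank(t) == 2

    def test_missing_metric_errors(self):
        t = self._table((0.9, 0.8, 0.7), (0.5, 0.4, 0.3), (1.0, 2.0, 3.0))
        del t[3]["silhouette"]
        with pytest.raises(DataContractError):
            es.select_rank(t)


class TestTopGenes:
    def test_kim_park_closed_forms(self):
        W = np.array([[5.0, 0.0],  # fully specific -> 1
                      [2.0, 2.0],  # uniform -> 0
                      [0.0, 0.0]])  # unscored
        scores = kim_park_scores(W)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(0.0)
        assert np.isnan(scores[2])

    def test_selects_exactly_the_specific_high_magnitude_genes(self, rng):
        W = np.abs(rng.normal(1.0, 0.01, size=(100, 2)))  # near-uniform bulk
        W[0] = [50.0, 0.0]
        W[1] = [0.0, 50.0]
        sigs = es.extract_top_genes(W)
        assert sorted(sigs.scores.index) == ["gene0", "gene1"]
        assert sigs.assignment["gene0"] == 1
        assert sigs.assignment["gene1"] == 2

    def test_scores_bounded_and_recover_planted_roles(self, stratified, cohort):
        sigs = stratified["signatures"]
        all_scores = sigs.all_scores.dropna()
        assert ((all_scores >= 0) & (all_scores <= 1)).all()
        roles = cohort["truth"].gene_role
        selected_roles = roles[sigs.scores.index]
        assert (selected_roles.str.startswith("signature")).all()


class TestOutcomeLabels:
    def test_higher_hazard_cluster_labeled_poor(self, stratified, cohort,
                                                normalized):
        outcome = stratified["outcome"]
        assert not stratified["outcome_flagged"]
        labels = stratified["consensus"].labels
        truth = cohort["truth"].sample_program[labels.index]
        poor_cluster = next(c for c, v in outcome.items() if v == "poor")
        # program 2 carries the positive planted log-HR
        majority_program = truth[labels == poor_cluster].mode()[0]
        assert majority_program == 2

    def test_identical_survival_unlabelable(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        clin = pd.DataFrame({"time_pfi": [5.0, 10.0, 5.0, 10.0],
                             "event_pfi": [1, 1, 1, 1]}, index=list("abcd"))
        out, flagged = es.label_clusters_by_outcome(labels, clin)
        assert flagged and out is None

    def test_all_censored_unlabelable(self):
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        clin = pd.DataFrame({"time_pfi": [5.0, 10.0, 3.0, 8.0],
                             "event_pfi": [0, 0, 0, 0]}, index=list("abcd"))
        out, flagged = es.label_clusters_by_outcome(labels, clin)
        assert flagged and out is None
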
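import math

import numpy as np
import pytest

from gnmfclust import (
    CopyNumberMatrix,
    ModelScore,
    cophenetic_correlation,
    gnmf_bic,
    gnmf_log_likelihood,
    hierarchical_cluster,
    select_best_model,
)
from gnmfclust.model_selection import SIGMA_FLOOR

from conftest import make_grid


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def join_height_brute_force(Z, i, j):
    """Height of the lowest dendrogram node containing both leaves i and j."""
    n = Z.shape[0] + 1
    members = {k: {k} for k in range(n)}
    for step in range(n - 1):
        a, b, height, _ = Z[step]
        merged = members[int(a)] | members[int(b)]
        if i in merged and j in merged:
            return height
        members[n + step] = merged
    raise AssertionError("leaves never joined")


def cophenetic_brute_force(d, Z):
    """Pairwise correlation of original distances and join heights."""
    m = d.shape[0]
    xs, ts = [], []
    for i in range(m):
        for j in range(i + 1, m):
            xs.append(d[i, j])
            ts.append(join_height_brute_force(Z, i, j))
    xs, ts = np.array(xs), np.array(ts)
    xbar, tbar = xs.mean(), ts.mean()
    return float(
        np.sum((xs - xbar) * (ts - tbar))
        / math.sqrt(np.sum((xs - xbar) ** 2) * np.sum((ts - tbar) ** 2))
    )


def loglik_brute_force(values, assignment, floor=SIGMA_FLOOR):
    """Triple loop over clusters, samples, segments using scalar math."""
    y = np.log(values)
    labels = np.unique(assignment)
    # pooled sigma for singleton clusters, mirroring the documented model
    num = np.zeros(y.shape[0])
    cnt = 0
    for lab in labels:
        cols = y[:, assignment == lab]
        if cols.shape[1] >= 2:
            num += cols.shape[1] * cols.var(axis=1)
            cnt += cols.shape[1]
    pooled = np.maximum(np.sqrt(num / cnt), floor) if cnt else np.full(y.shape[0], floor)

    total = 0.0
    for lab in labels:
        cols = y[:, assignment == lab]
        for t in range(cols.shape[0]):
            mu = cols[t].mean()
            sig = pooled[t] if cols.shape[1] < 2 else max(cols[t].std(), floor)
            for v in cols[t]:
                total += -0.5 * math.log(2 * math.pi) - math.log(sig) \
                         - (v - mu) ** 2 / (2 * sig**2)
    return total


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestCopheneticCorrelation:
    def test_ultrametric_input_scores_one(self):
        # two tight pairs far apart: average-linkage tree reproduces distances
        d = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        dend = hierarchical_cluster(d)
        assert cophenetic_correlation(d, dend) == pytest.approx(1.0)

    def test_matches_brute_force_pair_enumeration(self, rng):
        x = rng.uniform(0, 1, (8, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dend = hierarchical_cluster(d)
        expected = cophenetic_brute_force(d, dend.linkage_matrix)
        assert cophenetic_correlation(d, dend) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_uniform_distance_scaling(self, rng):
        x = rng.uniform(0, 1, (7, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        c1 = cophenetic_correlation(d, hierarchical_cluster(d))
        c2 = cophenetic_correlation(5 * d, hierarchical_cluster(5 * d))
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_star_dendrogram_undefined(self):
        d = np.ones((4, 4)) - np.eye(4)  # all equidistant
        dend = hierarchical_cluster(d)
        with pytest.raises(ValueError):
            cophenetic_correlation(d, dend)


class TestLogLikelihood:
    def test_two_identical_samples_closed_form(self):
        # single cluster, single segment, both samples at copy number e:
        # mu = 1, sigma floored; L = 2 ln phi(1; 1, floor)
        m = CopyNumberMatrix(np.array([[np.e, np.e]]), make_grid(1), ["a", "b"])
        ll, tables = gnmf_log_likelihood(m, np.array([0, 0]))
        expected = 2 * (-0.5 * math.log(2 * math.pi) - math.log(SIGMA_FLOOR))
        assert ll == pytest.approx(expected)
        assert tables[0]["mu"][0] == pytest.approx(1.0)

    def test_matches_triple_loop_oracle(self, rng):
        values = rng.uniform(1.0, 3.5, (20, 12))
        assignment = rng.integers(0, 3, 12)
        ll, _ = gnmf_log_likelihood(values, assignment)
        assert ll == pytest.approx(loglik_brute_force(values, assignment), rel=1e-12)

    def test_singleton_cluster_uses_pooled_sigma(self, rng):
        values = rng.uniform(1.0, 3.5, (10, 7))
        assignment = np.array([0, 0, 0, 1, 1, 1, 2])  # cluster 2 is a singleton
        ll, tables = gnmf_log_likelihood(values, assignment)
        assert ll == pytest.approx(loglik_brute_force(values, assignment), rel=1e-12)
        singleton = [t for t in tables if t["n"] == 1][0]
        assert np.all(singleton["sigma"] >= SIGMA_FLOOR)

    def test_duplicating_a_sample_never_lowers_per_sample_loglik(self, rng):
        values = rng.uniform(1.0, 3.5, (15, 6))
        assignment = np.zeros(6, dtype=int)
        ll, _ = gnmf_log_likelihood(values, assignment)
        dup = np.column_stack([values, values[:, 0]])
        ll_dup, _ = gnmf_log_likelihood(dup, np.zeros(7, dtype=int))
        assert ll_dup / 7 >= ll / 6 - 1e-9


class TestBIC:
    def test_decomposition_identity(self, rng):
        values = rng.uniform(1.0, 3.5, (20, 12))
        assignment = rng.integers(0, 3, 12)
        score = gnmf_bic(values, assignment, r=3)
        assert score.k_params == 2 * 3 * 20
        assert score.bic + 2 * score.log_likelihood == pytest.approx(
            2 * 3 * 20 * math.log(12), rel=1e-12
        )

    def test_equal_likelihood_penalizes_larger_r(self, rng):
        values = rng.uniform(1.0, 3.5, (10, 8))
        assignment = rng.integers(0, 2, 8)
        ll, _ = gnmf_log_likelihood(values, assignment)
        s2 = gnmf_bic(values, assignment, r=2)
        s3 = gnmf_bic(values, assignment, r=3)  # same assignment, claimed rank 3
        assert s3.bic > s2.bic

    def test_single_sample_penalty_is_zero(self):
        values = np.array([[2.0], [2.5]])
        score = gnmf_bic(values, np.array([0]), r=1)
        assert score.bic == pytest.approx(-2 * score.log_likelihood)


class TestSelectBestModel:
    def make_scores(self, bics, cophs):
        return [
            ModelScore(r=r, cophenetic=c, bic=b, log_likelihood=0.0, k_params=0)
            for r, (b, c) in enumerate(zip(bics, cophs), start=3)
        ]

    def test_identical_bic_breaks_toward_smaller_r(self):
        scores = self.make_scores([100.0, 100.0, 120.0], [0.9, 0.8, 0.7])
        report = select_best_model(scores)
        assert report.bic_choice == 3

    def test_disagreement_reported_and_bic_wins(self):
        # min BIC at r=5, biggest cophenetic drop after r=3
        scores = self.make_scores([100.0, 99.0, 90.0], [0.9, 0.5, 0.45])
        report = select_best_model(scores)
        assert report.selected_r == 5
        assert report.cophenetic_choice == 3
        assert not report.agree
        assert any("disagree" in n for n in report.notes)

    def test_non_consecutive_ranks_skip_decrease_rule(self):
        scores = [
            ModelScore(r=2, cophenetic=0.9, bic=10.0, log_likelihood=0, k_params=0),
            ModelScore(r=4, cophenetic=0.7, bic=5.0, log_likelihood=0, k_params=0),
        ]
        report = select_best_model(scores)
        assert report.cophenetic_choice is None
        assert report.selected_r == 4
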
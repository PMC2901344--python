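"""Divergence-objective NMF with multiplicative updates and consensus runs.

The factorization V ~ W H decomposes an ``n_segments x m_samples`` positive
copy-number matrix into r nonnegative subgroup profiles (columns of W) and
per-sample weights (columns of H).  The objective is the generalized
Kullback-Leibler divergence

    D(V || WH) = sum_ij [ V_ij * ln(V_ij / (WH)_ij) - V_ij + (WH)_ij ]

minimized by the Lee-Seung multiplicative updates, which never increase D.
Two departures from a plain NMF make this the clustering variant used here:

* the iteration stops when, checked every ``check_interval`` steps, the
  divergence fails to drop by more than ``rel_tol`` (default 1e-5, i.e.
  0.001%) of its value at the previous checkpoint; and
* many random initiations are aggregated into a consensus: the Pearson
  correlation matrix of H's sample columns is averaged over runs, and
  average-linkage hierarchical clustering of ``1 - mean correlation`` cut at
  r groups gives the final assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

#: Additive guard inside update denominators; numerically inert for floored
#: inputs but prevents 0/0 on adversarial ones.
_EPS = 1e-12


@dataclass
class GNMFModel:
    """One factorization from a single random initiation."""

    W: np.ndarray
    H: np.ndarray
    r: int
    divergence_trace: list[float]
    seed: int
    steps: int

    @property
    def divergence(self) -> float:
        return self.divergence_trace[-1]

    def max_weight_assignment(self) -> np.ndarray:
        """Per-sample cluster = argmax component weight (single-run rule).

        The consensus path is the default; this single-run shortcut exists
        for diagnostics and comparison.
        """
        return np.argmax(self.H, axis=0)


@dataclass
class ConsensusResult:
    """Averaged H-correlation matrix over runs and the derived assignment."""

    avg_correlation: np.ndarray
    assignment: np.ndarray  # cluster label per sample, 0-based
    r: int
    n_runs: int
    seeds: list[int]
    linkage_matrix: np.ndarray = field(repr=False, default=None)
    n_degenerate_runs: int = 0

    @property
    def distance_matrix(self) -> np.ndarray:
        """``1 - avg_correlation`` with an exactly zero diagonal."""
        d = 1.0 - self.avg_correlation
        np.fill_diagonal(d, 0.0)
        return np.maximum(d, 0.0)


def kl_divergence(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Generalized KL divergence ``D(V || WH)``; zero iff V equals WH."""
    V = np.asarray(V, float)
    WH = np.asarray(W, float) @ np.asarray(H, float)
    if np.any(WH <= 0):
        raise ValueError("WH has a non-positive entry; inputs must be floored > 0")
    if np.any(V <= 0):
        raise ValueError("V must be strictly positive")
    return float(np.sum(V * np.log(V / WH) - V + WH))


def multiplicative_step(
    V: np.ndarray, W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One Lee-Seung divergence-form update of H then W.

    H_au <- H_au * sum_i W_ia V_iu / (WH)_iu / sum_i W_ia, then the symmetric
    update for W with the refreshed H.  Divergence never increases.
    """
    WH = W @ H
    H_new = H * (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
    WH = W @ H_new
    W_new = W * ((V / WH) @ H_new.T) / (H_new.sum(axis=1)[None, :] + _EPS)
    if not (np.all(np.isfinite(W_new)) and np.all(np.isfinite(H_new))):
        raise FloatingPointError("non-finite factor entries after update")
    return W_new, H_new


def run_gnmf_single(
    V: np.ndarray,
    r: int,
    seed: int,
    check_interval: int = 100,
    rel_tol: float = 1e-5,
    max_steps: int = 20_000,
) -> GNMFModel:
    """Factorize V at rank r from one seeded random initiation.

    W and H start i.i.d. uniform on (0, 1].  Every ``check_interval`` steps
    the divergence is evaluated; iteration stops at the first checkpoint
    where the decrease is at most ``rel_tol`` of the previous checkpoint's
    divergence, or at ``max_steps`` with a warning.
    """
    V = np.asarray(V, float)
    n, m = V.shape
    if not 1 <= r <= min(n, m):
        raise ValueError(f"rank r={r} out of range [1, {min(n, m)}]")
    if np.any(V <= 0):
        raise ValueError("V must be strictly positive (apply the load-time floor)")

    rng = np.random.default_rng(seed)
    # uniform on (0, 1]: flip the half-open side of random()
    W = 1.0 - rng.random((n, r))
    H = 1.0 - rng.random((r, m))

    trace = [kl_divergence(V, W, H)]
    steps = 0
    while steps < max_steps:
        for _ in range(check_interval):
            W, H = multiplicative_step(V, W, H)
        steps += check_interval
        d = kl_divergence(V, W, H)
        d_prev = trace[-1]
        trace.append(d)
        # comparisons start at the second checkpoint: the step-0 divergence
        # is diagnostic, not a checkpoint of the stop rule
        if len(trace) >= 3 and d_prev - d <= rel_tol * d_prev:
            break
    else:
        logger.warning(
            "run_gnmf_single(seed=%d, r=%d): hit max_steps=%d without meeting "
            "the divergence criterion", seed, r, max_steps,
        )
    return GNMFModel(W=W, H=H, r=r, divergence_trace=trace, seed=seed, steps=steps)


def h_correlation(H: np.ndarray, on_constant: str = "raise") -> np.ndarray:
    """Pearson correlation between every pair of sample weight columns of H.

    A constant column (a run that collapsed a component) leaves the
    correlation undefined; ``on_constant="jitter"`` instead perturbs such
    columns by a deterministic ``1e-9 * component_index`` ramp so the
    consensus average stays defined, and the caller counts the run as
    degenerate.
    """
    H = np.asarray(H, float)
    if H.shape[0] < 2:
        raise ValueError("h_correlation needs r >= 2 weight components")
    const = np.ptp(H, axis=0) == 0
    if const.any():
        if on_constant == "raise":
            raise ValueError(
                f"constant H column(s) at sample index {np.where(const)[0].tolist()}"
            )
        H = H.copy()
        ramp = 1e-9 * np.arange(H.shape[0])
        H[:, const] += ramp[:, None]
    corr = np.corrcoef(H, rowvar=False)
    return np.clip(corr, -1.0, 1.0)


def consensus_assignment(
    avg_correlation: np.ndarray, r: int, linkage_method: str = "average"
) -> tuple[np.ndarray, np.ndarray]:
    """Cut the average-linkage tree of ``1 - avg_correlation`` into r groups."""
    d = 1.0 - avg_correlation
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    Z = linkage(squareform(d, checks=False), method=linkage_method)
    labels = cut_tree(Z, n_clusters=r).ravel()
    return labels, Z


def run_gnmf_consensus(
    V: np.ndarray,
    r: int,
    n_runs: int = 200,
    base_seed: int = 0,
    linkage_method: str = "average",
    check_interval: int = 100,
    rel_tol: float = 1e-5,
    max_steps: int = 20_000,
) -> ConsensusResult:
    """Multi-initiation consensus clustering at rank r.

    Run i uses seed ``base_seed + i``.  The H-column correlation matrices of
    the runs are averaged; cutting the average-linkage dendrogram of one
    minus that average at r groups yields the assignment.
    """
    V = np.asarray(V, float)
    m = V.shape[1]
    if r < 2:
        raise ValueError("consensus clustering needs r >= 2")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    seeds = [base_seed + i for i in range(n_runs)]
    acc = np.zeros((m, m))
    n_degenerate = 0
    for seed in seeds:
        model = run_gnmf_single(
            V, r, seed,
            check_interval=check_interval, rel_tol=rel_tol, max_steps=max_steps,
        )
        try:
            corr = h_correlation(model.H, on_constant="raise")
        except ValueError:
            corr = h_correlation(model.H, on_constant="jitter")
            n_degenerate += 1
        acc += corr
    if n_degenerate:
        logger.info(
            "run_gnmf_consensus: %d/%d run(s) had a collapsed component "
            "(jittered before correlation)", n_degenerate, n_runs,
        )
    avg = acc / n_runs
    avg = (avg + avg.T) / 2.0
    np.fill_diagonal(avg, 1.0)
    labels, Z = consensus_assignment(avg, r, linkage_method)
    return ConsensusResult(
        avg_correlation=avg,
        assignment=labels,
        r=r,
        n_runs=n_runs,
        seeds=seeds,
        linkage_matrix=Z,
        n_degenerate_runs=n_degenerate,
    )
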
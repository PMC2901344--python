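"""10-fold cross-validation stability of a consensus clustering.

Repeatedly leave 10% of samples out, re-cluster the remaining 90% with the
same parameters, and count retained samples that land in a different
subgroup than in the reference model.  Cluster labels are arbitrary, so
each repeat's labels are first matched to the reference by the optimal
one-to-one mapping on the confusion matrix.  The aggregate error rate over
repeats measures how stable the clustering is under sample permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .nmf import run_gnmf_consensus

logger = logging.getLogger(__name__)


@dataclass
class RepeatRecord:
    holdout: list[int]
    n_retained: int
    n_errors: int


@dataclass
class StabilityReport:
    n_repeats: int
    repeats: list[RepeatRecord]
    error_rate: float
    r: int
    consensus_runs: int

    def summary(self) -> str:
        return f"error rate = {100.0 * self.error_rate:.2f}%"


def match_labels(
    reference: np.ndarray, new: np.ndarray
) -> tuple[dict[int, int], int]:
    """Optimal one-to-one mapping of new labels onto reference labels.

    Maximizes agreement via the assignment problem on the confusion matrix.
    Returns ``(mapping new_label -> reference_label, n_disagreements)``.
    When the label sets differ in size the mapping is partial: samples whose
    new label maps to nothing (or to the wrong reference label) count as
    disagreements.
    """
    reference = np.asarray(reference)
    new = np.asarray(new)
    if reference.shape != new.shape:
        raise ValueError("assignments must cover the same samples")
    ref_labels = np.unique(reference)
    new_labels = np.unique(new)
    C = np.zeros((len(ref_labels), len(new_labels)), dtype=int)
    for i, rl in enumerate(ref_labels):
        for j, nl in enumerate(new_labels):
            C[i, j] = int(np.sum((reference == rl) & (new == nl)))
    rows, cols = linear_sum_assignment(-C)
    mapping = {int(new_labels[j]): int(ref_labels[i]) for i, j in zip(rows, cols)}
    agreement = int(C[rows, cols].sum())
    return mapping, int(reference.size - agreement)


def tenfold_stability(
    V: np.ndarray,
    r: int,
    reference_assignment: np.ndarray,
    n_repeats: int = 200,
    holdout_fraction: float = 0.1,
    base_seed: int = 0,
    consensus_runs: int = 200,
    check_interval: int = 100,
    rel_tol: float = 1e-5,
    max_steps: int = 20_000,
) -> StabilityReport:
    """Leave-10%-out stability test of the rank-r consensus clustering.

    Each repeat holds out ``holdout_fraction`` of samples uniformly at
    random (seeded), re-runs the full consensus procedure on the rest at the
    same r and parameters, matches labels to the reference restricted to the
    retained samples, and counts disagreements.  The error rate is total
    disagreements over total retained assignments.
    """
    V = np.asarray(V, float)
    m = V.shape[1]
    reference_assignment = np.asarray(reference_assignment)
    if reference_assignment.shape[0] != m:
        raise ValueError("reference assignment length must equal sample count")
    n_hold = int(round(holdout_fraction * m))
    if m - n_hold < r:
        raise ValueError("too few retained samples for the requested rank")

    rng = np.random.default_rng(base_seed)
    repeats: list[RepeatRecord] = []
    total_errors = 0
    total_retained = 0
    for rep in range(n_repeats):
        holdout = rng.choice(m, size=n_hold, replace=False)
        retained = np.setdiff1d(np.arange(m), holdout)
        if r == 1:
            n_err = 0  # a single cluster cannot change
        else:
            sub = run_gnmf_consensus(
                V[:, retained], r,
                n_runs=consensus_runs,
                base_seed=int(rng.integers(0, 2**31 - 1)),
                check_interval=check_interval,
                rel_tol=rel_tol,
                max_steps=max_steps,
            )
            ref_sub = reference_assignment[retained]
            if len(np.unique(sub.assignment)) < r:
                logger.warning("stability repeat %d: a cluster emptied", rep)
            _, n_err = match_labels(ref_sub, sub.assignment)
        repeats.append(
            RepeatRecord(holdout=holdout.tolist(), n_retained=len(retained), n_errors=n_err)
        )
        total_errors += n_err
        total_retained += len(retained)

    return StabilityReport(
        n_repeats=n_repeats,
        repeats=repeats,
        error_rate=total_errors / total_retained,
        r=r,
        consensus_runs=consensus_runs,
    )
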
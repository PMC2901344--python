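"""Choose the number of clusters: cophenetic correlation and lognormal BIC.

For each candidate r the consensus clustering yields a distance matrix
(1 - average H correlation), a dendrogram and a hard assignment.  Two scores
rank the candidates:

* the cophenetic correlation between original pairwise distances x(i, j)
  and dendrogram join heights t(i, j) — how faithfully the consensus tree
  preserves the distances; it drops sharply once r exceeds the true number
  of clusters; and
* BIC = -2 ln L + k ln(n) with k = 2 r m parameters (a mean and standard
  deviation per cluster per segment, m segments) and n samples, where L is
  a segment-independent lognormal likelihood: within each cluster the log
  copy numbers of each segment are modeled as Gaussian.

The primary selection rule is minimum BIC; the secondary rule picks the r
after which the cophenetic correlation drops the most.  Both are reported,
and disagreement is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .data_model import CopyNumberMatrix
from .pilot import Dendrogram

logger = logging.getLogger(__name__)

#: Floor on the within-cluster log-scale standard deviation.  Singleton
#: clusters and constant segments would otherwise give sigma = 0 and an
#: infinite likelihood spike.
SIGMA_FLOOR = 1e-3


@dataclass
class ModelScore:
    """Scores for one candidate cluster number r."""

    r: int
    cophenetic: float
    bic: float
    log_likelihood: float
    k_params: int


@dataclass
class SelectionReport:
    """Outcome of the dual-rule model selection."""

    selected_r: int
    bic_choice: int
    cophenetic_choice: int | None
    agree: bool
    scores: list[ModelScore]
    notes: list[str]


def cophenetic_correlation(
    distance_matrix: np.ndarray, dend: Dendrogram | np.ndarray
) -> float:
    """Correlation between pairwise distances and dendrogram join heights.

    Pairs are all unordered (i, j), i < j; the join height t(i, j) is the
    height of the lowest node under which both leaves sit.  Undefined (and
    raising) when all join heights are equal (star dendrogram).
    """
    Z = dend.linkage_matrix if isinstance(dend, Dendrogram) else np.asarray(dend)
    d = np.asarray(distance_matrix, float)
    m = d.shape[0]
    if m < 3:
        raise ValueError("cophenetic correlation needs at least 3 samples")
    x = squareform(d, checks=False)
    _, t = cophenet(Z, x)
    if np.ptp(t) == 0:
        raise ValueError("all join heights equal; cophenetic correlation undefined")
    if np.ptp(x) == 0:
        raise ValueError("all pairwise distances equal; correlation undefined")
    return float(np.corrcoef(x, t)[0, 1])


def gnmf_log_likelihood(
    matrix: CopyNumberMatrix | np.ndarray,
    assignment: np.ndarray,
    sigma_floor: float = SIGMA_FLOOR,
) -> tuple[float, list[dict]]:
    """Segment-independent lognormal log-likelihood of a hard clustering.

    Within cluster i, the log copy numbers of segment t are Gaussian with
    the cluster's empirical mean mu_it and standard deviation sigma_it
    (floored at ``sigma_floor``).  A singleton cluster carries no variance
    information of its own — its maximum-likelihood sigma is 0, and any
    tiny constant in its place hands the cluster an artificial likelihood
    bonus that rewards splitting off outliers.  Singletons therefore borrow
    the pooled within-cluster sigma of the clusters with >= 2 samples
    (size-weighted, per segment), falling back to ``sigma_floor`` only when
    every cluster is a singleton.  Returns the total log density over all
    samples and segments plus a per-cluster parameter table.
    """
    values = matrix.values if isinstance(matrix, CopyNumberMatrix) else np.asarray(matrix, float)
    assignment = np.asarray(assignment)
    if assignment.shape[0] != values.shape[1]:
        raise ValueError("assignment length must equal sample count")
    if np.any(values <= 0):
        raise ValueError("copy numbers must be positive for the log transform")

    y = np.log(values)
    labels = np.unique(assignment)

    # pooled per-segment sigma over informative (>= 2 sample) clusters,
    # size-weighted; lends a variance to singleton clusters
    var_acc = np.zeros(y.shape[0])
    n_acc = 0
    for label in labels:
        cols = y[:, assignment == label]
        if cols.shape[1] >= 2:
            var_acc += cols.shape[1] * cols.var(axis=1, ddof=0)
            n_acc += cols.shape[1]
    pooled_sigma = (
        np.maximum(np.sqrt(var_acc / n_acc), sigma_floor)
        if n_acc
        else np.full(y.shape[0], sigma_floor)
    )

    total = 0.0
    tables: list[dict] = []
    for label in labels:
        cols = y[:, assignment == label]
        n_i = cols.shape[1]
        mu = cols.mean(axis=1)
        if n_i < 2:
            logger.warning(
                "cluster %s has %d sample(s); using pooled within-cluster sigma",
                label, n_i,
            )
            sigma = pooled_sigma
        else:
            sigma = np.maximum(cols.std(axis=1, ddof=0), sigma_floor)
        total += float(norm.logpdf(cols, loc=mu[:, None], scale=sigma[:, None]).sum())
        tables.append({"cluster": label, "n": n_i, "mu": mu, "sigma": sigma})
    return total, tables


def gnmf_bic(
    matrix: CopyNumberMatrix | np.ndarray,
    assignment: np.ndarray,
    r: int,
    cophenetic: float = np.nan,
    sigma_floor: float = SIGMA_FLOOR,
) -> ModelScore:
    """BIC = -2 ln L + k ln(n), k = 2 r m (m segments, n samples)."""
    values = matrix.values if isinstance(matrix, CopyNumberMatrix) else np.asarray(matrix, float)
    n_samples = values.shape[1]
    m_segments = values.shape[0]
    ll, _ = gnmf_log_likelihood(values, assignment, sigma_floor)
    k = 2 * r * m_segments
    if n_samples == 1:
        logger.warning("single-sample matrix: BIC penalty term is 0 (ln 1)")
    bic = -2.0 * ll + k * np.log(n_samples)
    return ModelScore(
        r=r, cophenetic=cophenetic, bic=float(bic), log_likelihood=ll, k_params=k
    )


def select_best_model(scores: list[ModelScore]) -> SelectionReport:
    """Apply minimum BIC (primary) and greatest cophenetic decrease (secondary).

    The cophenetic rule needs consecutive r values: it selects the r whose
    step to r+1 shows the most negative change in cophenetic correlation —
    the value *before* the drop.  Ties in BIC break toward smaller r
    (parsimony).  When the rules disagree, minimum BIC wins and the report
    says so.
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 candidate models")
    scores = sorted(scores, key=lambda s: s.r)
    notes: list[str] = []

    bics = np.array([s.bic for s in scores])
    bic_choice = scores[int(np.argmin(bics))].r  # argmin takes first = smallest r

    rs = [s.r for s in scores]
    consecutive = all(b - a == 1 for a, b in zip(rs, rs[1:]))
    coph_choice: int | None = None
    if consecutive and not any(np.isnan(s.cophenetic) for s in scores):
        drops = np.array(
            [scores[i + 1].cophenetic - scores[i].cophenetic for i in range(len(scores) - 1)]
        )
        coph_choice = scores[int(np.argmin(drops))].r
    else:
        notes.append(
            "cophenetic greatest-decrease rule skipped: candidate r values "
            "not consecutive or cophenetic missing"
        )
        logger.warning(notes[-1])

    agree = coph_choice == bic_choice
    if coph_choice is not None and not agree:
        notes.append(
            f"rules disagree: min BIC -> r={bic_choice}, greatest cophenetic "
            f"decrease -> r={coph_choice}; min BIC wins"
        )
        logger.warning(notes[-1])
    return SelectionReport(
        selected_r=bic_choice,
        bic_choice=bic_choice,
        cophenetic_choice=coph_choice,
        agree=agree,
        scores=scores,
        notes=notes,
    )
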
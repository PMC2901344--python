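"""Assign new samples to discovered clusters and validate against outcomes.

A validation sample joins the cluster of its single best-correlated
representative sample (1-nearest-neighbor by Pearson correlation of
copy-number profiles).  Clinical relevance of a clustering is then tested by
comparing time-to-event endpoints (overall survival, time to recurrence)
across clusters with a logrank test and Kaplan-Meier medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .data_model import CopyNumberMatrix

logger = logging.getLogger(__name__)


@dataclass
class SurvivalTable:
    """Per-sample time-to-event records for one endpoint."""

    table: pd.DataFrame  # columns: sample, time, event
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        required = {"sample", "time", "event"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"survival table missing column(s): {sorted(missing)}")
        if (self.table["time"] < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not self.table["event"].isin([0, 1]).all():
            raise ValueError("event flags must be 0 (censored) or 1 (event)")


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    medians: dict[str, float | None]  # None = not reached
    group_sizes: dict[str, int]


def assign_by_correlation(
    new_matrix: CopyNumberMatrix,
    reference_matrix: CopyNumberMatrix,
    reference_assignment: dict[str, int],
    representative_ids: list[str] | None = None,
) -> pd.DataFrame:
    """1-NN cluster assignment by Pearson correlation.

    Each new sample is correlated against every representative reference
    sample and inherits the cluster of the best match; ties break toward
    the earlier representative in input order (logged).  Representatives
    default to all reference samples and must cover every cluster.
    """
    if not new_matrix.same_grid(reference_matrix):
        raise ValueError("new and reference matrices are on different segment grids")
    if representative_ids is None:
        representative_ids = list(reference_matrix.sample_ids)
    unknown = [s for s in representative_ids if s not in reference_assignment]
    if unknown:
        raise ValueError(f"representative(s) without cluster assignment: {unknown}")
    covered = {reference_assignment[s] for s in representative_ids}
    uncovered = set(reference_assignment.values()) - covered
    if uncovered:
        raise ValueError(f"cluster(s) with no representative: {sorted(uncovered)}")

    ref = reference_matrix.select_samples(representative_ids)
    X = new_matrix.values
    R = ref.values
    # Pearson correlation of each new column against each representative column
    Xc = (X - X.mean(axis=0)) / X.std(axis=0)
    Rc = (R - R.mean(axis=0)) / R.std(axis=0)
    corr = (Xc.T @ Rc) / X.shape[0]

    rows = []
    for j, sid in enumerate(new_matrix.sample_ids):
        best = int(np.argmax(corr[j]))  # argmax takes the first maximum: tie rule
        ties = np.sum(corr[j] == corr[j, best])
        if ties > 1:
            logger.info(
                "assign_by_correlation: sample %s has %d tied best matches; "
                "keeping first in input order", sid, ties,
            )
        rows.append(
            {
                "sample": sid,
                "cluster": reference_assignment[representative_ids[best]],
                "best_match": representative_ids[best],
                "correlation": float(corr[j, best]),
            }
        )
    return pd.DataFrame(rows)


def _km_median(times: np.ndarray, events: np.ndarray) -> float | None:
    """Kaplan-Meier median; None when fewer than half the group reaches an event."""
    km = KaplanMeierFitter()
    km.fit(times, events)
    med = km.median_survival_time_
    return None if np.isinf(med) else float(med)


def logrank_by_cluster(
    assignment: dict[str, int],
    survival: SurvivalTable,
    merge_groups: set[int] | None = None,
) -> LogrankResult:
    """k-group logrank test of the endpoint across clusters.

    ``merge_groups`` pools the listed cluster labels into one group before
    testing (e.g. merging two small clusters).  Medians come from
    Kaplan-Meier fits, reported as None ("not reached") when fewer than half
    the group has events.
    """
    df = survival.table[survival.table["sample"].isin(assignment)].copy()
    if df.empty:
        raise ValueError("no survival records match the assignment")
    df["group"] = df["sample"].map(assignment)
    if merge_groups:
        merged_label = "+".join(str(g) for g in sorted(merge_groups))
        df["group"] = df["group"].apply(
            lambda g: merged_label if g in merge_groups else str(g)
        )
    else:
        df["group"] = df["group"].astype(str)

    groups = df["group"].unique()
    if len(groups) < 2:
        raise ValueError("logrank test needs at least 2 groups")
    if df["event"].sum() == 0:
        raise ValueError("all samples censored; logrank test undefined")

    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    medians = {}
    sizes = {}
    for g, sub in df.groupby("group"):
        medians[str(g)] = _km_median(sub["time"].to_numpy(), sub["event"].to_numpy())
        sizes[str(g)] = len(sub)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        medians=medians,
        group_sizes=sizes,
    )
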
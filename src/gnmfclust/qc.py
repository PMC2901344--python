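"""Normal-contamination QC: flag and drop diluted tumor samples.

Stromal admixture pulls a tumor's copy-number profile toward flat diploid
and washes out the aberration signal the clustering relies on.  A random
forest trained to separate clearly aberrant tumors (highest aberration
burden) from normal samples scores every incoming tumor/cell-line sample;
the fraction of trees voting "normal" is read as the contamination
probability, and samples over 50% are excluded.

The forest uses extremely-randomized trees (random split thresholds rather
than impurity-optimal ones).  With optimal thresholds every split lands at
the midpoint between pure tumors and pure normals and an intermediate
mixture falls on an essentially arbitrary side, so vote fractions saturate
toward the training prior; random thresholds integrate over cut points,
making the vote fraction increase smoothly with the normal fraction of the
sample — exactly the quantity the 50% cutoff is applied to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier

from .data_model import CopyNumberMatrix, aberration_burden, call_aberrations

logger = logging.getLogger(__name__)

#: Strict decision boundary: contamination probability must exceed 0.5
#: ("over 50%") for exclusion; exactly 0.5 keeps the sample.
CONTAMINATION_CUTOFF = 0.5


@dataclass
class ContaminationReport:
    """Per-sample contamination probabilities and keep/exclude decisions."""

    table: pd.DataFrame  # columns: sample, probability, decision
    tumor_like_ids: list[str]
    normal_ids: list[str]

    def excluded(self) -> list[str]:
        return self.table.loc[self.table["decision"] == "exclude", "sample"].tolist()

    def kept(self) -> list[str]:
        return self.table.loc[self.table["decision"] == "keep", "sample"].tolist()


@dataclass
class ContaminationClassifier:
    """Fitted forest plus the segment grid it was trained on."""

    forest: ExtraTreesClassifier
    n_segments: int
    tumor_like_ids: list[str]
    normal_ids: list[str]

    def contamination_probability(self, matrix: CopyNumberMatrix) -> np.ndarray:
        if matrix.n_segments != self.n_segments:
            raise ValueError(
                f"segment grid mismatch: classifier expects {self.n_segments} "
                f"segments, matrix has {matrix.n_segments}"
            )
        proba = self.forest.predict_proba(matrix.values.T)
        normal_col = list(self.forest.classes_).index("normal")
        return proba[:, normal_col]


def build_training_set(
    matrix: CopyNumberMatrix,
    burden: dict[str, int] | None = None,
    n_top: int | None = None,
    normal_ids: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Pick the QC training classes.

    Tumor-like class: the ``n_top`` tumor/cell-line samples with the highest
    aberration burden (ties broken lexicographically by sample id); default
    n_top is 25% of tumor samples (at least 2).  Normal class: explicit ids,
    or every sample annotated ``normal``.
    """
    if burden is None:
        burden = aberration_burden(call_aberrations(matrix))
    if normal_ids is None:
        normal_ids = matrix.samples_of_class("normal")
    for nid in normal_ids:
        matrix.sample_index(nid)  # raises on unknown id
    if len(normal_ids) < 2:
        raise ValueError("need at least 2 normal samples for QC training")

    candidates = [
        s for s in matrix.samples_of_class("tumor", "cell_line", "unknown")
        if s not in set(normal_ids)
    ]
    if n_top is None:
        n_top = max(2, len(candidates) // 4)
    if n_top < 2:
        raise ValueError("n_top must be >= 2")
    if n_top > len(candidates):
        raise ValueError(
            f"n_top={n_top} exceeds the {len(candidates)} available tumor samples"
        )
    ranked = sorted(candidates, key=lambda s: (-burden.get(s, 0), s))
    tumor_like = ranked[:n_top]
    return tumor_like, list(normal_ids)


def fit_contamination_classifier(
    matrix: CopyNumberMatrix,
    tumor_like_ids: list[str],
    normal_ids: list[str],
    n_trees: int = 500,
    seed: int = 0,
) -> ContaminationClassifier:
    """Train the tumor-vs-normal randomized forest on segment copy numbers."""
    if not tumor_like_ids or not normal_ids:
        raise ValueError("both training classes must be non-empty")
    overlap = set(tumor_like_ids) & set(normal_ids)
    if overlap:
        raise ValueError(f"sample(s) in both training classes: {sorted(overlap)}")

    train = matrix.select_samples(list(tumor_like_ids) + list(normal_ids))
    X = train.values.T
    y = ["tumor"] * len(tumor_like_ids) + ["normal"] * len(normal_ids)
    forest = ExtraTreesClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    return ContaminationClassifier(
        forest=forest,
        n_segments=matrix.n_segments,
        tumor_like_ids=list(tumor_like_ids),
        normal_ids=list(normal_ids),
    )


def score_and_filter(
    matrix: CopyNumberMatrix,
    classifier: ContaminationClassifier,
    cutoff: float = CONTAMINATION_CUTOFF,
) -> tuple[ContaminationReport, CopyNumberMatrix]:
    """Score every tumor/cell-line sample and drop the contaminated ones.

    Normal samples never enter the clustering matrix.  A sample is excluded
    iff its contamination probability is strictly greater than ``cutoff``.
    """
    target_ids = matrix.samples_of_class("tumor", "cell_line", "unknown")
    target = matrix.select_samples(target_ids)
    prob = classifier.contamination_probability(target)
    decision = np.where(prob > cutoff, "exclude", "keep")
    table = pd.DataFrame(
        {"sample": target_ids, "probability": prob, "decision": decision}
    )
    kept = table.loc[table["decision"] == "keep", "sample"].tolist()
    n_excl = len(target_ids) - len(kept)
    if n_excl:
        logger.info("QC excluded %d/%d sample(s) as contaminated", n_excl, len(target_ids))
    report = ContaminationReport(
        table=table,
        tumor_like_ids=classifier.tumor_like_ids,
        normal_ids=classifier.normal_ids,
    )
    return report, matrix.select_samples(kept)


def run_qc(
    matrix: CopyNumberMatrix,
    n_top: int | None = None,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[ContaminationReport | None, CopyNumberMatrix]:
    """Convenience wrapper: train on burden-ranked tumors vs annotated normals.

    Without any annotated normal samples QC cannot run; it is skipped with a
    warning and the tumor/cell-line matrix passes through unfiltered.
    """
    normal_ids = matrix.samples_of_class("normal")
    if len(normal_ids) < 2:
        logger.warning("QC skipped: fewer than 2 normal samples annotated")
        keep = matrix.samples_of_class("tumor", "cell_line", "unknown")
        return None, matrix.select_samples(keep)
    tumor_like, normals = build_training_set(matrix, n_top=n_top, normal_ids=normal_ids)
    clf = fit_contamination_classifier(matrix, tumor_like, normals, n_trees, seed)
    return score_and_filter(matrix, clf)
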
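"""End-to-end orchestration: QC -> pilot -> consensus NMF -> selection -> stability.

``run_full_workflow`` wires the stages together exactly as the separate
subcommands would run them (same seeds, same parameters), persists every
stage's tabular output, and writes a JSON manifest with versions, seeds,
parameters and input checksums so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import CopyNumberMatrix, read_matrix, reduce_dimensions
from .model_selection import (
    ModelScore,
    SelectionReport,
    cophenetic_correlation,
    gnmf_bic,
    select_best_model,
)
from .nmf import ConsensusResult, run_gnmf_consensus
from .pilot import Dendrogram, hierarchical_cluster, pearson_dissimilarity, suggest_cluster_range
from .qc import ContaminationReport, run_qc
from .stability import StabilityReport, tenfold_stability

logger = logging.getLogger(__name__)


@dataclass
class WorkflowConfig:
    """Everything a full run needs; round-trips through YAML."""

    matrix_path: str = ""
    out_dir: str = "gnmf_out"
    floor: float = 0.01
    min_range: float = 0.0
    # QC
    qc_enabled: bool = True
    qc_n_top: int | None = None
    qc_n_trees: int = 500
    # candidate ranks
    r_min: int = 2
    r_max: int = 5
    # consensus NMF
    n_runs: int = 200
    base_seed: int = 0
    check_interval: int = 100
    rel_tol: float = 1e-5
    max_steps: int = 20_000
    # stability
    stability_repeats: int = 200
    stability_runs: int | None = None  # defaults to n_runs
    holdout_fraction: float = 0.1

    def validate(self) -> None:
        if not (2 <= self.r_min <= self.r_max):
            raise ValueError("need 2 <= r_min <= r_max")
        if self.n_runs < 1 or self.check_interval < 1 or self.max_steps < 1:
            raise ValueError("run counts and step limits must be positive")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.rel_tol < 0 or self.floor <= 0:
            raise ValueError("rel_tol must be >= 0 and floor > 0")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class WorkflowResult:
    config: WorkflowConfig
    qc_report: ContaminationReport | None
    pilot_dendrogram: Dendrogram
    suggested_range: tuple[int, int, bool]
    consensus: dict[int, ConsensusResult]
    selection: SelectionReport
    stability: StabilityReport
    matrix: CopyNumberMatrix
    manifest: dict = field(default_factory=dict)

    @property
    def selected_r(self) -> int:
        return self.selection.selected_r

    @property
    def assignment(self) -> np.ndarray:
        return self.consensus[self.selected_r].assignment


def _checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_full_workflow(
    config: WorkflowConfig,
    matrix: CopyNumberMatrix | None = None,
    write_outputs: bool = True,
) -> WorkflowResult:
    """Execute the whole classification pipeline.

    ``matrix`` may be passed directly (e.g. from the simulator) instead of
    ``config.matrix_path``.  Each stage's outputs go under ``config.out_dir``
    as the stage finishes, so a failing stage leaves earlier results behind.
    """
    config.validate()
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "package_version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    if matrix is None:
        if not config.matrix_path:
            raise ValueError("no input matrix: set matrix_path or pass matrix")
        matrix = read_matrix(config.matrix_path, floor=config.floor)
        manifest["input_checksum"] = _checksum(config.matrix_path)

    stage = "qc"
    try:
        if config.qc_enabled:
            qc_report, clustering_matrix = run_qc(
                matrix, n_top=config.qc_n_top,
                n_trees=config.qc_n_trees, seed=config.base_seed,
            )
        else:
            qc_report = None
            keep = matrix.samples_of_class("tumor", "cell_line", "unknown")
            clustering_matrix = matrix.select_samples(keep)
        if write_outputs and qc_report is not None:
            qc_report.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["stages"]["qc"] = {
            "n_input": matrix.n_samples,
            "n_kept": clustering_matrix.n_samples,
        }

        stage = "dimension_reduction"
        if config.min_range > 0:
            clustering_matrix = reduce_dimensions(clustering_matrix, config.min_range)
        manifest["stages"]["dimension_reduction"] = {
            "n_segments": clustering_matrix.n_segments
        }

        stage = "pilot"
        dist = pearson_dissimilarity(clustering_matrix)
        dend = hierarchical_cluster(dist, clustering_matrix.sample_ids)
        # the pilot scans a little beyond the candidate range so a degenerate
        # single-candidate config still yields a valid advisory bracket
        pilot_max_k = min(
            max(config.r_max + 1, 8), clustering_matrix.n_samples - 1
        )
        k_lo, k_hi, low_conf = suggest_cluster_range(
            dend, min_k=min(config.r_min, pilot_max_k - 1), max_k=pilot_max_k
        )
        manifest["stages"]["pilot"] = {
            "suggested_range": [k_lo, k_hi], "low_confidence": low_conf,
        }

        stage = "consensus"
        consensus: dict[int, ConsensusResult] = {}
        scores: list[ModelScore] = []
        for r in range(config.r_min, config.r_max + 1):
            res = run_gnmf_consensus(
                clustering_matrix.values, r,
                n_runs=config.n_runs,
                base_seed=config.base_seed + 1000 * r,
                check_interval=config.check_interval,
                rel_tol=config.rel_tol,
                max_steps=config.max_steps,
            )
            consensus[r] = res
            coph = cophenetic_correlation(res.distance_matrix, res.linkage_matrix)
            scores.append(
                gnmf_bic(clustering_matrix, res.assignment, r, cophenetic=coph)
            )
            if write_outputs:
                pd.DataFrame(
                    res.avg_correlation,
                    index=clustering_matrix.sample_ids,
                    columns=clustering_matrix.sample_ids,
                ).to_csv(out / f"consensus_r{r}.tsv", sep="\t")

        stage = "model_selection"
        if len(scores) == 1:
            logger.warning("single candidate r=%d: selection is trivial", scores[0].r)
            selection = SelectionReport(
                selected_r=scores[0].r, bic_choice=scores[0].r,
                cophenetic_choice=None, agree=False, scores=scores,
                notes=["single-candidate range; selection trivial"],
            )
        else:
            selection = select_best_model(scores)
        if write_outputs:
            pd.DataFrame(
                [
                    {"r": s.r, "cophenetic": s.cophenetic, "BIC": s.bic,
                     "log_likelihood": s.log_likelihood}
                    for s in selection.scores
                ]
            ).to_csv(out / "model_scores.tsv", sep="\t", index=False)
        manifest["stages"]["model_selection"] = {
            "selected_r": selection.selected_r,
            "bic_choice": selection.bic_choice,
            "cophenetic_choice": selection.cophenetic_choice,
        }

        stage = "stability"
        stab_runs = config.stability_runs or config.n_runs
        stability = tenfold_stability(
            clustering_matrix.values,
            selection.selected_r,
            consensus[selection.selected_r].assignment,
            n_repeats=config.stability_repeats,
            holdout_fraction=config.holdout_fraction,
            base_seed=config.base_seed,
            consensus_runs=stab_runs,
            check_interval=config.check_interval,
            rel_tol=config.rel_tol,
            max_steps=config.max_steps,
        )
        manifest["stages"]["stability"] = {
            "error_rate": stability.error_rate,
            "n_repeats": stability.n_repeats,
        }

        if write_outputs:
            pd.DataFrame(
                {
                    "sample": clustering_matrix.sample_ids,
                    "cluster": consensus[selection.selected_r].assignment + 1,
                }
            ).to_csv(out / "assignment.tsv", sep="\t", index=False)
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"workflow failed at stage '{stage}': {exc}") from exc

    return WorkflowResult(
        config=config,
        qc_report=qc_report,
        pilot_dendrogram=dend,
        suggested_range=(k_lo, k_hi, low_conf),
        consensus=consensus,
        selection=selection,
        stability=stability,
        matrix=clustering_matrix,
        manifest=manifest,
    )
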
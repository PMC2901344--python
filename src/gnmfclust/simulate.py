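"""Synthetic copy-number cohorts with planted cluster structure.

Each cluster has a blueprint profile: diploid (2 copies) everywhere except a
set of aberrant segment blocks set to a target copy number (e.g. gain to 3.2,
loss to 1.2).  Observed values are the blueprint times multiplicative
lognormal noise, ``blueprint * exp(N(0, sigma^2))`` per cell — the same
noise model the lognormal likelihood in model selection assumes, so
parameter-recovery tests close the loop.  Cohorts may include flat normal
samples and contaminated samples built as convex mixtures
``w * normal + (1 - w) * tumor blueprint`` before noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CopyNumberMatrix, Segment


@dataclass(frozen=True)
class AberrationBlock:
    """Contiguous run of segments set to a target copy number."""

    start_index: int
    end_index: int  # half-open
    copy_number: float

    def __post_init__(self) -> None:
        if self.copy_number <= 0:
            raise ValueError("target copy number must be > 0")
        if self.start_index >= self.end_index:
            raise ValueError("block start_index must be < end_index")


@dataclass
class SimulationDesign:
    """Recipe for one synthetic cohort.

    ``cluster_sizes`` defines the planted number of clusters r*;
    ``blueprints`` gives the aberration blocks per cluster.  ``sigma`` is the
    lognormal noise scale on the log-copy-number axis.  Contaminated samples
    draw their mixing weight w (fraction normal) uniformly from
    ``contamination_weight`` and inherit the blueprint of a cycling tumor
    cluster.
    """

    n_segments: int
    cluster_sizes: list[int]
    blueprints: list[list[AberrationBlock]]
    sigma: float = 0.1
    n_normal: int = 0
    n_contaminated: int = 0
    contamination_weight: tuple[float, float] = (0.7, 0.9)
    seed: int = 0
    name: str = "cohort"

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != len(self.blueprints):
            raise ValueError("one blueprint per cluster required")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        lo, hi = self.contamination_weight
        if not (0 <= lo <= hi <= 1):
            raise ValueError("contamination weights must satisfy 0 <= lo <= hi <= 1")
        seen = set()
        for bp in self.blueprints:
            key = tuple(sorted((b.start_index, b.end_index, b.copy_number) for b in bp))
            if key in seen:
                raise ValueError("cluster blueprints must be pairwise distinct")
            seen.add(key)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)


def _blueprint_profile(design: SimulationDesign, cluster: int) -> np.ndarray:
    profile = np.full(design.n_segments, 2.0)
    for block in design.blueprints[cluster]:
        if block.end_index > design.n_segments:
            raise ValueError("aberration block exceeds segment count")
        profile[block.start_index : block.end_index] = block.copy_number
    return profile


def _pseudo_grid(n_segments: int) -> list[Segment]:
    """22 pseudo-autosomes with uniform 1 Mb segments; coordinates arbitrary."""
    per_chrom = -(-n_segments // 22)  # ceil
    segments = []
    i = 0
    for c in range(1, 23):
        for k in range(per_chrom):
            if i >= n_segments:
                return segments
            segments.append(Segment(f"chr{c}", k * 1_000_000, (k + 1) * 1_000_000, 100))
            i += 1
    return segments


def simulate_cohort(
    design: SimulationDesign,
) -> tuple[CopyNumberMatrix, dict[str, int], dict[str, bool]]:
    """Draw one cohort.

    Returns the matrix, the true cluster label per tumor sample (normals and
    contaminated samples are absent from this dict), and a per-sample
    contamination flag (True for the mixture samples).
    Deterministic given ``design.seed``.
    """
    total = sum(design.cluster_sizes) + design.n_normal + design.n_contaminated
    if total == 0:
        raise ValueError("cohort has zero samples")
    rng = np.random.default_rng(design.seed)

    profiles: list[np.ndarray] = []
    sample_ids: list[str] = []
    sample_class: list[str] = []
    truth: dict[str, int] = {}
    contaminated: dict[str, bool] = {}

    for c, size in enumerate(design.cluster_sizes):
        bp = _blueprint_profile(design, c)
        for j in range(size):
            sid = f"T{c + 1}_{j + 1:02d}"
            profiles.append(bp)
            sample_ids.append(sid)
            sample_class.append("tumor")
            truth[sid] = c
            contaminated[sid] = False

    normal_bp = np.full(design.n_segments, 2.0)
    for j in range(design.n_normal):
        sid = f"N_{j + 1:02d}"
        profiles.append(normal_bp)
        sample_ids.append(sid)
        sample_class.append("normal")
        contaminated[sid] = False

    n_clusters = max(design.n_clusters, 1)
    for j in range(design.n_contaminated):
        sid = f"C_{j + 1:02d}"
        w = rng.uniform(*design.contamination_weight)
        tumor_bp = (
            _blueprint_profile(design, j % n_clusters)
            if design.n_clusters
            else normal_bp
        )
        profiles.append(w * normal_bp + (1 - w) * tumor_bp)
        sample_ids.append(sid)
        sample_class.append("tumor")  # looks like a tumor specimen on arrival
        contaminated[sid] = True

    blueprint = np.column_stack(profiles)
    noise = (
        np.exp(rng.normal(0.0, design.sigma, blueprint.shape))
        if design.sigma > 0
        else 1.0
    )
    values = blueprint * noise
    matrix = CopyNumberMatrix(
        values, _pseudo_grid(design.n_segments), sample_ids, sample_class
    )
    return matrix, truth, contaminated


def _block_grid(
    n_segments: int, n_clusters: int, gain: float, loss: float, width: int
) -> list[list[AberrationBlock]]:
    """Give each cluster a disjoint gained block and a disjoint lost block."""
    blueprints = []
    for c in range(n_clusters):
        start = c * 2 * width
        blueprints.append(
            [
                AberrationBlock(start, start + width, gain),
                AberrationBlock(start + width, start + 2 * width, loss),
            ]
        )
    if n_clusters * 2 * width > n_segments:
        raise ValueError("not enough segments for the requested blueprints")
    return blueprints


def default_benchmark_designs(seed: int = 0) -> dict[str, SimulationDesign]:
    """The named fixtures the test-suite and benchmarks run on.

    - ``separable-3``: 3 clusters x 20 samples, 200 segments, strong
      aberrations (gain 3.2 / loss 1.2, i.e. shifts of +1.2 / -0.8 copies
      against diploid), sigma = 0.1.  The anchor fixture: consensus NMF at
      r = 3 should recover the partition exactly.
    - ``overlapping-4``: 4 clusters with weaker shifts (2.6 / 1.5) and more
      noise; clustering is possible but no longer trivial.
    - ``null``: 40 i.i.d. diploid samples — no structure at all.
    - ``contaminated``: 3 tumor clusters plus normals plus 20% of samples
      built as >= 70% normal mixtures, exercising the QC filter.
    """
    return {
        "separable-3": SimulationDesign(
            n_segments=200,
            cluster_sizes=[20, 20, 20],
            blueprints=_block_grid(200, 3, gain=3.2, loss=1.2, width=20),
            sigma=0.1,
            seed=seed,
            name="separable-3",
        ),
        "overlapping-4": SimulationDesign(
            n_segments=200,
            cluster_sizes=[20, 20, 20, 20],
            blueprints=_block_grid(200, 4, gain=2.6, loss=1.5, width=15),
            sigma=0.15,
            seed=seed,
            name="overlapping-4",
        ),
        "null": SimulationDesign(
            n_segments=200,
            cluster_sizes=[40],
            blueprints=[[]],
            sigma=0.1,
            seed=seed,
            name="null",
        ),
        "contaminated": SimulationDesign(
            n_segments=200,
            cluster_sizes=[24, 24, 24],
            blueprints=_block_grid(200, 3, gain=3.2, loss=1.2, width=20),
            sigma=0.1,
            n_normal=10,
            n_contaminated=18,
            contamination_weight=(0.7, 0.9),
            seed=seed,
            name="contaminated",
        ),
    }
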
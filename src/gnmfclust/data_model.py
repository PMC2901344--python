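"""Core data types and I/O for segment-smoothed copy-number data.

The universal container is :class:`CopyNumberMatrix`: an ``n_segments x
n_samples`` matrix of strictly positive copy numbers (diploid = 2) together
with the genomic segment grid and per-sample class labels.  Files use
1-based inclusive coordinates; internally coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Copy-number state thresholds: strict inequalities, boundary values are
#: called normal ("lower than 1.65 (deletion) or higher than 2.65 (gain)").
LOSS_THRESHOLD = 1.65
GAIN_THRESHOLD = 2.65

#: Default positivity floor applied at load time (copies).  NMF divergence
#: and the lognormal likelihood require strictly positive entries; homozygous
#: deletions can legitimately reach 0.
DEFAULT_FLOOR = 0.01

SampleClass = Literal["tumor", "cell_line", "normal", "unknown"]

META_COLUMNS = ["chrom", "start", "end", "n_probes"]


class CopyNumberError(ValueError):
    """Raised on malformed copy-number input."""


@dataclass(frozen=True)
class Segment:
    """A genomic interval of approximately constant copy number.

    Coordinates are 0-based half-open.  ``n_probes`` records how many array
    probes supported the segment during upstream segmentation (provenance
    only; segmentation itself happens before this package is invoked).
    """

    chromosome: str
    start: int
    end: int
    n_probes: int = 1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CopyNumberError(
                f"segment {self.chromosome}:{self.start}-{self.end}: start must be < end"
            )
        if self.n_probes < 1:
            raise CopyNumberError(
                f"segment {self.chromosome}:{self.start}-{self.end}: n_probes must be >= 1"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _validate_segment_grid(segments: Sequence[Segment]) -> None:
    """Segments on the same chromosome must be sorted and non-overlapping."""
    last: dict[str, Segment] = {}
    for i, seg in enumerate(segments):
        prev = last.get(seg.chromosome)
        if prev is not None:
            if seg.start < prev.end:
                raise CopyNumberError(
                    f"segment row {i} ({seg.chromosome}:{seg.start}-{seg.end}) overlaps "
                    f"or precedes {prev.chromosome}:{prev.start}-{prev.end}"
                )
        last[seg.chromosome] = seg


@dataclass
class CopyNumberMatrix:
    """Segments x samples matrix of strictly positive copy numbers.

    Parameters
    ----------
    values
        Array of shape ``(n_segments, n_samples)``; diploid = 2.
    segments
        Ordered segment grid, one per row.
    sample_ids
        Unique sample labels, one per column.
    sample_class
        Per-sample label in {tumor, cell_line, normal, unknown}.
    """

    values: np.ndarray
    segments: list[Segment]
    sample_ids: list[str]
    sample_class: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CopyNumberError("values must be 2-dimensional")
        n, m = self.values.shape
        if len(self.segments) != n:
            raise CopyNumberError(
                f"{len(self.segments)} segments but {n} value rows"
            )
        if len(self.sample_ids) != m:
            raise CopyNumberError(
                f"{len(self.sample_ids)} sample ids but {m} value columns"
            )
        if len(set(self.sample_ids)) != m:
            dupes = sorted(
                s for s in set(self.sample_ids) if self.sample_ids.count(s) > 1
            )
            raise CopyNumberError(f"duplicate sample id(s): {', '.join(dupes)}")
        if not self.sample_class:
            self.sample_class = ["unknown"] * m
        if len(self.sample_class) != m:
            raise CopyNumberError("sample_class length must match sample count")
        bad = set(self.sample_class) - {"tumor", "cell_line", "normal", "unknown"}
        if bad:
            raise CopyNumberError(f"invalid sample class(es): {sorted(bad)}")
        if not np.all(np.isfinite(self.values)):
            raise CopyNumberError("values contain non-finite entries")
        if np.any(self.values <= 0):
            raise CopyNumberError(
                "values must be strictly positive; apply a floor at load time"
            )
        _validate_segment_grid(self.segments)

    # -- basic accessors -------------------------------------------------
    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def select_samples(self, ids: Sequence[str]) -> "CopyNumberMatrix":
        """Return a column-subset matrix preserving the given order."""
        idx = [self.sample_index(s) for s in ids]
        return CopyNumberMatrix(
            values=self.values[:, idx].copy(),
            segments=list(self.segments),
            sample_ids=[self.sample_ids[i] for i in idx],
            sample_class=[self.sample_class[i] for i in idx],
        )

    def samples_of_class(self, *classes: str) -> list[str]:
        return [
            s for s, c in zip(self.sample_ids, self.sample_class) if c in classes
        ]

    def same_grid(self, other: "CopyNumberMatrix") -> bool:
        return self.segments == other.segments

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with 1-based inclusive coordinates (file convention)."""
        meta = pd.DataFrame(
            {
                "chrom": [s.chromosome for s in self.segments],
                "start": [s.start + 1 for s in self.segments],
                "end": [s.end for s in self.segments],
                "n_probes": [s.n_probes for s in self.segments],
            }
        )
        vals = pd.DataFrame(self.values, columns=self.sample_ids)
        return pd.concat([meta, vals], axis=1)


@dataclass(frozen=True)
class AberrationCall:
    """Gain/normal/loss state of one (segment, sample) cell."""

    sample_id: str
    segment_index: int
    state: Literal["gain", "normal", "loss"]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_matrix(
    path: str | Path,
    floor: float = DEFAULT_FLOOR,
    sample_class: dict[str, str] | None = None,
) -> CopyNumberMatrix:
    """Read a tab-delimited copy-number matrix.

    Expected columns: ``chrom  start  end  n_probes  <sample1> <sample2> ...``
    with a header row; coordinates 1-based inclusive.  Any value <= ``floor``
    is replaced by ``floor`` (count logged) so downstream factorization and
    lognormal likelihoods are defined.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if header[: len(META_COLUMNS)] != META_COLUMNS:
        raise CopyNumberError(
            f"{path}: header must start with {META_COLUMNS}, got {header[:4]}"
        )
    sample_ids = header[len(META_COLUMNS):]
    if not sample_ids:
        raise CopyNumberError(f"{path}: no sample columns")
    dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
    if dupes:
        raise CopyNumberError(f"{path}: duplicate sample id(s): {', '.join(dupes)}")

    df = pd.read_csv(path, sep="\t", header=None, names=header, skiprows=1)
    try:
        values = df[sample_ids].to_numpy(dtype=float)
    except ValueError as exc:
        raise CopyNumberError(f"{path}: non-numeric copy-number cell ({exc})") from exc
    if not np.all(np.isfinite(values)):
        row, col = np.argwhere(~np.isfinite(values))[0]
        raise CopyNumberError(
            f"{path}: non-numeric cell at data row {row + 1}, sample {sample_ids[col]}"
        )

    segments = [
        Segment(str(c), int(s) - 1, int(e), int(p))
        for c, s, e, p in zip(df["chrom"], df["start"], df["end"], df["n_probes"])
    ]

    n_floored = int(np.sum(values <= floor))
    if n_floored:
        logger.info("read_matrix: floored %d value(s) at %.4g", n_floored, floor)
        values = np.maximum(values, floor)

    classes = None
    if sample_class is not None:
        classes = [sample_class.get(s, "unknown") for s in sample_ids]
    return CopyNumberMatrix(values, segments, sample_ids, classes or [])


def write_matrix(matrix: CopyNumberMatrix, path: str | Path) -> None:
    """Write the matrix in the tab-delimited format read by :func:`read_matrix`."""
    matrix.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_seg_tables(
    paths: Iterable[str | Path],
    segment_grid: Sequence[Segment],
    fill_value: float = 2.0,
) -> CopyNumberMatrix:
    """Project per-sample SEG-like tables onto a shared segment grid.

    Each file holds columns ``sample  chrom  start  end  n_probes  mean_cn``
    (linear copy number, not log2 ratio; coordinates 1-based inclusive).
    Grid values are coverage-weighted means of overlapping sample segments;
    grid segments with no coverage get the diploid ``fill_value`` with a
    warning.
    """
    segment_grid = list(segment_grid)
    _validate_segment_grid(segment_grid)
    grid_chroms = {s.chromosome for s in segment_grid}

    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    for path in paths:
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if df.empty:
            raise CopyNumberError(f"{path}: empty segment table")
        required = {"sample", "chrom", "start", "end", "n_probes", "mean_cn"}
        missing = required - set(df.columns)
        if missing:
            raise CopyNumberError(f"{path}: missing column(s) {sorted(missing)}")
        names = df["sample"].unique()
        if len(names) != 1:
            raise CopyNumberError(f"{path}: expected one sample per file, got {list(names)}")
        sample = str(names[0])
        bad_chroms = set(df["chrom"].astype(str)) - grid_chroms
        if bad_chroms:
            raise CopyNumberError(
                f"{path}: chromosome(s) {sorted(bad_chroms)} not in grid"
            )

        col = np.full(len(segment_grid), np.nan)
        for gi, gseg in enumerate(segment_grid):
            on_chrom = df[df["chrom"].astype(str) == gseg.chromosome]
            starts = on_chrom["start"].to_numpy(dtype=int) - 1  # to half-open
            ends = on_chrom["end"].to_numpy(dtype=int)
            overlap = np.minimum(ends, gseg.end) - np.maximum(starts, gseg.start)
            mask = overlap > 0
            if mask.any():
                w = overlap[mask].astype(float)
                col[gi] = np.average(on_chrom["mean_cn"].to_numpy()[mask], weights=w)
        n_missing = int(np.isnan(col).sum())
        if n_missing:
            logger.warning(
                "read_seg_tables: sample %s lacks coverage for %d grid segment(s); "
                "filled with %.3g", sample, n_missing, fill_value,
            )
            col = np.where(np.isnan(col), fill_value, col)
        columns.append(col)
        sample_ids.append(sample)

    values = np.column_stack(columns)
    return CopyNumberMatrix(values, segment_grid, sample_ids)


# ---------------------------------------------------------------------------
# Aberration calling and dimension reduction
# ---------------------------------------------------------------------------

def call_aberrations(
    matrix: CopyNumberMatrix,
    loss_threshold: float = LOSS_THRESHOLD,
    gain_threshold: float = GAIN_THRESHOLD,
) -> list[AberrationCall]:
    """Call each (segment, sample) cell as gain / normal / loss.

    Thresholds are strict: a value must be strictly below ``loss_threshold``
    to be a loss and strictly above ``gain_threshold`` to be a gain; boundary
    values are normal.
    """
    if loss_threshold >= gain_threshold:
        raise ValueError("loss_threshold must be < gain_threshold")
    calls: list[AberrationCall] = []
    for j, sid in enumerate(matrix.sample_ids):
        col = matrix.values[:, j]
        for i, v in enumerate(col):
            if v < loss_threshold:
                state = "loss"
            elif v > gain_threshold:
                state = "gain"
            else:
                state = "normal"
            calls.append(AberrationCall(sid, i, state))
    return calls


def aberration_burden(calls: Iterable[AberrationCall]) -> dict[str, int]:
    """Count aberrant (gain or loss) segments per sample.

    High-burden samples are the clearest tumors and seed the QC training set.
    """
    burden: dict[str, int] = {}
    for call in calls:
        burden.setdefault(call.sample_id, 0)
        if call.state != "normal":
            burden[call.sample_id] += 1
    return burden


def reduce_dimensions(
    matrix: CopyNumberMatrix, min_range: float = 0.0
) -> CopyNumberMatrix:
    """Drop segments whose across-sample range (max - min) is <= ``min_range``.

    A simple variability filter: with the default ``min_range=0`` the matrix
    passes through unchanged.  Raises if every segment would be dropped.
    """
    if min_range < 0:
        raise ValueError("min_range must be >= 0")
    rng = matrix.values.max(axis=1) - matrix.values.min(axis=1)
    keep = rng > min_range if min_range > 0 else np.ones(matrix.n_segments, bool)
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise CopyNumberError(
            "reduce_dimensions dropped all segments; lower min_range"
        )
    logger.info(
        "reduce_dimensions: kept %d / %d segments (min_range=%.4g)",
        n_kept, matrix.n_segments, min_range,
    )
    return CopyNumberMatrix(
        values=matrix.values[keep, :].copy(),
        segments=[s for s, k in zip(matrix.segments, keep) if k],
        sample_ids=list(matrix.sample_ids),
        sample_class=list(matrix.sample_class),
    )
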
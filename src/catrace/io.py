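"""Line-scan kymograph and fluorescence-trace I/O.

A line scan is a 2-D fluorescence matrix whose rows are successive scan
lines of a single line drawn across a cell; stacking rows over time gives a
kymograph with the time axis along rows (row 0 is t = 0).  Collapsing a
kymograph by per-line averaging yields the fluorescence-versus-time trace
that all downstream analysis operates on.

Supported formats: single-page grayscale TIFF (8/16-bit or float), grayscale
PNG, numeric matrix CSV, and 2-column (time_s, intensity) trace CSV.
Intensities are kept in native units; no bit-depth rescaling is applied on
read because the downstream dF/F0 normalization is scale invariant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

#: Line period of the reference acquisition protocol (75 ms per scan line).
DEFAULT_LINE_PERIOD_S = 0.075

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass
class LineScan:
    """A kymograph: ``matrix[i, j]`` is pixel ``j`` of scan line ``i``.

    Parameters
    ----------
    matrix
        Fluorescence intensities, shape ``(n_lines, n_pixels)``; finite and
        non-negative.
    line_period_s
        Time between successive scan lines, seconds.
    origin_label
        Free-text provenance (file name, cell id, ...).
    """

    matrix: np.ndarray
    line_period_s: float = DEFAULT_LINE_PERIOD_S
    origin_label: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DataError(
                f"line scan must be a 2-D matrix, got {self.matrix.ndim} dimensions"
            )
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 1:
            raise DataError("line scan must have at least one line and one pixel")
        if not np.all(np.isfinite(self.matrix)):
            raise DataError("line scan contains non-finite intensities")
        if np.any(self.matrix < 0):
            raise DataError("line scan contains negative intensities")
        if not (self.line_period_s > 0):
            raise DataError("line_period_s must be > 0")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]

    @property
    def duration_s(self) -> float:
        """Total span covered by the scan, ``n_lines * line_period_s``."""
        return self.n_lines * self.line_period_s


@dataclass
class FluorescenceTrace:
    """A uniformly sampled fluorescence time series."""

    time_s: np.ndarray
    intensity: np.ndarray
    origin_label: str = field(default="")

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s.shape != self.intensity.shape or self.time_s.ndim != 1:
            raise DataError("time and intensity must be equal-length 1-D vectors")
        if self.time_s.size == 0:
            raise DataError("empty trace")
        if self.time_s.size > 1:
            dt = np.diff(self.time_s)
            if np.any(dt <= 0):
                raise DataError("non-monotone time column")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=0):
                raise DataError("time grid is not uniform")

    @property
    def dt_s(self) -> float:
        if self.time_s.size < 2:
            return float("nan")
        return float(self.time_s[1] - self.time_s[0])

    @property
    def duration_s(self) -> float:
        """Span including the final sampling interval."""
        if self.time_s.size < 2:
            return 0.0
        return float(self.time_s[-1] - self.time_s[0] + self.dt_s)

    def __len__(self) -> int:
        return int(self.time_s.size)


def read_linescan(
    path: str | Path,
    line_period_s: float = DEFAULT_LINE_PERIOD_S,
    transpose: bool = False,
) -> LineScan:
    """Load a kymograph from TIFF/PNG or matrix CSV.

    Rows are interpreted as scan lines (time along rows); pass
    ``transpose=True`` for column-major files.  Multi-channel images are
    rejected: split channels upstream and pass a single-channel image.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if path.suffix.lower() in _IMAGE_SUFFIXES:
        if path.suffix.lower() == ".png":
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path))
        else:
            import tifffile

            arr = np.asarray(tifffile.imread(path))
        if arr.ndim == 3:
            raise DataError(
                f"image has {arr.shape[-1]} channels; expected single-channel "
                "grayscale — pre-split channels before analysis"
            )
        if arr.ndim != 2:
            raise DataError(f"expected 2-D image, got {arr.ndim}-D")
        matrix = arr.astype(float)
    else:
        matrix = _read_matrix_csv(path)
    if transpose:
        matrix = matrix.T
    return LineScan(matrix, line_period_s=line_period_s, origin_label=path.name)


def _read_matrix_csv(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh)):
            if not row:
                continue
            vals = []
            for j, cell in enumerate(row):
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise DataError(
                        f"non-numeric value {cell!r} at row {i + 1}, column {j + 1} "
                        f"of {path.name}"
                    ) from None
            rows.append(vals)
    if not rows:
        raise DataError(f"empty matrix file: {path}")
    if len({len(r) for r in rows}) != 1:
        raise DataError(f"ragged rows in matrix file: {path}")
    return np.asarray(rows, dtype=float)


def write_linescan(scan: LineScan, path: str | Path) -> Path:
    """Write a kymograph as float32 single-page TIFF or matrix CSV."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, scan.matrix.astype(np.float32))
    else:
        np.savetxt(path, scan.matrix, delimiter=",")
    return path


def collapse_to_trace(scan: LineScan) -> FluorescenceTrace:
    """Average each scan line to one intensity sample.

    ``intensity[i]`` is the mean of line ``i`` and ``time_s[i] = i *
    line_period_s``, so a 4000-line scan at 75 ms/line yields a 300 s trace
    whose final sample sits at 299.925 s.
    """
    intensity = scan.matrix.mean(axis=1)
    time_s = np.arange(scan.n_lines) * scan.line_period_s
    return FluorescenceTrace(time_s, intensity, origin_label=scan.origin_label)


def read_trace(path: str | Path) -> FluorescenceTrace:
    """Read a 2-column (time_s, intensity) CSV trace.

    A header row is accepted and skipped.  Non-monotone time columns and
    empty files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise DataError(f"empty trace file: {path}") from None
    # tolerate a header row of labels
    if df.shape[0] and not np.issubdtype(np.asarray(df.iloc[0]).dtype, np.number):
        try:
            [float(v) for v in df.iloc[0]]
        except (TypeError, ValueError):
            df = df.iloc[1:]
    if df.shape[0] == 0:
        raise DataError(f"empty trace file: {path}")
    if df.shape[1] < 2:
        raise DataError(f"expected 2 columns (time_s, intensity) in {path}")
    try:
        arr = df.iloc[:, :2].astype(float).to_numpy()
    except ValueError as exc:
        raise DataError(f"non-numeric value in trace file {path}: {exc}") from None
    return FluorescenceTrace(arr[:, 0], arr[:, 1], origin_label=path.name)


def write_trace(trace: FluorescenceTrace, path: str | Path) -> Path:
    """Write a trace as 2-column CSV with full double precision."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "intensity"])
        for t, f in zip(trace.time_s, trace.intensity):
            w.writerow([repr(float(t)), repr(float(f))])
    return path
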
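"""Dose grids, the textgrid interchange format, normalization and dose thresholds.

A :class:`DoseGrid` is a 2D scalar dose field with cell-center geometry: the
physical position of cell ``(i, j)`` is ``origin + (i * row_spacing, j *
col_spacing)`` in millimetres, 0-based, row-major.  Grids are either
``absolute`` (dose in Gy) or ``relative`` (percent of the distribution
maximum, so ``max == 100``).  Every comparison engine in this package consumes
a high-resolution *reference* (planned) grid and a coarser *evaluated*
(measured) grid expressed in the same mode.

The on-disk format (``textgrid``) is deliberately minimal: UTF-8, ``#``-prefixed
header lines carrying the geometry, then whitespace-separated rows of dose
values.  An optional DICOM RTDOSE import is provided for single-frame 2D dose
planes when :mod:`pydicom` is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import (
    DegenerateInputError,
    FormatError,
    GeometryError,
    ValidationError,
)

__all__ = [
    "DoseGrid",
    "EvaluationMask",
    "read_dose_grid",
    "write_dose_grid",
    "normalize_to_max",
    "apply_ldt",
    "nearest_reference_indices",
]

#: tolerance for the relative-mode ``max == 100`` invariant and for lattice checks
_TOL = 1e-9

_MODES = ("absolute", "relative")

_HEADER_KEYS = (
    "rows",
    "cols",
    "row_spacing_mm",
    "col_spacing_mm",
    "origin_y_mm",
    "origin_x_mm",
    "mode",
)


@dataclass(frozen=True)
class DoseGrid:
    """A 2D dose distribution with cell-center geometry.

    Parameters
    ----------
    values
        Dose array of shape ``(rows, cols)``; Gy in absolute mode, percent of
        maximum in relative mode.  All entries must be finite and >= 0.
    spacing
        ``(row_mm, col_mm)`` cell pitch, strictly positive.
    origin
        ``(y_mm, x_mm)`` physical position of cell ``(0, 0)``.
    mode
        ``"absolute"`` or ``"relative"``.
    source
        Optional analytic field ``f(y_mm, x_mm) -> dose`` the grid samples.
        Carried by synthetic plans so that rigid shifts can be re-sampled
        exactly rather than interpolated; ignored by comparisons and I/O.
    """

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    mode: str = "absolute"
    source: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = field(
        default=None, compare=False, repr=False
    )

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.size == 0:
            raise ValidationError(f"dose values must be a non-empty 2D array, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValidationError("dose values must all be finite")
        if values.min() < 0:
            raise ValidationError(f"negative dose encountered (min {values.min():g})")
        spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValidationError(f"grid spacing must be strictly positive, got {spacing}")
        origin = (float(self.origin[0]), float(self.origin[1]))
        if self.mode not in _MODES:
            raise ValidationError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.mode == "relative" and abs(values.max() - 100.0) > _TOL:
            raise ValidationError(
                f"relative-mode grid must have max 100, got {values.max():.12g}"
            )
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def row_positions(self) -> np.ndarray:
        """Physical y (mm) of each row of cell centers."""
        return self.origin[0] + np.arange(self.shape[0]) * self.spacing[0]

    @property
    def col_positions(self) -> np.ndarray:
        """Physical x (mm) of each column of cell centers."""
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """``(y_min, y_max, x_min, x_max)`` spanned by cell centers, mm."""
        ry, cx = self.row_positions, self.col_positions
        return (ry[0], ry[-1], cx[0], cx[-1])

    def max(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class EvaluationMask:
    """Boolean inclusion mask over a grid, from a lower dose threshold (LDT).

    ``included[p]`` is False exactly when the reference dose at ``p`` falls
    strictly below ``ldt_percent`` of the reference maximum.  Excluded points
    never enter an agreement index, neither numerator nor denominator.
    """

    included: np.ndarray
    ldt_percent: float

    def __post_init__(self) -> None:
        included = np.asarray(self.included, dtype=bool)
        if included.ndim != 2:
            raise ValidationError("mask must be 2D")
        if not 0.0 <= float(self.ldt_percent) < 100.0:
            raise ValidationError(f"ldt_percent must lie in [0, 100), got {self.ldt_percent}")
        included.setflags(write=False)
        object.__setattr__(self, "included", included)
        object.__setattr__(self, "ldt_percent", float(self.ldt_percent))

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


# ---------------------------------------------------------------------------
# textgrid I/O
# ---------------------------------------------------------------------------

def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    """Serialize *grid* to the textgrid format (full double precision)."""
    path = Path(path)
    lines = [
        "# doseagree textgrid",
        f"# rows {grid.shape[0]}",
        f"# cols {grid.shape[1]}",
        f"# row_spacing_mm {grid.spacing[0]:.17g}",
        f"# col_spacing_mm {grid.spacing[1]:.17g}",
        f"# origin_y_mm {grid.origin[0]:.17g}",
        f"# origin_x_mm {grid.origin[1]:.17g}",
        f"# mode {grid.mode}",
    ]
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in grid.values)
    path.write_text("\n".join(lines) + "\n" + body + "\n", encoding="utf-8")


def _parse_textgrid(path: Path) -> DoseGrid:
    header: dict[str, str] = {}
    data_lines: list[str] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("#").strip().split(None, 1)
            if len(parts) == 2 and parts[0] in _HEADER_KEYS:
                header[parts[0]] = parts[1]
            # other comment lines (e.g. the banner) are ignored
        else:
            data_lines.append((lineno, line))
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise FormatError(f"{path}: missing header line(s): {', '.join('# ' + k for k in missing)}")
    try:
        rows, cols = int(header["rows"]), int(header["cols"])
        spacing = (float(header["row_spacing_mm"]), float(header["col_spacing_mm"]))
        origin = (float(header["origin_y_mm"]), float(header["origin_x_mm"]))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed header value: {exc}") from None
    mode = header["mode"]
    values = np.empty((rows, cols), dtype=float)
    if len(data_lines) != rows:
        raise FormatError(f"{path}: expected {rows} data rows, found {len(data_lines)}")
    for i, (lineno, line) in enumerate(data_lines):
        fields = line.split()
        if len(fields) != cols:
            raise FormatError(f"{path}:{lineno}: expected {cols} values, found {len(fields)}")
        try:
            values[i] = [float(f) for f in fields]
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric dose value") from None
    return DoseGrid(values, spacing, origin, mode)


def _read_rtdose(path: Path) -> DoseGrid:
    """Import a single-frame DICOM RTDOSE plane as an absolute-mode grid."""
    try:
        import pydicom
    except ImportError:  # pragma: no cover - optional dependency
        raise FormatError("rtdose format requires the optional pydicom dependency") from None
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array * float(ds.DoseGridScaling)
    if arr.ndim == 3:
        if arr.shape[0] != 1:
            raise FormatError(f"{path}: multi-frame RTDOSE is not supported (2D planes only)")
        arr = arr[0]
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    return DoseGrid(np.asarray(arr, dtype=float), spacing, (float(ipp[1]), float(ipp[0])), "absolute")


def read_dose_grid(path: str | Path, format_name: str = "textgrid") -> DoseGrid:
    """Read a dose grid from *path*.

    ``format_name`` is ``"textgrid"`` (native) or ``"rtdose"`` (DICOM RTDOSE,
    requires pydicom).  Malformed files raise :class:`FormatError` naming the
    offending line; invariant violations (negative dose, zero spacing) raise
    :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_name == "textgrid":
        return _parse_textgrid(path)
    if format_name == "rtdose":
        return _read_rtdose(path)
    raise ValueError(f"unknown format {format_name!r} (expected 'textgrid' or 'rtdose')")


# ---------------------------------------------------------------------------
# normalization and thresholding
# ---------------------------------------------------------------------------

def normalize_to_max(grid: DoseGrid) -> DoseGrid:
    """Rescale *grid* so its maximum is exactly 100 and mark it relative.

    Normalization at dose maximum is the convention for relative-dose
    comparisons; the operation is idempotent and preserves shape, spacing and
    the ordering of values.
    """
    peak = grid.max()
    if peak <= 0.0:
        raise DegenerateInputError("cannot normalize an all-zero dose grid")
    values = grid.values * (100.0 / peak)
    # guard against round-off pushing the max off 100 exactly
    values[np.unravel_index(np.argmax(values), values.shape)] = 100.0
    src = grid.source
    scaled = None if src is None else (lambda y, x, _f=src, _s=100.0 / peak: _f(y, x) * _s)
    return DoseGrid(values, grid.spacing, grid.origin, "relative", source=scaled)


def apply_ldt(
    reference: DoseGrid,
    ldt_percent: float,
    on: DoseGrid | None = None,
) -> EvaluationMask:
    """Build the lower-dose-threshold mask from the *reference* distribution.

    Points whose reference dose is strictly below ``ldt_percent`` of the
    reference maximum are excluded.  With ``on=None`` the mask lies on the
    reference lattice; passing the evaluated grid as ``on`` produces a mask on
    that (typically coarser) lattice, thresholding on the reference dose at
    the nearest reference cell.  Thresholding always uses the planned
    distribution so that the mask is independent of measurement noise.
    """
    if not 0.0 <= ldt_percent < 100.0:
        raise ValidationError(f"ldt_percent must lie in [0, 100), got {ldt_percent}")
    cutoff = ldt_percent / 100.0 * reference.max()
    if on is None:
        ref_at_points = reference.values
    else:
        ii, jj = nearest_reference_indices(reference, on)
        ref_at_points = reference.values[ii, jj]
    return EvaluationMask(ref_at_points >= cutoff, ldt_percent)


def nearest_reference_indices(
    reference: DoseGrid, evaluated: DoseGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the reference cell nearest each evaluated cell.

    Ties (an evaluated point equidistant between two reference centers) break
    toward the lower index.  Raises :class:`GeometryError` if any evaluated
    point falls outside the reference extent.
    """
    y0, y1, x0, x1 = reference.extent
    ey, ex = evaluated.row_positions, evaluated.col_positions
    if ey[0] < y0 - _TOL or ey[-1] > y1 + _TOL or ex[0] < x0 - _TOL or ex[-1] > x1 + _TOL:
        raise GeometryError(
            "evaluated grid extends outside the reference extent "
            f"(evaluated y [{ey[0]:g}, {ey[-1]:g}] x [{ex[0]:g}, {ex[-1]:g}] vs "
            f"reference y [{y0:g}, {y1:g}] x [{x0:g}, {x1:g}])"
        )
    ti = (ey - reference.origin[0]) / reference.spacing[0]
    tj = (ex - reference.origin[1]) / reference.spacing[1]
    i = np.clip(np.ceil(ti - 0.5).astype(int), 0, reference.shape[0] - 1)
    j = np.clip(np.ceil(tj - 0.5).astype(int), 0, reference.shape[1] - 1)
    return np.meshgrid(i, j, indexing="ij")
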
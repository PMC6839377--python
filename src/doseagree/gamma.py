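"""Gamma-index comparison of an evaluated dose grid against a reference grid.

For each evaluated (measured) point ``e`` at position ``r_e`` with dose
``D_e``, the gamma value is the minimum over reference points ``r`` of

    gamma(e) = min_r sqrt( |r - r_e|^2 / DTA^2  +  delta(e, r)^2 / dD^2 )

where ``delta(e, r) = 100 (D_e - D_ref(r)) / N`` is the percent dose
difference, normalized either globally (``N`` = maximum of the reference
distribution) or locally (``N = D_ref(r)``, with zero-dose reference points
skipped).  A point passes when gamma <= 1; the agreement index (gamma pass
rate, %GP) is the percentage of included points that pass.

The search is exact: it starts from a window of radius ``3 * DTA`` around the
evaluated point and doubles the radius until the spatial term alone at the
window boundary exceeds the best gamma found, at which point no point outside
the window can improve the minimum.  The brute-force search over every
reference point is retained (``exhaustive=True``) as an oracle.  Neither grid
is interpolated: the comparison samples the discrete reference lattice, which
bounds the discretization error by half the (fine) reference spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .errors import DegenerateInputError, GeometryError, ValidationError
from .grids import DoseGrid, EvaluationMask, apply_ldt

__all__ = ["CriteriaPair", "ComparisonResult", "gamma_map", "pass_rate"]


@dataclass(frozen=True)
class CriteriaPair:
    """Dose-difference / distance-to-agreement acceptance criteria.

    ``delta_d`` is the dose criterion in percent, ``dta`` the distance
    criterion in mm, both strictly positive.  ``normalization`` selects the
    percent-difference denominator: the reference maximum (``"global"``) or
    the local reference dose (``"local"``).
    """

    delta_d: float
    dta: float
    normalization: str = "global"

    def __post_init__(self) -> None:
        if self.delta_d <= 0 or self.dta <= 0:
            raise ValidationError(
                f"criteria must be strictly positive, got {self.delta_d}%/{self.dta}mm"
            )
        if self.normalization not in ("global", "local"):
            raise ValidationError(f"normalization must be 'global' or 'local', got {self.normalization!r}")

    def label(self) -> str:
        return f"{self.delta_d:g}%/{self.dta:g}mm ({self.normalization})"


@dataclass(frozen=True)
class ComparisonResult:
    """Per-point index map plus the derived agreement index.

    ``index_map`` is aligned to the evaluated grid and holds the per-point
    index (gamma, or |NDD| for the MADD technique); excluded points are NaN.
    ``agreement_index`` is the percentage of included points with index <= 1.
    """

    index_map: np.ndarray
    mask: EvaluationMask
    agreement_index: float
    technique: str
    criteria: object

    @classmethod
    def from_index_map(
        cls,
        index_map: np.ndarray,
        mask: EvaluationMask,
        technique: str,
        criteria: object,
    ) -> "ComparisonResult":
        return cls(index_map, mask, _pass_percentage(index_map, mask), technique, criteria)


def _pass_percentage(index_map: np.ndarray, mask: EvaluationMask) -> float:
    included = mask.included
    n = int(included.sum())
    if n == 0:
        raise DegenerateInputError("no points above the lower dose threshold")
    passed = int(np.sum(index_map[included] <= 1.0))
    return 100.0 * passed / n


def pass_rate(result: ComparisonResult) -> float:
    """Agreement index (%GP) of *result*: percent of included points with index <= 1."""
    return _pass_percentage(result.index_map, result.mask)


def _check_alignment(reference: DoseGrid, evaluated: DoseGrid) -> None:
    if reference.mode != evaluated.mode:
        raise ValidationError(
            f"cannot compare {reference.mode} reference with {evaluated.mode} evaluated grid"
        )
    ry0, ry1, rx0, rx1 = reference.extent
    ey, ex = evaluated.row_positions, evaluated.col_positions
    tol = 1e-9
    if ey[0] < ry0 - tol or ey[-1] > ry1 + tol or ex[0] < rx0 - tol or ex[-1] > rx1 + tol:
        raise GeometryError("evaluated points lie outside the reference extent")


def gamma_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: CriteriaPair,
    mask: EvaluationMask | None = None,
    *,
    ldt_percent: float | None = None,
    exhaustive: bool = False,
) -> ComparisonResult:
    """Compute the gamma map of *evaluated* against *reference*.

    Parameters
    ----------
    reference, evaluated
        Planned (fine) and measured (coarse) grids in the same dose mode.
        Evaluated cell centers must lie inside the reference extent.
    criteria
        Dose/distance criteria and normalization mode.
    mask
        Inclusion mask on the evaluated lattice.  If omitted, built from
        ``ldt_percent`` (default 0: all points included).
    exhaustive
        Search every reference point instead of the expanding window; the two
        agree exactly and the flag exists as a self-check oracle.

    Under local normalization, reference candidates with zero dose are
    skipped; an evaluated point for which every candidate is skipped gets
    gamma = +inf (it fails).
    """
    _check_alignment(reference, evaluated)
    if mask is None:
        mask = apply_ldt(reference, ldt_percent or 0.0, on=evaluated)
    if mask.included.shape != evaluated.shape:
        raise ValidationError(
            f"mask shape {mask.included.shape} does not match evaluated grid {evaluated.shape}"
        )
    if mask.n_included == 0:
        raise DegenerateInputError("evaluation mask excludes every point")

    ref = reference.values
    ref_y = reference.row_positions
    ref_x = reference.col_positions
    n_global = reference.max()
    local = criteria.normalization == "local"
    dta = criteria.dta
    dd = criteria.delta_d
    dy_mm, dx_mm = reference.spacing

    ev_y = evaluated.row_positions
    ev_x = evaluated.col_positions
    nrows, ncols = reference.shape

    index_map = np.full(evaluated.shape, np.nan)
    ii, jj = np.nonzero(mask.included)
    for i, j in zip(ii, jj):
        ye, xe = ev_y[i], ev_x[j]
        de = evaluated.values[i, j]
        if exhaustive:
            index_map[i, j] = _gamma_window(
                ref, ref_y, ref_x, 0, nrows, 0, ncols, ye, xe, de, dta, dd, local, n_global
            )
            continue
        radius = 3.0 * dta
        while True:
            i0 = max(0, int(np.ceil((ye - radius - reference.origin[0]) / dy_mm)))
            i1 = min(nrows, int(np.floor((ye + radius - reference.origin[0]) / dy_mm)) + 1)
            j0 = max(0, int(np.ceil((xe - radius - reference.origin[1]) / dx_mm)))
            j1 = min(ncols, int(np.floor((xe + radius - reference.origin[1]) / dx_mm)) + 1)
            full = i0 == 0 and j0 == 0 and i1 == nrows and j1 == ncols
            best = _gamma_window(
                ref, ref_y, ref_x, i0, i1, j0, j1, ye, xe, de, dta, dd, local, n_global
            )
            # any reference point outside the window is farther than `radius`
            # in at least one axis, so its gamma exceeds radius/DTA
            if full or best <= radius / dta:
                index_map[i, j] = best
                break
            radius *= 2.0

    return ComparisonResult.from_index_map(index_map, mask, f"gamma_{criteria.normalization}", criteria)


def _gamma_window(
    ref: np.ndarray,
    ref_y: np.ndarray,
    ref_x: np.ndarray,
    i0: int,
    i1: int,
    j0: int,
    j1: int,
    ye: float,
    xe: float,
    de: float,
    dta: float,
    dd: float,
    local: bool,
    n_global: float,
) -> float:
    """Minimum gamma over the reference sub-window [i0:i1, j0:j1]."""
    if i0 >= i1 or j0 >= j1:
        return np.inf
    sub = ref[i0:i1, j0:j1]
    dy = (ref_y[i0:i1] - ye) / dta
    dx = (ref_x[j0:j1] - xe) / dta
    dist2 = dy[:, None] ** 2 + dx[None, :] ** 2
    if local:
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 100.0 * (de - sub) / sub
        g2 = dist2 + (delta / dd) ** 2
        g2 = np.where(sub > 0.0, g2, np.inf)
    else:
        delta = 100.0 * (de - sub) / n_global
        g2 = dist2 + (delta / dd) ** 2
    best = g2.min()
    return float(np.sqrt(best)) if np.isfinite(best) else np.inf
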
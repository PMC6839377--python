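"""Maximum allowed dose difference (MADD) comparison.

MADD converts the distance-to-agreement criterion into a dose tolerance by
multiplying the local dose-gradient magnitude ``g`` (percent of the reference
maximum per mm) by DTA, then combines it with the dose criterion ``dD``:

    MADD_b     = dD + g * DTA            (box)
    MADD_gamma = sqrt(dD^2 + (g*DTA)^2)  (quadrature)

The measured-minus-planned dose difference, in percent of the reference
maximum, normalized by the local MADD gives the normalized dose difference
(NDD); |NDD| <= 1 passes.  The test is pointwise — no spatial search — which
makes it insensitive to the dose-grid resolution.  Since a + b >= sqrt(a^2 +
b^2) for a, b >= 0, the box tolerance is never smaller than the quadrature
one, so the box agreement index is never lower.

Dose differences and tolerances are expressed in percent of the reference
maximum throughout (global-style units); the gradient is evaluated on the
fine reference grid at the reference point nearest each measured point,
because the coarse measured lattice undersamples penumbra gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .gamma import ComparisonResult, CriteriaPair, _check_alignment
from .grids import DoseGrid, EvaluationMask, apply_ldt, nearest_reference_indices

__all__ = ["GradientMap", "MADDMap", "dose_gradient", "madd_map", "ndd_map", "madd_compare"]

_MADD_MODES = ("box", "gamma")


@dataclass(frozen=True)
class GradientMap:
    """Reference dose-gradient magnitude, percent of reference maximum per mm."""

    magnitude: np.ndarray

    def __post_init__(self) -> None:
        mag = np.asarray(self.magnitude, dtype=float)
        if not np.all(np.isfinite(mag)) or mag.min() < 0:
            raise ValidationError("gradient magnitude must be finite and non-negative")
        mag.setflags(write=False)
        object.__setattr__(self, "magnitude", mag)


@dataclass(frozen=True)
class MADDMap:
    """Per-point maximum allowed dose difference (percent), on the evaluated lattice."""

    allowed: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in _MADD_MODES:
            raise ValidationError(f"MADD mode must be one of {_MADD_MODES}, got {self.mode!r}")


def dose_gradient(reference: DoseGrid) -> GradientMap:
    """Gradient magnitude of the reference dose, in % of reference max per mm.

    Central finite differences in the interior, one-sided at the borders
    (``numpy.gradient`` semantics), combined as the Euclidean norm of the two
    directional derivatives.
    """
    if reference.shape[0] < 2 or reference.shape[1] < 2:
        raise DegenerateInputError("gradient requires at least 2 rows and 2 columns")
    peak = reference.max()
    if peak <= 0:
        raise DegenerateInputError("gradient undefined on an all-zero grid")
    gy, gx = np.gradient(reference.values, reference.spacing[0], reference.spacing[1])
    return GradientMap(np.hypot(gy, gx) * (100.0 / peak))


def madd_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: CriteriaPair,
    mode: str = "box",
) -> MADDMap:
    """Maximum allowed dose difference at each evaluated point.

    The gradient is sampled at the reference cell nearest each evaluated cell
    (ties toward the lower index).  ``mode="box"`` sums the two tolerances,
    ``mode="gamma"`` combines them in quadrature; in both cases the result is
    at least ``delta_d`` everywhere.
    """
    if mode not in _MADD_MODES:
        raise ValidationError(f"MADD mode must be one of {_MADD_MODES}, got {mode!r}")
    grad = dose_gradient(reference)
    ii, jj = nearest_reference_indices(reference, evaluated)
    g = grad.magnitude[ii, jj]
    dta_equiv = g * criteria.dta
    if mode == "box":
        allowed = criteria.delta_d + dta_equiv
    else:
        allowed = np.sqrt(criteria.delta_d**2 + dta_equiv**2)
    return MADDMap(allowed, mode)


def ndd_map(
    reference: DoseGrid,
    evaluated: DoseGrid,
    madd: MADDMap,
    mask: EvaluationMask | None = None,
    *,
    criteria: CriteriaPair | None = None,
) -> ComparisonResult:
    """Normalized dose difference |NDD| per point and its agreement index.

    ``|NDD|(e) = |100 (D_e - D_ref(nearest)) / N| / MADD(e)`` with ``N`` the
    reference maximum; values <= 1 agree.
    """
    _check_alignment(reference, evaluated)
    if mask is None:
        mask = apply_ldt(reference, 0.0, on=evaluated)
    if mask.included.shape != evaluated.shape:
        raise ValidationError("mask shape does not match evaluated grid")
    if madd.allowed.shape != evaluated.shape:
        raise ValidationError("MADD map shape does not match evaluated grid")
    ii, jj = nearest_reference_indices(reference, evaluated)
    diff_pct = 100.0 * (evaluated.values - reference.values[ii, jj]) / reference.max()
    index = np.abs(diff_pct) / madd.allowed
    index = np.where(mask.included, index, np.nan)
    return ComparisonResult.from_index_map(index, mask, f"madd_{madd.mode}", criteria)


def madd_compare(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: CriteriaPair,
    mode: str = "box",
    mask: EvaluationMask | None = None,
) -> ComparisonResult:
    """Convenience wrapper: MADD map + NDD in one call."""
    madd = madd_map(reference, evaluated, criteria, mode)
    return ndd_map(reference, evaluated, madd, mask, criteria=criteria)
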
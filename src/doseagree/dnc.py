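"""Divide-and-conquer (D&C) regional gamma evaluation.

The reference distribution is segmented into four isodose regions — high dose
(HD, >= 90% of maximum), high gradient (HG, 50-90%), medium dose (MD,
20-50%) and low dose (LD, 10-20%); points below 10% are excluded — and gamma
analysis is run separately in each region with a region-specific dose
criterion and a shared DTA.  Region membership is frozen from the planned
(reference) dose before any comparison, so a point's region never depends on
the measurement.  Boundaries are lower-inclusive, upper-exclusive.

The per-region dose criteria are tabulated against the base gamma criterion
``dD_gamma``; they were designed so that the local (per-region) percent
difference corresponds to approximately the same difference expressed in
percent of the maximum dose.  E.g. for the 5% row, a 7% difference in the HG
region, centered around the 70% isodose, is 0.70 * 0.07 = 0.049 of the
maximum dose — within rounding of the 5% HD criterion.

By default the regional gamma runs with local normalization, matching that
design rationale; global normalization is available for sensitivity checks.
The overall agreement index pools pass counts across regions (count-weighted),
so it equals the plain gamma pass rate when all four region criteria coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnsupportedCriteriaError, ValidationError
from .gamma import ComparisonResult, CriteriaPair, gamma_map
from .grids import DoseGrid, EvaluationMask, nearest_reference_indices

__all__ = [
    "REGIONS",
    "REGION_BOUNDS",
    "DNC_CRITERIA_TABLE",
    "RegionCriteria",
    "RegionMask",
    "DnCResult",
    "dnc_criteria",
    "hg_criterion_as_max_fraction",
    "segment_regions",
    "dnc_evaluate",
]

REGIONS = ("HD", "HG", "MD", "LD")

#: region -> [lower, upper) bounds in percent of the reference maximum
REGION_BOUNDS = {"HD": (90.0, np.inf), "HG": (50.0, 90.0), "MD": (20.0, 50.0), "LD": (10.0, 20.0)}

#: base gamma dose criterion (%) -> (HD, HG, MD, LD) dose criteria (%)
DNC_CRITERIA_TABLE = {
    1.0: (1.0, 1.5, 3.0, 6.0),
    2.0: (2.0, 3.0, 5.0, 8.0),
    3.0: (3.0, 4.0, 5.0, 10.0),
    5.0: (5.0, 7.0, 10.0, 15.0),
}


@dataclass(frozen=True)
class RegionCriteria:
    """Per-region dose criteria (%) plus the shared DTA (mm)."""

    delta_d_gamma: float
    delta_d_hd: float
    delta_d_hg: float
    delta_d_md: float
    delta_d_ld: float
    dta: float

    def __post_init__(self) -> None:
        if not (0 < self.delta_d_hd <= self.delta_d_hg <= self.delta_d_md <= self.delta_d_ld):
            raise ValidationError(
                "region criteria must satisfy 0 < HD <= HG <= MD <= LD, got "
                f"({self.delta_d_hd}, {self.delta_d_hg}, {self.delta_d_md}, {self.delta_d_ld})"
            )
        if self.dta <= 0:
            raise ValidationError(f"DTA must be strictly positive, got {self.dta}")

    def for_region(self, region: str) -> float:
        return {
            "HD": self.delta_d_hd,
            "HG": self.delta_d_hg,
            "MD": self.delta_d_md,
            "LD": self.delta_d_ld,
        }[region]


def dnc_criteria(delta_d_gamma: float, dta: float = 3.0) -> RegionCriteria:
    """Tabulated region criteria for base dose criterion ``delta_d_gamma``.

    Only the tabulated rows (1, 2, 3, 5%) exist; there is no interpolation
    between rows, and other values raise :class:`UnsupportedCriteriaError`.
    """
    key = float(delta_d_gamma)
    if key not in DNC_CRITERIA_TABLE:
        raise UnsupportedCriteriaError(
            f"no tabulated D&C criteria for dD={delta_d_gamma}%; "
            f"supported rows: {sorted(DNC_CRITERIA_TABLE)}"
        )
    return RegionCriteria(key, *DNC_CRITERIA_TABLE[key], dta=float(dta))


def hg_criterion_as_max_fraction(criteria: RegionCriteria, isodose_fraction: float = 0.70) -> float:
    """The HG-region dose criterion converted to a fraction of the maximum dose.

    The HG region is centered around the 70% isodose, so a local difference of
    ``delta_d_hg`` percent corresponds to ``0.70 * delta_d_hg / 100`` of the
    maximum dose — e.g. 0.70 * 0.07 = 0.049 for the 5% row, within rounding of
    that row's 5% HD criterion.
    """
    return isodose_fraction * criteria.delta_d_hg / 100.0


@dataclass(frozen=True)
class RegionMask:
    """Region label per evaluated point.

    ``labels`` holds one of ``"HD"``, ``"HG"``, ``"MD"``, ``"LD"`` or
    ``"excluded"`` per cell; the labels partition the evaluated lattice.
    """

    labels: np.ndarray

    def region(self, name: str) -> np.ndarray:
        return self.labels == name

    def counts(self) -> dict[str, int]:
        return {r: int((self.labels == r).sum()) for r in REGIONS}


def segment_regions(reference: DoseGrid, evaluated: DoseGrid) -> RegionMask:
    """Assign each evaluated point to an isodose region of the reference.

    The reference dose at the nearest reference cell, in percent of the
    reference maximum, selects the region; bounds are lower-inclusive.
    """
    ii, jj = nearest_reference_indices(reference, evaluated)
    pct = 100.0 * reference.values[ii, jj] / reference.max()
    labels = np.full(evaluated.shape, "excluded", dtype=object)
    for region, (lo, hi) in REGION_BOUNDS.items():
        labels[(pct >= lo) & (pct < hi)] = region
    return RegionMask(labels)


@dataclass(frozen=True)
class DnCResult:
    """Per-region and pooled agreement of a D&C evaluation.

    ``per_region`` maps region name to ``(pass_percent, n_points)``; empty
    regions carry ``(None, 0)``.  ``overall`` pools pass counts over the four
    regions, so the pooled numerator/denominator equal the sums of the
    per-region ones.
    """

    per_region: dict[str, tuple[float | None, int]]
    overall: float
    index_map: np.ndarray
    regions: RegionMask
    criteria: RegionCriteria
    normalization: str

    @property
    def empty_regions(self) -> list[str]:
        return [r for r, (gp, n) in self.per_region.items() if n == 0]


def dnc_evaluate(
    reference: DoseGrid,
    evaluated: DoseGrid,
    criteria: RegionCriteria,
    normalization: str = "local",
    *,
    region_mask: RegionMask | None = None,
) -> DnCResult:
    """Run region-wise gamma evaluation and pool the pass counts.

    Each region is evaluated with the shared DTA and its own dose criterion;
    ``normalization`` applies to every region (local by default).  An empty
    region is reported with count 0 and an undefined pass rate rather than an
    error.
    """
    if region_mask is None:
        region_mask = segment_regions(reference, evaluated)
    index_map = np.full(evaluated.shape, np.nan)
    per_region: dict[str, tuple[float | None, int]] = {}
    passed_total = 0
    count_total = 0
    for region in REGIONS:
        included = region_mask.region(region)
        n = int(included.sum())
        if n == 0:
            per_region[region] = (None, 0)
            continue
        pair = CriteriaPair(criteria.for_region(region), criteria.dta, normalization)
        sub = gamma_map(
            reference,
            evaluated,
            pair,
            EvaluationMask(included, ldt_percent=10.0),
        )
        index_map[included] = sub.index_map[included]
        n_pass = int(np.sum(sub.index_map[included] <= 1.0))
        per_region[region] = (100.0 * n_pass / n, n)
        passed_total += n_pass
        count_total += n
    overall = 100.0 * passed_total / count_total if count_total else float("nan")
    return DnCResult(per_region, overall, index_map, region_mask, criteria, normalization)
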
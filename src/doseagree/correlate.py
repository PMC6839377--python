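"""Cohort-wide agreement tables and cross-technique correlation analysis.

Every plan in a cohort is evaluated under each requested (technique,
criteria, lower-dose-threshold) combination, producing an agreement table
(plans x combinations of %GP values) with a mean +/- SD summary.  Pairwise
similarity of behavior between combinations is then quantified by ordinary
least squares regression: the coefficient of determination R^2 (equal to the
squared Pearson correlation for simple regression, hence symmetric in the
pair), the two-sided p-value of the slope's t test, and a Sidak-corrected
significance flag.  R^2 >= 0.64 (= 0.8^2, a Pearson correlation of at least
0.8) marks a pair as behaving alike; with m comparisons in a family, the
Sidak-corrected per-comparison level is 1 - (1 - alpha)^(1/m).

Plans whose index is undefined for a combination (e.g. an empty isodose
region) are dropped pairwise and counted, never imputed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dnc import dnc_criteria, dnc_evaluate, segment_regions
from .errors import DegenerateInputError, UnsupportedCriteriaError, ValidationError
from .gamma import CriteriaPair, gamma_map
from .grids import DoseGrid, apply_ldt, read_dose_grid
from .madd import madd_compare
from .synth import CohortManifest

__all__ = [
    "TECHNIQUES",
    "DEFAULT_CRITERIA",
    "DEFAULT_LDTS",
    "AgreementTable",
    "CorrelationReport",
    "plan_indices",
    "batch_indices",
    "ols_r2",
    "sidak_correct",
    "correlation_matrix",
]

logger = logging.getLogger("doseagree")

#: the five technique variants compared throughout
TECHNIQUES = ("gamma_global", "gamma_local", "dnc", "madd_b", "madd_gamma")

#: (dose %, distance mm) criteria pairs of the standard sweep
DEFAULT_CRITERIA: tuple[tuple[float, float], ...] = (
    (1.0, 1.0),
    (2.0, 2.0),
    (2.0, 3.0),
    (3.0, 2.0),
    (3.0, 3.0),
    (5.0, 3.0),
)

#: lower dose thresholds (percent of reference maximum) of the standard sweep
DEFAULT_LDTS: tuple[float, ...] = (5.0, 10.0)

#: the divide-and-conquer region definitions exclude doses below 10% of
#: maximum, so D&C columns exist only at this threshold
_DNC_LDT = 10.0


@dataclass
class AgreementTable:
    """Plans x (technique, criteria, LDT) matrix of agreement indices (%).

    ``data`` has one row per plan and a MultiIndex column
    ``(technique, dd, dta, ldt)``; undefined cells are NaN and counted in
    ``n_missing``.  ``labels`` carries the per-plan clean/errored label.
    """

    data: pd.DataFrame
    labels: pd.Series
    n_missing: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD of each combination over the cohort."""
        return pd.DataFrame({"mean": self.data.mean(), "sd": self.data.std(ddof=1)})

    def column(self, technique: str, dd: float, dta: float, ldt: float) -> pd.Series:
        return self.data[(technique, float(dd), float(dta), float(ldt))]


def plan_indices(
    reference: DoseGrid,
    evaluated: DoseGrid,
    techniques: Sequence[str] = TECHNIQUES,
    criteria_list: Sequence[tuple[float, float]] = DEFAULT_CRITERIA,
    ldt_list: Sequence[float] = DEFAULT_LDTS,
    *,
    dnc_normalization: str = "local",
) -> dict[tuple[str, float, float, float], float]:
    """Agreement index of one plan under every requested combination.

    Returns a mapping ``(technique, dd, dta, ldt) -> %GP``; combinations that
    are undefined (D&C at thresholds other than 10%, or a base dose criterion
    without a tabulated D&C row) map to NaN.
    """
    out: dict[tuple[str, float, float, float], float] = {}
    masks = {ldt: apply_ldt(reference, ldt, on=evaluated) for ldt in ldt_list}
    regions = segment_regions(reference, evaluated) if "dnc" in techniques else None
    for dd, dta in criteria_list:
        for ldt in ldt_list:
            mask = masks[ldt]
            for tech in techniques:
                key = (tech, float(dd), float(dta), float(ldt))
                if tech in ("gamma_global", "gamma_local"):
                    pair = CriteriaPair(dd, dta, tech.removeprefix("gamma_"))
                    out[key] = gamma_map(reference, evaluated, pair, mask).agreement_index
                elif tech in ("madd_b", "madd_gamma"):
                    mode = "box" if tech == "madd_b" else "gamma"
                    pair = CriteriaPair(dd, dta, "global")
                    out[key] = madd_compare(reference, evaluated, pair, mode, mask).agreement_index
                elif tech == "dnc":
                    if ldt != _DNC_LDT:
                        out[key] = float("nan")
                        continue
                    try:
                        crit = dnc_criteria(dd, dta)
                    except UnsupportedCriteriaError:
                        out[key] = float("nan")
                        continue
                    res = dnc_evaluate(
                        reference, evaluated, crit, dnc_normalization, region_mask=regions
                    )
                    out[key] = res.overall
                else:
                    raise ValidationError(f"unknown technique {tech!r}")
    return out


def batch_indices(
    manifest: CohortManifest | Sequence[tuple[str, DoseGrid, DoseGrid, str]],
    techniques: Sequence[str] = TECHNIQUES,
    criteria_list: Sequence[tuple[float, float]] = DEFAULT_CRITERIA,
    ldt_list: Sequence[float] = DEFAULT_LDTS,
    *,
    dnc_normalization: str = "local",
) -> AgreementTable:
    """Evaluate a whole cohort; one agreement-table cell per plan x combination.

    Accepts either a :class:`CohortManifest` (grids are read from its file
    paths) or an in-memory list of ``(plan_id, reference, measured, label)``.
    A plan whose files cannot be read is recorded as a failure and skipped;
    the run continues.
    """
    if isinstance(manifest, CohortManifest):
        loader = (
            (
                r.plan_id,
                lambda r=r: (read_dose_grid(r.ref_path), read_dose_grid(r.meas_path)),
                r.label,
            )
            for r in manifest.records
        )
    else:
        loader = ((pid, lambda ref=ref, meas=meas: (ref, meas), lab) for pid, ref, meas, lab in manifest)
    rows: dict[str, dict] = {}
    labels: dict[str, str] = {}
    failures = 0
    for plan_id, load, label in loader:
        try:
            ref, meas = load()
            rows[plan_id] = plan_indices(
                ref, meas, techniques, criteria_list, ldt_list, dnc_normalization=dnc_normalization
            )
            labels[plan_id] = label
        except (OSError, DegenerateInputError) as exc:
            failures += 1
            logger.warning("plan %s failed: %s", plan_id, exc)
    if not rows:
        raise DegenerateInputError("no plan in the cohort could be evaluated")
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = pd.MultiIndex.from_tuples(data.columns, names=["technique", "dd", "dta", "ldt"])
    n_missing = int(data.isna().sum().sum()) + failures
    return AgreementTable(data, pd.Series(labels), n_missing)


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def ols_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple OLS regression of *y* on *x*: ``(R^2, p)``.

    R^2 = 1 - SS_res/SS_tot; the p-value is the two-sided t test on the
    slope.  A constant *x* leaves the regression undefined and raises
    :class:`DegenerateInputError`; a constant *y* returns R^2 = 0 with p = 1
    by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D vectors of equal length")
    if x.size < 3:
        raise DegenerateInputError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateInputError("regression undefined for constant x")
    if np.ptp(y) == 0:
        return 0.0, 1.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.pvalue)


def sidak_correct(alpha: float, m: int) -> float:
    """Sidak-corrected per-comparison significance level for *m* comparisons."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


@dataclass
class CorrelationReport:
    """Pairwise R^2 / significance summary of agreement-table columns.

    ``pairs`` has one row per column pair with R^2, p, n (pairwise-complete
    plans), the correlation flag (R^2 >= ``r2_threshold``) and the
    Sidak-corrected significance flag.  ``m`` is the family size used for
    the correction.
    """

    pairs: pd.DataFrame
    m: int
    alpha: float
    corrected_alpha: float
    r2_threshold: float
    n_dropped: int = 0

    def r2_matrix(self) -> pd.DataFrame:
        """Square symmetric matrix of R^2 values (NaN off the evaluated pairs)."""
        cols = sorted({p for pair in self.pairs[["col_x", "col_y"]].itertuples(index=False) for p in pair})
        mat = pd.DataFrame(np.nan, index=cols, columns=cols)
        for row in self.pairs.itertuples(index=False):
            mat.loc[[row.col_x], [row.col_y]] = row.r2
            mat.loc[[row.col_y], [row.col_x]] = row.r2
        return mat


def correlation_matrix(
    table: AgreementTable,
    family: Sequence[tuple] | None = None,
    alpha: float = 0.05,
    r2_threshold: float = 0.64,
) -> CorrelationReport:
    """OLS R^2 and Sidak-corrected significance for each column pair.

    ``family`` is the set of column-key pairs forming one multiple-comparison
    family (default: all unordered pairs of the table's columns); its size is
    the m of the Sidak correction.  R^2 is symmetric in the pair order; the
    regression direction (y on x) follows the pair as given.
    """
    columns = list(table.data.columns)
    if family is None:
        family = list(itertools.combinations(columns, 2))
    m = len(family)
    if m == 0:
        raise DegenerateInputError("empty comparison family")
    level = sidak_correct(alpha, m)
    records = []
    dropped = 0
    for cx, cy in family:
        x = table.data[cx]
        y = table.data[cy]
        ok = x.notna() & y.notna()
        dropped += int((~ok).sum())
        rec = {"col_x": _fmt_col(cx), "col_y": _fmt_col(cy), "n": int(ok.sum())}
        try:
            r2, p = ols_r2(x[ok].to_numpy(), y[ok].to_numpy())
            rec.update(
                r2=r2,
                p_value=p,
                correlated=bool(r2 >= r2_threshold),
                significant_after_sidak=bool(p <= level),
                error="",
            )
        except DegenerateInputError as exc:
            rec.update(r2=np.nan, p_value=np.nan, correlated=False,
                       significant_after_sidak=False, error=str(exc))
        records.append(rec)
    return CorrelationReport(pd.DataFrame(records), m, alpha, level, r2_threshold, dropped)


def _fmt_col(col: tuple) -> str:
    if isinstance(col, tuple) and len(col) == 4:
        tech, dd, dta, ldt = col
        return f"{tech}:{dd:g}%/{dta:g}mm:LDT{ldt:g}"
    return str(col)
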
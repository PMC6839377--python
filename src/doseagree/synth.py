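"""Synthetic planned/measured dose-grid cohorts.

Real patient-specific QA data pairs a treatment-planning-system dose grid
(fine, 1 mm) with a diode-array measurement (coarse, 1 cm).  This module
emulates that structure with fully analytic plans: a rectangular plateau with
error-function penumbra, modulated by Gaussian dose lobes.  Because the plan
is a closed-form field, a rigid spatial shift is an exact re-sampling of the
analytic form — no interpolation artifacts enter the distance-to-agreement
tests.

Delivery errors are injected in a fixed order — rigid shift, multiplicative
scaling, localized Gaussian "blob" perturbations, additive detector noise —
and the measured grid is produced by point-sampling the delivered field at
the detector pitch (no volume averaging or angular response; the cohort
exercises the comparison mathematics, not detector physics).

The default cohort mirrors a clinical QA audit: 100 plans of which 12% carry
deliberate delivery errors.  Errored plans always include a low-dose-region
discrepancy (a blob centered where the planned dose is 5-15% of maximum,
4-9% of maximum in amplitude) — low-dose regions are where large percent
dose differences are most prevalent in measured QA cohorts — plus one
secondary error: a dose-scaling error, a rigid shift, or an in-field blob,
and mild detector noise.  Clean plans are exact (identity error model), so a
clean pair gives gamma = 0 and NDD = 0 under every technique.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.special import erf

from .errors import DegenerateInputError, GeometryError, ValidationError
from .grids import DoseGrid, normalize_to_max, read_dose_grid, write_dose_grid

__all__ = [
    "PlanSpec",
    "ErrorModel",
    "IDENTITY_ERROR_MODEL",
    "PlanRecord",
    "CohortManifest",
    "generate_plan",
    "inject_errors",
    "sample_detector",
    "cohort_pairs",
    "generate_cohort",
    "regenerate_plan_files",
]

#: dose bands (percent of max) that every generated plan must populate,
#: matching the divide-and-conquer region definitions
_REQUIRED_BANDS = ((10.0, 20.0), (20.0, 50.0), (50.0, 90.0), (90.0, 100.0 + 1e-9))


@dataclass(frozen=True)
class PlanSpec:
    """Parameters of an analytic modulated plan.

    The plateau (``base_dose_gy``) spans the extent inset by
    ``field_margin_mm`` with an error-function penumbra of scale
    ``penumbra_mm``; ``n_lobes`` Gaussian lobes with relative amplitude,
    width and center drawn from the stated ranges modulate it.  Defaults give
    a 20 x 20 cm field sampled at 1 mm whose dose sweep populates all four
    isodose bands (10-20, 20-50, 50-90, >= 90% of maximum).
    """

    extent_mm: tuple[float, float] = (200.0, 200.0)
    n_lobes: int = 3
    lobe_amplitude: tuple[float, float] = (0.25, 0.6)
    lobe_width_mm: tuple[float, float] = (14.0, 28.0)
    lobe_margin_mm: float = 60.0
    penumbra_mm: float = 8.0
    field_margin_mm: float = 30.0
    edge_jitter_mm: float = 5.0
    base_dose_gy: float = 2.0
    grid_spacing_mm: float = 1.0
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.extent_mm[0] <= 0 or self.extent_mm[1] <= 0:
            raise ValidationError("plan extent must be positive")
        if self.n_lobes < 1:
            raise ValidationError("a plan needs at least one lobe")
        if self.penumbra_mm <= 0:
            raise ValidationError("penumbra scale must be positive")
        if self.base_dose_gy <= 0 or self.grid_spacing_mm <= 0:
            raise ValidationError("base dose and grid spacing must be positive")


@dataclass(frozen=True)
class ErrorModel:
    """Controlled delivery-error injection.

    ``scale_factor`` multiplies the delivered dose (1.0 = none);
    ``shift_mm = (dy, dx)`` rigidly displaces the field; each blob is
    ``(center_y_mm, center_x_mm, width_mm, amplitude_percent)`` with the
    amplitude in percent of the plan maximum; ``noise_sd_percent`` is the SD
    of zero-mean Gaussian detector noise, again in percent of the plan
    maximum.
    """

    scale_factor: float = 1.0
    shift_mm: tuple[float, float] = (0.0, 0.0)
    blob_errors: tuple[tuple[float, float, float, float], ...] = ()
    noise_sd_percent: float = 0.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be strictly positive")
        if self.noise_sd_percent < 0:
            raise ValidationError("noise_sd_percent must be non-negative")
        object.__setattr__(self, "shift_mm", tuple(float(v) for v in self.shift_mm))
        object.__setattr__(
            self, "blob_errors", tuple(tuple(float(v) for v in b) for b in self.blob_errors)
        )

    @property
    def is_identity(self) -> bool:
        return (
            self.scale_factor == 1.0
            and self.shift_mm == (0.0, 0.0)
            and not self.blob_errors
            and self.noise_sd_percent == 0.0
        )


IDENTITY_ERROR_MODEL = ErrorModel()


# ---------------------------------------------------------------------------
# plan generation
# ---------------------------------------------------------------------------

def _plateau(t: np.ndarray, t0: float, t1: float, s: float) -> np.ndarray:
    return 0.5 * (erf((t - t0) / s) + erf((t1 - t) / s))


def generate_plan(spec: PlanSpec, seed: int) -> DoseGrid:
    """Deterministically generate an analytic plan sampled at the fine pitch.

    The returned grid carries the analytic field in ``source`` so that error
    injection can re-sample shifts exactly.  Raises
    :class:`DegenerateInputError` if the drawn plan fails to populate all
    four isodose bands (possible only for pathological specs).
    """
    rng = np.random.default_rng(seed)
    hy, hx = spec.extent_mm
    m = spec.lobe_margin_mm
    lo_y, hi_y = min(m, hy / 2), max(hy - m, hy / 2)
    lo_x, hi_x = min(m, hx / 2), max(hx - m, hx / 2)
    centers = np.column_stack(
        [rng.uniform(lo_y, hi_y, spec.n_lobes), rng.uniform(lo_x, hi_x, spec.n_lobes)]
    )
    widths = rng.uniform(*spec.lobe_width_mm, spec.n_lobes)
    amps = rng.uniform(*spec.lobe_amplitude, spec.n_lobes)
    # field edges vary plan to plan, as clinical field sizes do; without the
    # jitter every penumbra would sit at the same phase of the detector lattice
    j = spec.edge_jitter_mm
    ey = rng.uniform(-j, j, 4) if j > 0 else np.zeros(4)
    t0y, t1y = spec.field_margin_mm + ey[0], hy - spec.field_margin_mm + ey[1]
    t0x, t1x = spec.field_margin_mm + ey[2], hx - spec.field_margin_mm + ey[3]
    s = spec.penumbra_mm
    base = spec.base_dose_gy

    def field_fn(y: np.ndarray, x: np.ndarray) -> np.ndarray:
        plateau = _plateau(y, t0y, t1y, s) * _plateau(x, t0x, t1x, s)
        mod = np.ones_like(np.asarray(y, dtype=float) * np.asarray(x, dtype=float))
        for (cy, cx), w, a in zip(centers, widths, amps):
            mod = mod + a * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * w**2))
        return base * plateau * mod

    step = spec.grid_spacing_mm
    ys = np.arange(0.0, hy + step / 2, step)
    xs = np.arange(0.0, hx + step / 2, step)
    values = field_fn(ys[:, None], xs[None, :])
    grid = DoseGrid(values, (step, step), (0.0, 0.0), "absolute", source=field_fn)
    pct = 100.0 * grid.values / grid.max()
    for lo, hi in _REQUIRED_BANDS:
        if not np.any((pct >= lo) & (pct < hi)):
            raise DegenerateInputError(
                f"generated plan does not populate the {lo:g}-{hi:g}% dose band; "
                "widen the penumbra or adjust lobe ranges"
            )
    if spec.mode == "relative":
        return normalize_to_max(grid)
    return grid


# ---------------------------------------------------------------------------
# error injection and detector sampling
# ---------------------------------------------------------------------------

def inject_errors(plan: DoseGrid, model: ErrorModel, seed: int) -> DoseGrid:
    """Apply a delivery-error model to *plan* (shift, scale, blobs, noise).

    The shift re-samples the plan's analytic field at displaced coordinates,
    so *plan* must carry ``source`` when ``shift_mm`` is nonzero.  Blob and
    noise amplitudes are percent of the input plan's maximum.  Noise is drawn
    from ``seed``; the returned grid carries the noise-free delivered field
    as its ``source``.  An identity model returns the plan unchanged.
    """
    if model.is_identity:
        return plan
    peak = plan.max()
    dy, dx = model.shift_mm
    scale = model.scale_factor
    blobs = model.blob_errors

    if (dy, dx) != (0.0, 0.0):
        if plan.source is None:
            raise ValidationError(
                "rigid shifts require a plan with an analytic source field "
                "(grids generated by generate_plan carry one)"
            )
        base_fn = plan.source

        def delivered_fn(y, x, _f=base_fn, _dy=dy, _dx=dx, _s=scale):
            return _f(y - _dy, x - _dx) * _s

        ys, xs = plan.row_positions, plan.col_positions
        values = delivered_fn(ys[:, None], xs[None, :])
        # a shift must not drag appreciable dose off the grid: the delivered
        # border dose has to stay negligible relative to the plan maximum
        border = np.concatenate([values[0], values[-1], values[:, 0], values[:, -1]])
        if border.max() > 0.01 * peak:
            raise GeometryError(
                f"shift {model.shift_mm} mm moves the field edge onto the grid border "
                f"(border dose {border.max():.3g} vs maximum {peak:.3g})"
            )
        source = delivered_fn
    else:
        values = plan.values * scale
        src = plan.source
        source = None if src is None else (lambda y, x, _f=src, _s=scale: _f(y, x) * _s)

    if blobs:
        ys, xs = plan.row_positions, plan.col_positions
        yy, xx = ys[:, None], xs[None, :]
        values = values.copy()
        for cy, cx, w, amp in blobs:
            values = values + amp / 100.0 * peak * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * w**2)
            )
        prev = source
        if prev is not None:
            def source(y, x, _f=prev, _blobs=blobs, _peak=peak):  # noqa: F811
                v = _f(y, x)
                for cy, cx, w, amp in _blobs:
                    v = v + amp / 100.0 * _peak * np.exp(
                        -((y - cy) ** 2 + (x - cx) ** 2) / (2.0 * w**2)
                    )
                return v

    if model.noise_sd_percent > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, model.noise_sd_percent / 100.0 * peak, values.shape)

    # dose is physically non-negative; negative excursions from noise or
    # subtractive blobs in near-zero regions are clamped
    values = np.maximum(values, 0.0)
    return DoseGrid(values, plan.spacing, plan.origin, plan.mode, source=source)


def sample_detector(grid: DoseGrid, spacing_mm: float = 10.0) -> DoseGrid:
    """Point-sample *grid* at the detector pitch (no averaging).

    The detector lattice starts at the grid origin and keeps every k-th cell,
    where k = ``spacing_mm`` / grid spacing must be a whole number; sampled
    values equal the source values exactly.
    """
    ratios = []
    for axis in (0, 1):
        r = spacing_mm / grid.spacing[axis]
        k = round(r)
        if k < 1 or abs(r - k) > 1e-9:
            raise ValidationError(
                f"detector spacing {spacing_mm} mm is not an integer multiple of "
                f"grid spacing {grid.spacing[axis]} mm"
            )
        ratios.append(k)
    values = grid.values[:: ratios[0], :: ratios[1]]
    return DoseGrid(values, (spacing_mm, spacing_mm), grid.origin, grid.mode, source=grid.source)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def default_error_sampler(rng: np.random.Generator, plan: DoseGrid) -> ErrorModel:
    """Draw the default delivery-error model for an errored plan.

    Always places two low-dose-region blobs (centers where the planned dose
    is 6-10% of maximum, amplitude 5-10% of maximum, width 8-16 mm) — the
    low-dose periphery is where measured QA cohorts show the largest percent
    dose discrepancies — then adds one secondary error: a 1.5-3.5 mm rigid
    shift per axis (p=0.5) or an in-field blob of 3-6% (p=0.5), plus 0.2-0.5%
    detector noise.  Uniform dose-scaling errors are not drawn here: under
    global normalization a pure scale error concentrates its failures in the
    high-dose region, the opposite of the low-dose-dominated error structure
    this cohort models; scaling cohorts are built explicitly (pass a custom
    ``error_sampler``) when studying sensitivity to calibration errors.
    """
    pct = 100.0 * plan.values / plan.max()
    ys, xs = plan.row_positions, plan.col_positions

    def _pick_center(lo: float, hi: float) -> tuple[float, float]:
        cells = np.argwhere((pct >= lo) & (pct < hi))
        i, j = cells[rng.integers(len(cells))]
        return float(ys[i]), float(xs[j])

    blobs = []
    for _ in range(2):
        cy, cx = _pick_center(6.0, 10.0)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        blobs.append((cy, cx, float(rng.uniform(8.0, 16.0)), sign * float(rng.uniform(5.0, 10.0))))
    scale = 1.0
    shift = (0.0, 0.0)
    kind = rng.random()
    if kind < 0.5:
        shift = (
            (-1.0 if rng.random() < 0.5 else 1.0) * float(rng.uniform(1.5, 3.5)),
            (-1.0 if rng.random() < 0.5 else 1.0) * float(rng.uniform(1.5, 3.5)),
        )
    else:
        by, bx = _pick_center(40.0, 95.0)
        bsign = -1.0 if rng.random() < 0.5 else 1.0
        blobs.append((by, bx, float(rng.uniform(10.0, 20.0)), bsign * float(rng.uniform(3.0, 6.0))))
    return ErrorModel(scale, shift, tuple(blobs), float(rng.uniform(0.2, 0.5)))


@dataclass(frozen=True)
class PlanRecord:
    """One cohort entry: identifiers, seeds, generation parameters, file paths."""

    plan_id: str
    seed: int
    error_seed: int
    label: str  # "clean" | "errored"
    spec: PlanSpec
    error_model: ErrorModel
    ref_path: str = ""
    meas_path: str = ""


@dataclass
class CohortManifest:
    """Cohort description from which every file regenerates bit-identically."""

    n: int
    errored_fraction: float
    seed: int
    mode: str
    detector_spacing_mm: float
    records: list[PlanRecord] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                {
                    "plan_id": r.plan_id,
                    "seed": r.seed,
                    "error_seed": r.error_seed,
                    "label": r.label,
                    "ref_path": r.ref_path,
                    "meas_path": r.meas_path,
                    "plan_spec": json.dumps(asdict(r.spec)),
                    "error_model": json.dumps(asdict(r.error_model)),
                }
            )
        df = pd.DataFrame(rows)
        header = (
            f"# doseagree cohort manifest\n# n {self.n}\n# errored_fraction "
            f"{self.errored_fraction:.17g}\n# seed {self.seed}\n# mode {self.mode}\n"
            f"# detector_spacing_mm {self.detector_spacing_mm:.17g}\n"
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortManifest":
        import pandas as pd

        meta: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                k, _, v = line.lstrip("#").strip().partition(" ")
                meta[k] = v
                body_start = i + 1
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
        records = []
        for row in df.itertuples(index=False):
            spec_d = json.loads(row.plan_spec)
            for key in ("extent_mm", "lobe_amplitude", "lobe_width_mm"):
                spec_d[key] = tuple(spec_d[key])
            model_d = json.loads(row.error_model)
            model_d["shift_mm"] = tuple(model_d["shift_mm"])
            model_d["blob_errors"] = tuple(tuple(b) for b in model_d["blob_errors"])
            records.append(
                PlanRecord(
                    str(row.plan_id),
                    int(row.seed),
                    int(row.error_seed),
                    str(row.label),
                    PlanSpec(**spec_d),
                    ErrorModel(**model_d),
                    str(row.ref_path),
                    str(row.meas_path),
                )
            )
        return cls(
            int(meta["n"]),
            float(meta["errored_fraction"]),
            int(meta["seed"]),
            meta["mode"],
            float(meta["detector_spacing_mm"]),
            records,
        )


def _plan_pair(record: PlanRecord, detector_spacing_mm: float, mode: str) -> tuple[DoseGrid, DoseGrid]:
    """Rebuild the (reference, measured) pair of one cohort record."""
    plan = generate_plan(record.spec, record.seed)
    delivered = inject_errors(plan, record.error_model, record.error_seed)
    measured = sample_detector(delivered, detector_spacing_mm)
    if mode == "relative":
        return normalize_to_max(plan), normalize_to_max(measured)
    return plan, measured


def _build_records(
    n: int,
    errored_fraction: float,
    seed: int,
    spec: PlanSpec,
    error_sampler: Callable[[np.random.Generator, DoseGrid], ErrorModel],
) -> list[PlanRecord]:
    if n < 2:
        raise ValidationError("a cohort needs at least 2 plans")
    if not 0.0 <= errored_fraction <= 1.0:
        raise ValidationError("errored_fraction must lie in [0, 1]")
    master = np.random.default_rng(seed)
    plan_seeds = master.integers(0, 2**31, size=n)
    while len(set(plan_seeds.tolist())) < n:  # pragma: no cover - collisions are ~2^-31
        plan_seeds = master.integers(0, 2**31, size=n)
    error_seeds = master.integers(0, 2**31, size=n)
    n_err = int(np.floor(n * errored_fraction + 0.5))
    errored = set(master.choice(n, size=n_err, replace=False).tolist())
    records = []
    for k in range(n):
        plan_seed = int(plan_seeds[k])
        if k in errored:
            plan = generate_plan(spec, plan_seed)
            model = error_sampler(master, plan)
            label = "errored"
        else:
            model = IDENTITY_ERROR_MODEL
            label = "clean"
        records.append(
            PlanRecord(f"plan{k:04d}", plan_seed, int(error_seeds[k]), label, spec, model)
        )
    return records


def cohort_pairs(
    n: int = 100,
    errored_fraction: float = 0.12,
    seed: int = 0,
    *,
    spec: PlanSpec | None = None,
    mode: str = "absolute",
    detector_spacing_mm: float = 10.0,
    error_sampler: Callable[[np.random.Generator, DoseGrid], ErrorModel] | None = None,
) -> list[tuple[str, DoseGrid, DoseGrid, str]]:
    """In-memory cohort: list of ``(plan_id, reference, measured, label)``.

    Same construction as :func:`generate_cohort` without touching disk.
    """
    spec = spec or PlanSpec()
    records = _build_records(n, errored_fraction, seed, spec, error_sampler or default_error_sampler)
    out = []
    for rec in records:
        ref, meas = _plan_pair(rec, detector_spacing_mm, mode)
        out.append((rec.plan_id, ref, meas, rec.label))
    return out


def generate_cohort(
    n: int,
    errored_fraction: float,
    seed: int,
    out_dir: str | Path,
    *,
    spec: PlanSpec | None = None,
    mode: str = "absolute",
    detector_spacing_mm: float = 10.0,
    error_sampler: Callable[[np.random.Generator, DoseGrid], ErrorModel] | None = None,
) -> CohortManifest:
    """Write a reproducible planned/measured cohort to *out_dir*.

    ``round(n * errored_fraction)`` plans carry non-identity error models.
    The manifest (``manifest.tsv``) records seeds, plan specs and error
    models; regenerating from it reproduces every file bit-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = spec or PlanSpec()
    records = _build_records(n, errored_fraction, seed, spec, error_sampler or default_error_sampler)
    manifest = CohortManifest(n, errored_fraction, seed, mode, detector_spacing_mm)
    for rec in records:
        ref, meas = _plan_pair(rec, detector_spacing_mm, mode)
        ref_path = out_dir / f"{rec.plan_id}_ref.txt"
        meas_path = out_dir / f"{rec.plan_id}_meas.txt"
        write_dose_grid(ref, ref_path)
        write_dose_grid(meas, meas_path)
        manifest.records.append(replace(rec, ref_path=str(ref_path), meas_path=str(meas_path)))
    manifest.to_tsv(out_dir / "manifest.tsv")
    return manifest


def regenerate_plan_files(manifest: CohortManifest, record: PlanRecord) -> None:
    """Rewrite one record's grid files from its seeds and parameters."""
    ref, meas = _plan_pair(record, manifest.detector_spacing_mm, manifest.mode)
    write_dose_grid(ref, record.ref_path)
    write_dose_grid(meas, record.meas_path)
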
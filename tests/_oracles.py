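"""Independent reference computations used as oracles by the test suite.

Kept deliberately separate from the package implementation: the gamma oracle
searches every reference point by explicit broadcasting with no windowing or
early exit, and the regression oracle works from raw sums of squares.
"""

from __future__ import annotations

import numpy as np


def bruteforce_gamma(ref, ev, dd: float, dta: float, norm: str) -> np.ndarray:
    """Gamma map by exhaustive search over every reference point (no cap)."""
    ry, rx = ref.row_positions, ref.col_positions
    n_global = ref.values.max()
    out = np.zeros(ev.shape)
    for i, ye in enumerate(ev.row_positions):
        for j, xe in enumerate(ev.col_positions):
            de = ev.values[i, j]
            dist2 = ((ry[:, None] - ye) ** 2 + (rx[None, :] - xe) ** 2) / dta**2
            if norm == "local":
                with np.errstate(divide="ignore", invalid="ignore"):
                    delta = 100.0 * (de - ref.values) / ref.values
                g2 = np.where(ref.values > 0, dist2 + (delta / dd) ** 2, np.inf)
            else:
                delta = 100.0 * (de - ref.values) / n_global
                g2 = dist2 + (delta / dd) ** 2
            m = g2.min()
            out[i, j] = np.sqrt(m) if np.isfinite(m) else np.inf
    return out


def ols_from_sums(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Simple-regression R^2 and slope p-value from raw sums of squares."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    beta = sxy / sxx
    ss_res = syy - beta * sxy
    r2 = 1.0 - ss_res / syy
    se = np.sqrt(ss_res / (n - 2) / sxx)
    tval = beta / se
    p = 2.0 * t_dist.sf(abs(tval), n - 2)
    return float(r2), float(p)
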
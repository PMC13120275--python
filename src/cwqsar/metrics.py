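"""Statistical quality measures for observed-vs-calculated series.

Beyond the usual R², RMSE, Lin's concordance (CCC), leave-one-out Q² and
the one-descriptor F-ratio, two less common indices drive the TF1 target
function:

* **IIC**, the index of ideality of correlation: Pearson r scaled by the
  ratio of the smaller to the larger one-sided mean absolute residual.  It
  penalizes models whose errors pile up on one side of the line, enforcing
  consistency between correlation and dispersion.

* **CII**, the correlation intensity index: 1 minus the summed "protests",
  where a point's protest is the gain in R² obtained by deleting it.  It
  penalizes correlations propped up (or down) by influential outliers.

Throughout, R² is the squared Pearson correlation of observed and
calculated values, and Pearson r inside CCC uses population (n-denominator)
moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateError, InputError


def _paired(observed, calculated, min_n: int = 2):
    x = np.asarray(observed, dtype=float)
    y = np.asarray(calculated, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("observed and calculated must be 1-D of equal length")
    if x.size < min_n:
        raise InputError(f"need at least {min_n} points, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite value in series")
    return x, y


def pearson_r(observed, calculated) -> float:
    """Pearson correlation coefficient (denominators cancel, so the
    population/sample distinction is immaterial)."""
    x, y = _paired(observed, calculated)
    xc, yc = x - x.mean(), y - y.mean()
    den = float(np.sqrt((xc @ xc) * (yc @ yc)))
    if den <= 0.0:
        raise DegenerateError("zero variance: correlation undefined")
    return float((xc @ yc) / den)


def r2(observed, calculated) -> float:
    """Determination coefficient: squared Pearson correlation."""
    return pearson_r(observed, calculated) ** 2


def rmse(observed, calculated) -> float:
    x, y = _paired(observed, calculated)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def iic(observed, calculated) -> float:
    """Index of ideality of correlation.

    Residuals ``d = observed - calculated`` split into the negative side
    (d < 0) and the non-negative side (d >= 0); IIC = r * min(MAE-, MAE+) /
    max(MAE-, MAE+).  If one side is empty the ratio is 0 (maximal
    one-sided bias) except at the perfect fit, where IIC = r.
    """
    x, y = _paired(observed, calculated)
    r = pearson_r(x, y)
    return r * _mae_ratio(x - y)


def _mae_ratio(delta: np.ndarray) -> float:
    neg = delta[delta < 0]
    pos = delta[delta >= 0]
    mae_neg = float(np.mean(-neg)) if neg.size else 0.0
    mae_pos = float(np.mean(pos)) if pos.size else 0.0
    hi = max(mae_neg, mae_pos)
    if hi == 0.0:
        # both sides empty or all residuals exactly zero: perfect fit
        return 1.0
    return min(mae_neg, mae_pos) / hi


def _loo_r2(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation after deleting each point, vectorized
    via sum downdates.  Undefined deletions (zero variance) yield NaN."""
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    dx, dy = sx - x, sy - y
    num = m * (sxy - x * y) - dx * dy
    den = (m * (sxx - x * x) - dx * dx) * (m * (syy - y * y) - dy * dy)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num * num / den
    out[den <= 0] = np.nan
    return out


def cii(observed, calculated) -> float:
    """Correlation intensity index: ``1 - sum of protests``.

    A point's protest is ``max(0, R_k^2 - R^2)`` where ``R_k^2`` is the
    determination coefficient with point k deleted.  Deletions that leave
    a zero-variance series contribute protest 0 (with a warning): an
    undefined correlation cannot evidence an influential outlier.
    """
    x, y = _paired(observed, calculated, min_n=4)
    full = r2(x, y)
    loo = _loo_r2(x, y)
    if np.isnan(loo).any():
        warnings.warn(
            "zero-variance leave-one-out subset in CII; protest set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        loo = np.nan_to_num(loo, nan=full)
    protests = np.clip(loo - full, 0.0, None)
    return float(1.0 - protests.sum())


def ccc(observed, calculated) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    x, y = _paired(observed, calculated)
    vx, vy = float(np.var(x)), float(np.var(y))
    if vx <= 0.0 or vy <= 0.0:
        raise DegenerateError("zero variance: CCC undefined")
    cov = float(np.mean((x - x.mean()) * (y - y.mean())))
    return 2.0 * cov / (vx + vy + (float(x.mean()) - float(y.mean())) ** 2)


def q2_loo(dcw_values, endpoints) -> float:
    """Leave-one-out cross-validated R² of the one-descriptor regression.

    For each point the intercept/slope are refit on the remaining points
    (correlation weights frozen) and the held-out endpoint is predicted;
    Q² = 1 - PRESS / SS_total.
    """
    x, y = _paired(dcw_values, endpoints, min_n=3)
    n = x.size
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0.0:
        raise DegenerateError("zero endpoint variance: Q2 undefined")
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    m = n - 1
    dx, dy = sx - x, sy - y
    den = m * (sxx - x * x) - dx * dx
    if np.any(den <= 0):
        raise DegenerateError("zero DCW variance in a leave-one-out fold")
    slope = (m * (sxy - x * y) - dx * dy) / den
    intercept = (dy - slope * dx) / m
    press = float(np.sum((y - (intercept + slope * x)) ** 2))
    return 1.0 - press / ss_tot


def f_ratio(r2_value: float, n: int) -> float:
    """Fisher F of the one-descriptor regression: ``r2 (n-2) / (1-r2)``."""
    if not 0.0 <= r2_value <= 1.0:
        raise InputError(f"r2 must lie in [0, 1], got {r2_value}")
    if n < 3:
        raise InputError(f"F-ratio needs n >= 3, got {n}")
    if r2_value >= 1.0:
        raise DegenerateError("r2 = 1: F-ratio diverges")
    return r2_value * (n - 2) / (1.0 - r2_value)


@dataclass
class MetricsReport:
    """One row of per-set statistics (n, R², CCC, IIC, CII, Q², RMSE, F)."""

    n: int
    r2: Optional[float] = None
    ccc: Optional[float] = None
    iic: Optional[float] = None
    cii: Optional[float] = None
    q2: Optional[float] = None
    rmse: Optional[float] = None
    f: Optional[float] = None

    COLUMNS = ("n", "r2", "ccc", "iic", "cii", "q2", "rmse", "f")

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in self.COLUMNS}

    def format_row(self, label: str = "") -> str:
        cells = [label, str(self.n)]
        for c in self.COLUMNS[1:]:
            v = getattr(self, c)
            cells.append("-" if v is None else f"{v:.4f}")
        return "\t".join(cells)


def evaluate_set(observed, calculated, dcw_values=None) -> MetricsReport:
    """Full metrics row for one partition block.

    CII needs n >= 4 and Q² needs the raw descriptor values; unavailable
    entries are left as None (rendered ``-``), matching how validation-set
    rows are conventionally reported.
    """
    x, y = _paired(observed, calculated)
    n = int(x.size)
    report = MetricsReport(n=n, rmse=rmse(x, y))
    try:
        report.r2 = r2(x, y)
        report.ccc = ccc(x, y)
        report.iic = iic(x, y)
    except DegenerateError:
        return report
    if n >= 4:
        report.cii = cii(x, y)
    if dcw_values is not None and n >= 3:
        try:
            report.q2 = q2_loo(dcw_values, x)
        except DegenerateError:
            report.q2 = None
    if report.r2 < 1.0 and n >= 3:
        report.f = f_ratio(report.r2, n)
    return report
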
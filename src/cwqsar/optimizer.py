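"""Monte Carlo optimization of correlation weights.

One *epoch* is a cycle of proposed modifications over all non-blocked
attributes, visited in a seeded random order.  Each visit draws a uniform
step size, evaluates the weight moved by +step and by -step, and accepts
the better direction iff the target function does not decrease:

* ``TF0 = rA + rP - |rA - rP| * 0.1`` rewards high, balanced Pearson
  correlations between endpoint and descriptor on the active and passive
  training blocks.
* ``TF1 = TF0 + (IIC_C + CII_C) * 0.5`` adds the calibration-set index of
  ideality of correlation and correlation intensity index, steering the
  search toward calibration quality rather than training fit.

IIC needs actual residuals, so each TF1 evaluation refits the C0/C1 line
on the active block (closed form) and scores the calibration predictions.
Blocked attributes never enter the weight vector, so their weights are
identically zero at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attributes import Attribute, AttributeDictionary, attribute_occurrences, tokenize_smiles
from .errors import ConfigurationError, DegenerateError, InputError
from .labels import ACTIVE, CALIBRATION, PASSIVE
from .metrics import _loo_r2, _mae_ratio
from .model import CorrelationWeights


def tf0(r_active: float, r_passive: float, penalty: float = 0.1) -> float:
    """Balanced-correlation target: ``rA + rP - |rA - rP| * penalty``."""
    return r_active + r_passive - abs(r_active - r_passive) * penalty


def tf1(tf0_value: float, iic_cal: float, cii_cal: float) -> float:
    """Calibration-aware target: ``TF0 + (IIC + CII) * 0.5``."""
    return tf0_value + (iic_cal + cii_cal) * 0.5


@dataclass
class OptimizerConfig:
    """Monte Carlo run parameters.

    Defaults reproduce the standard regime for this descriptor family:
    rarity threshold T = 3, N = 15 epochs, TF1 target.  ``step_magnitude``
    is the half-width of the uniform proposal step; ``initial_weight`` is
    the common start value of all non-blocked weights, so the zero-epoch
    descriptor is a raw attribute count.
    """

    t: int = 3
    n_epochs: int = 15
    target_function: str = "TF1"
    seed: int = 0
    step_magnitude: float = 0.5
    initial_weight: float = 1.0
    tf0_penalty: float = 0.1

    def __post_init__(self):
        if self.target_function not in ("TF0", "TF1"):
            raise ConfigurationError(
                f"target_function must be TF0 or TF1, got {self.target_function!r}"
            )
        if self.n_epochs < 0 or self.t < 1 or self.step_magnitude <= 0:
            raise ConfigurationError("invalid optimizer configuration")


@dataclass
class AcceptedMove:
    epoch: int
    attribute: Attribute
    old_weight: float
    new_weight: float
    tf: float


@dataclass
class EpochStats:
    epoch: int
    r_active: float
    r_passive: float
    iic_cal: float | None
    cii_cal: float | None
    tf: float


@dataclass
class OptimizationTrace:
    """Accepted moves plus per-epoch summary statistics."""

    moves: list[AcceptedMove] = field(default_factory=list)
    epochs: list[EpochStats] = field(default_factory=list)
    initial_tf: float = float("nan")
    final_tf: float = float("nan")


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    den = np.sqrt((xc @ xc) * (yc @ yc))
    if den <= 0.0:
        return 0.0
    return float((xc @ yc) / den)


def _safe_iic(obs: np.ndarray, calc: np.ndarray) -> float:
    r = _safe_r(obs, calc)
    if r == 0.0:
        return 0.0
    return r * _mae_ratio(obs - calc)


def _safe_cii(obs: np.ndarray, calc: np.ndarray) -> float:
    r = _safe_r(obs, calc)
    if r == 0.0:
        return 0.0
    full = r * r
    loo = _loo_r2(obs, calc)
    loo = np.nan_to_num(loo, nan=full)
    return float(1.0 - np.clip(loo - full, 0.0, None).sum())


def occurrence_matrix(records, attrs: list[Attribute]) -> np.ndarray:
    """Count matrix: rows = compounds, columns = attribute occurrence counts."""
    index = {a: j for j, a in enumerate(attrs)}
    x = np.zeros((len(records), len(attrs)))
    for i, rec in enumerate(records):
        for attr in attribute_occurrences(tokenize_smiles(rec.smiles)):
            j = index.get(attr)
            if j is not None:
                x[i, j] += 1.0
    return x


class _Objective:
    """Target-function evaluator over the three training-type blocks."""

    def __init__(self, x_a, y_a, x_p, y_p, x_c, y_c, config: OptimizerConfig):
        self.x = {ACTIVE: x_a, PASSIVE: x_p, CALIBRATION: x_c}
        self.y = {ACTIVE: y_a, PASSIVE: y_p, CALIBRATION: y_c}
        self.config = config

    def evaluate(self, dcw: dict) -> tuple[float, EpochStats]:
        ra = _safe_r(self.y[ACTIVE], dcw[ACTIVE])
        rp = _safe_r(self.y[PASSIVE], dcw[PASSIVE])
        value = tf0(ra, rp, self.config.tf0_penalty)
        iic_c = cii_c = None
        if self.config.target_function == "TF1":
            iic_c, cii_c = self._calibration_indices(dcw)
            value = tf1(value, iic_c, cii_c)
        return value, EpochStats(-1, ra, rp, iic_c, cii_c, value)

    def _calibration_indices(self, dcw: dict) -> tuple[float, float]:
        xa, ya = dcw[ACTIVE], self.y[ACTIVE]
        xc = xa - xa.mean()
        sxx = float(xc @ xc)
        if sxx <= 0.0:
            return 0.0, 0.0
        c1 = float(xc @ (ya - ya.mean())) / sxx
        c0 = float(ya.mean() - c1 * xa.mean())
        calc = c0 + c1 * dcw[CALIBRATION]
        obs = self.y[CALIBRATION]
        return _safe_iic(obs, calc), _safe_cii(obs, calc)


def optimize(
    dataset, dictionary: AttributeDictionary, config: OptimizerConfig
) -> tuple[CorrelationWeights, OptimizationTrace]:
    """Run N epochs of Monte Carlo weight optimization.

    Returns the final weight table (blocked attributes pinned at 0) and
    the full trace.  The accepted-move TF sequence is non-decreasing by
    construction; the proposal stream depends only on the seed, so the
    same dataset and configuration reproduce identical weights.
    """
    if dictionary.threshold != config.t:
        raise ConfigurationError(
            f"dictionary built with T={dictionary.threshold} "
            f"but optimizer configured with T={config.t}"
        )
    blocks = {}
    for label in (ACTIVE, PASSIVE, CALIBRATION):
        recs = dataset.subset(label)
        if not recs:
            raise ConfigurationError(f"empty {label} block")
        y = np.asarray([r.endpoint for r in recs], dtype=float)
        if np.any(~np.isfinite(y)):
            raise InputError(f"missing endpoint in {label} block")
        if np.var(y) <= 0.0:
            raise DegenerateError(f"zero endpoint variance in {label} block")
        blocks[label] = (recs, y)
    attrs = dictionary.non_blocked()
    if not attrs:
        raise ConfigurationError("all attributes are blocked; nothing to optimize")

    x = {label: occurrence_matrix(recs, attrs) for label, (recs, _) in blocks.items()}
    y = {label: yv for label, (_, yv) in blocks.items()}
    objective = _Objective(
        x[ACTIVE], y[ACTIVE], x[PASSIVE], y[PASSIVE], x[CALIBRATION], y[CALIBRATION], config
    )

    m = len(attrs)
    w = np.full(m, float(config.initial_weight))
    dcw = {label: x[label] @ w for label in x}
    rng = np.random.default_rng(config.seed)

    trace = OptimizationTrace()
    current_tf, stats = objective.evaluate(dcw)
    trace.initial_tf = current_tf

    for epoch in range(config.n_epochs):
        order = rng.permutation(m)
        for j in order:
            step = float(rng.uniform(0.0, config.step_magnitude))
            best_delta, best_tf, best_stats = None, current_tf, stats
            for delta in (step, -step):
                candidate = {
                    label: dcw[label] + delta * x[label][:, j] for label in dcw
                }
                cand_tf, cand_stats = objective.evaluate(candidate)
                if cand_tf >= best_tf:
                    best_delta, best_tf, best_stats = delta, cand_tf, cand_stats
            if best_delta is not None:
                w[j] += best_delta
                dcw = {
                    label: dcw[label] + best_delta * x[label][:, j] for label in dcw
                }
                current_tf, stats = best_tf, best_stats
                trace.moves.append(
                    AcceptedMove(
                        epoch, attrs[j], float(w[j] - best_delta), float(w[j]), best_tf
                    )
                )
        stats.epoch = epoch
        trace.epochs.append(
            EpochStats(epoch, stats.r_active, stats.r_passive, stats.iic_cal, stats.cii_cal, current_tf)
        )
    trace.final_tf = current_tf

    weights = CorrelationWeights(
        {attr: float(wj) for attr, wj in zip(attrs, w)},
        blocked=dictionary.blocked(),
    )
    return weights, trace
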
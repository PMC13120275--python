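"""Random four-way partitions and Las Vegas split selection.

The data are divided into active training, passive training, calibration
and validation blocks of approximately equal size.  Because model quality
depends noticeably on which compounds land in the calibration set, the
split itself is searched: draw k random partitions, score each with a
short probe optimization, and keep the best — a Las Vegas strategy in the
sense that more draws can only improve (never worsen) the selected split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .attributes import build_attribute_dictionary
from .errors import ConfigurationError, InputError
from .labels import SET_LABELS
from .metrics import r2 as _r2
from .optimizer import OptimizerConfig, _safe_cii, _safe_iic, occurrence_matrix, optimize

logger = logging.getLogger(__name__)

EQUAL_PROPORTIONS = (0.25, 0.25, 0.25, 0.25)


@dataclass
class SplitAssignment:
    """A four-way partition of a dataset, reproducible from its seed."""

    assignment: dict[str, str]
    proportions: tuple[float, float, float, float]
    seed: int
    #: filled by las_vegas_select: (candidate seed, probe score) per draw
    candidate_scores: list[tuple[int, float]] = field(default_factory=list)

    def apply(self, dataset):
        """Dataset copy with the partition written into the set labels."""
        return dataset.with_labels(self.assignment)

    def block_sizes(self) -> dict[str, int]:
        sizes = {label: 0 for label in SET_LABELS}
        for label in self.assignment.values():
            sizes[label] += 1
        return sizes


def _target_sizes(n: int, proportions) -> list[int]:
    """Largest-remainder rounding of n * proportions to integers summing n."""
    raw = [n * p for p in proportions]
    sizes = [int(np.floor(v)) for v in raw]
    remainders = [v - s for v, s in zip(raw, sizes)]
    for i in sorted(range(len(sizes)), key=lambda i: -remainders[i])[
        : n - sum(sizes)
    ]:
        sizes[i] += 1
    return sizes


def random_partition(dataset, proportions=EQUAL_PROPORTIONS, seed: int = 0) -> SplitAssignment:
    """Seeded random partition with largest-remainder block sizes."""
    proportions = tuple(float(p) for p in proportions)
    if len(proportions) != 4 or any(p <= 0 for p in proportions):
        raise ConfigurationError("need four positive proportions")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigurationError(
            f"proportions must sum to 1, got {sum(proportions)}"
        )
    n = len(dataset)
    if n < 8:
        raise ConfigurationError(f"dataset too small to split four ways: n={n}")
    sizes = _target_sizes(n, proportions)
    if any(s == 0 for s in sizes):
        raise ConfigurationError(f"a split block would be empty: sizes {sizes}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, str] = {}
    start = 0
    for label, size in zip(SET_LABELS, sizes):
        for i in order[start : start + size]:
            assignment[dataset[int(i)].id] = label
        start += size
    return SplitAssignment(assignment, proportions, seed)


def distribution_overlap(dataset, split: SplitAssignment, bins: int = 10) -> dict:
    """Histogram-intersection fraction of endpoint distributions per block pair.

    Shared equal-width bins over the pooled endpoint range; 1 means the
    two blocks' endpoint histograms coincide, 0 means disjoint support.
    """
    values = {label: [] for label in SET_LABELS}
    for record in dataset:
        label = split.assignment.get(record.id)
        if label is None:
            continue
        if record.endpoint is None:
            raise InputError(f"record {record.id!r} lacks an endpoint")
        values[label].append(record.endpoint)
    pooled = np.concatenate([np.asarray(v) for v in values.values() if v])
    pairs = [
        (a, b)
        for i, a in enumerate(SET_LABELS)
        for b in SET_LABELS[i + 1 :]
        if values[a] and values[b]
    ]
    lo, hi = float(pooled.min()), float(pooled.max())
    if hi <= lo:
        warnings.warn(
            "zero endpoint variance: all distribution overlaps are 1",
            UserWarning,
            stacklevel=2,
        )
        return {pair: 1.0 for pair in pairs}
    out = {}
    for a, b in pairs:
        ha, _ = np.histogram(values[a], bins=bins, range=(lo, hi))
        hb, _ = np.histogram(values[b], bins=bins, range=(lo, hi))
        pa = ha / ha.sum()
        pb = hb / hb.sum()
        out[(a, b)] = float(np.minimum(pa, pb).sum())
    return out


def _probe_score(labeled, t: int, probe_epochs: int, seed: int, criterion: str) -> float:
    """Score a candidate split: calibration quality after a short TF1 probe."""
    dictionary = build_attribute_dictionary(labeled, t)
    config = OptimizerConfig(t=t, n_epochs=probe_epochs, target_function="TF1", seed=seed)
    weights, _ = optimize(labeled, dictionary, config)
    attrs = dictionary.non_blocked()
    w = np.asarray([weights.weight_of(a) for a in attrs])
    act = labeled.subset("active")
    cal = labeled.subset("calibration")
    dcw_a = occurrence_matrix(act, attrs) @ w
    dcw_c = occurrence_matrix(cal, attrs) @ w
    y_a = np.asarray([r.endpoint for r in act])
    y_c = np.asarray([r.endpoint for r in cal])
    xc = dcw_a - dcw_a.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        return -np.inf
    c1 = float(xc @ (y_a - y_a.mean())) / sxx
    c0 = float(y_a.mean() - c1 * dcw_a.mean())
    calc = c0 + c1 * dcw_c
    if criterion == "iic_cii":
        return _safe_iic(y_c, calc) + _safe_cii(y_c, calc)
    if criterion == "r2":
        try:
            return _r2(y_c, calc)
        except Exception:
            return -np.inf
    raise ConfigurationError(f"unknown split criterion {criterion!r}")


def las_vegas_select(
    dataset,
    k: int = 10,
    probe_epochs: int = 3,
    t: int = 3,
    seed: int = 0,
    proportions=EQUAL_PROPORTIONS,
    criterion: str = "iic_cii",
) -> SplitAssignment:
    """Best of k random partitions, scored by a short probe optimization.

    Candidate seeds derive deterministically from *seed* and are
    prefix-stable in k, so enlarging k never loses (or reorders) the
    candidates already considered.  All candidate scores are retained on
    the returned assignment and logged.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    children = np.random.SeedSequence(seed).spawn(k)
    best: SplitAssignment | None = None
    best_score = -np.inf
    scores: list[tuple[int, float]] = []
    for child in children:
        child_seed = int(child.generate_state(1)[0] % (2**31))
        split = random_partition(dataset, proportions, child_seed)
        labeled = split.apply(dataset)
        if criterion == "overlap":
            overlaps = distribution_overlap(dataset, split)
            score = float(np.mean(list(overlaps.values())))
        else:
            score = _probe_score(labeled, t, probe_epochs, child_seed, criterion)
        scores.append((child_seed, score))
        logger.info("split candidate seed=%d score=%.6f", child_seed, score)
        if score > best_score:
            best, best_score = split, score
    logger.info("selected split seed=%d score=%.6f of k=%d", best.seed, best_score, k)
    best.candidate_scores = scores
    return best
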
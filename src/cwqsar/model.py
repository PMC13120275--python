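"""The optimal descriptor DCW and the final one-descriptor model.

The endpoint model is a single least-squares line

    endpoint = C0 + C1 * DCW(T, N)

where DCW is the sum of correlation weights over every attribute
occurrence in a compound's SMILES (singles plus adjacent pairs).  Blocked
(rare) attributes and attributes never seen in training contribute zero;
the latter are counted and surfaced alongside the applicability-domain
flag, so prediction never fails on a novel structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .attributes import (
    Attribute,
    AttributeDictionary,
    attribute_occurrences,
    tokenize_smiles,
)
from .errors import ConfigurationError, DegenerateError


class CorrelationWeights:
    """Mapping attribute -> real weight, with blocked attributes pinned at 0."""

    def __init__(
        self,
        weights: Optional[dict[Attribute, float]] = None,
        blocked: Iterable[Attribute] = (),
    ):
        self._weights = dict(weights or {})
        self.blocked = frozenset(blocked)
        clash = [a for a in self.blocked if self._weights.get(a, 0.0) != 0.0]
        if clash:
            raise ConfigurationError(
                f"blocked attribute carries a nonzero weight: {clash[0].render}"
            )
        for a in self.blocked:
            self._weights.pop(a, None)

    def weight_of(self, attr: Attribute) -> float:
        """Weight used in the descriptor sum; 0 for blocked or unknown."""
        return self._weights.get(attr, 0.0)

    def get(self, attr: Attribute) -> Optional[float]:
        """Weight of a known non-blocked attribute, else None."""
        return self._weights.get(attr)

    def is_known(self, attr: Attribute) -> bool:
        return attr in self._weights or attr in self.blocked

    def items(self):
        return self._weights.items()

    def __len__(self) -> int:
        return len(self._weights)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CorrelationWeights)
            and self._weights == other._weights
            and self.blocked == other.blocked
        )

    def scaled(self, factor: float) -> "CorrelationWeights":
        return CorrelationWeights(
            {a: w * factor for a, w in self._weights.items()}, self.blocked
        )


@dataclass
class ModelConfig:
    """Configuration echo of the run that produced a model."""

    t: int = 3
    n_epochs: int = 15
    target_function: str = "TF1"
    seed: int = 0


@dataclass
class QsarModel:
    """Fitted correlation-weight model plus everything prediction needs.

    The attribute dictionary (per-set counts) and the mean training defect
    travel with the model so that the applicability domain of new compounds
    can be evaluated without access to the training table.
    """

    weights: CorrelationWeights
    c0: float
    c1: float
    config: ModelConfig = field(default_factory=ModelConfig)
    dictionary: Optional[AttributeDictionary] = None
    d_bar: Optional[float] = None

    @property
    def fitted(self) -> bool:
        return self.c0 is not None and self.c1 is not None


def descriptor_profile(
    smiles: str, weights: CorrelationWeights
) -> tuple[float, int]:
    """DCW of a SMILES plus the number of unseen attribute occurrences.

    Unseen means absent from the weight table entirely (never observed in
    training); blocked attributes are known and simply contribute zero.
    """
    dcw = 0.0
    unseen = 0
    for attr in attribute_occurrences(tokenize_smiles(smiles)):
        if attr in weights.blocked:
            continue
        w = weights.get(attr)
        if w is None:
            unseen += 1
        else:
            dcw += w
    return dcw, unseen


def compute_dcw(smiles: str, weights: CorrelationWeights) -> float:
    """Sum of correlation weights over every attribute occurrence."""
    return descriptor_profile(smiles, weights)[0]


def fit_regression(dcw_values, endpoints) -> tuple[float, float]:
    """Ordinary least-squares intercept and slope of endpoint on DCW."""
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ConfigurationError(
            f"regression needs >= 3 paired points, got {x.size}/{y.size}"
        )
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0.0:
        raise DegenerateError("zero DCW variance: descriptor is degenerate")
    c1 = float(xc @ (y - y.mean())) / sxx
    c0 = float(y.mean() - c1 * x.mean())
    return c0, c1


def predict(smiles: str, model: QsarModel) -> tuple[float, float]:
    """DCW and endpoint estimate ``c0 + c1 * DCW`` for one compound."""
    if not model.fitted:
        raise ConfigurationError("model is not fitted (missing C0/C1)")
    dcw = compute_dcw(smiles, model.weights)
    return dcw, model.c0 + model.c1 * dcw
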
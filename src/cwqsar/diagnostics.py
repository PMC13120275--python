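"""Applicability domain and mechanistic interpretation.

**Statistical defects.**  For each attribute, the defect ``d_k`` measures
how unevenly the attribute is distributed over the active training,
passive training and calibration blocks: pairwise absolute differences of
its per-block occurrence probabilities, each divided by the summed
occurrence frequencies.  A compound's defect ``D_j`` is the sum of ``d_k``
over its non-blocked attribute occurrences, and a compound is in the
applicability domain iff ``D_j < 2 * D_bar``, where ``D_bar`` is the mean
defect over the training compounds (active + passive + calibration).  The
domain is advisory: it flags compounds built from statistically unstable
fragments, not chemically implausible ones.

**Promoters.**  An attribute whose correlation weight keeps one sign
across several independent optimization runs — and which is frequent in
all three training-type blocks — is interpreted as a promoter of endpoint
increase (all weights positive) or decrease (all negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .attributes import Attribute, AttributeDictionary, attribute_occurrences, tokenize_smiles
from .errors import ConfigurationError, InputError
from .labels import ACTIVE, CALIBRATION, PASSIVE
from .model import CorrelationWeights


def statistical_defect(attr: Attribute, dictionary: AttributeDictionary) -> float:
    """Attribute defect d_k over the three training-type blocks.

    ``d_k = |P-P'|/(N+N') + |P-P''|/(N+N'') + |P'-P''|/(N'+N'')`` with P
    the per-block compound fraction and N the per-block compound count of
    the attribute.  Zero iff the three probabilities coincide.
    """
    if attr not in dictionary:
        raise InputError(f"attribute {attr.render} not in dictionary")
    stats = dictionary[attr]
    counts = [stats.count(label) for label in (ACTIVE, PASSIVE, CALIBRATION)]
    sizes = [dictionary.set_sizes.get(label, 0) for label in (ACTIVE, PASSIVE, CALIBRATION)]
    if all(c == 0 for c in counts):
        warnings.warn(
            f"attribute {attr.render} absent from all training-type blocks; d_k = 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    if any(s == 0 for s in sizes):
        raise ConfigurationError("empty training-type block in dictionary")
    probs = [c / s for c, s in zip(counts, sizes)]
    d = 0.0
    for i in range(3):
        for j in range(i + 1, 3):
            freq_sum = counts[i] + counts[j]
            if freq_sum > 0:
                d += abs(probs[i] - probs[j]) / freq_sum
    return d


def attribute_defects(dictionary: AttributeDictionary) -> dict[Attribute, float]:
    """d_k for every dictionary attribute (0 for the all-absent ones)."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for attr in dictionary.entries:
            out[attr] = statistical_defect(attr, dictionary)
    return out


def compound_defect(
    smiles: str,
    dictionary: AttributeDictionary,
    defects: Optional[dict[Attribute, float]] = None,
) -> float:
    """Compound defect D_j: sum of d_k over non-blocked occurrences.

    Each occurrence contributes its attribute's d_k once (per-occurrence,
    mirroring the descriptor sum).  Blocked and never-seen attributes
    contribute nothing; a compound whose attributes are all blocked or
    unseen gets D_j = 0 with a warning.
    """
    if defects is None:
        defects = attribute_defects(dictionary)
    total = 0.0
    any_active = False
    for attr in attribute_occurrences(tokenize_smiles(smiles)):
        stats = dictionary.entries.get(attr)
        if stats is None or stats.blocked:
            continue
        any_active = True
        total += defects.get(attr, 0.0)
    if not any_active:
        warnings.warn(
            "compound has no non-blocked known attributes; D_j = 0",
            UserWarning,
            stacklevel=2,
        )
    return total


def in_domain(d_j: float, d_bar: float) -> bool:
    """Strict applicability-domain rule ``D_j < 2 * D_bar``.

    At ``D_bar = 0`` (degenerate, perfectly uniform data) nothing passes
    the strict inequality, so every compound is flagged out of domain.
    """
    return d_j < 2.0 * d_bar


@dataclass
class DefectReport:
    """Per-attribute and per-compound defect summary for a labeled dataset."""

    defects: dict[Attribute, float]
    compound_defects: dict[str, float]  # id -> D_j
    d_bar: float
    in_domain_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return 2.0 * self.d_bar


def build_defect_report(dataset, dictionary: AttributeDictionary) -> DefectReport:
    """Defects for every record; D_bar over active + passive + calibration."""
    defects = attribute_defects(dictionary)
    compound_defects: dict[str, float] = {}
    training: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for record in dataset:
            d_j = compound_defect(record.smiles, dictionary, defects)
            compound_defects[record.id] = d_j
            if record.set_label in (ACTIVE, PASSIVE, CALIBRATION):
                training.append(d_j)
    if not training:
        raise ConfigurationError("no training compounds to define the mean defect")
    d_bar = float(np.mean(training))
    if d_bar == 0.0:
        warnings.warn(
            "mean training defect is 0: the strict domain rule flags every "
            "compound out of domain",
            UserWarning,
            stacklevel=2,
        )
    flags = {cid: in_domain(dj, d_bar) for cid, dj in compound_defects.items()}
    return DefectReport(defects, compound_defects, d_bar, flags)


@dataclass
class PromoterRow:
    attribute: Attribute
    role: str  # "increase" or "decrease"
    weights: tuple[float, ...]
    count_active: int
    count_passive: int
    count_calibration: int
    d_k: float


@dataclass
class PromoterTable:
    rows: list[PromoterRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "attribute": [r.attribute.render for r in self.rows],
                "role": [r.role for r in self.rows],
                **{
                    f"run_{i + 1}": [r.weights[i] for r in self.rows]
                    for i in range(len(self.rows[0].weights) if self.rows else 0)
                },
                "n_active": [r.count_active for r in self.rows],
                "n_passive": [r.count_passive for r in self.rows],
                "n_calibration": [r.count_calibration for r in self.rows],
                "d_k": [r.d_k for r in self.rows],
            }
        )


def extract_promoters(
    runs: Sequence[CorrelationWeights],
    dictionary: AttributeDictionary,
    min_frequency: int = 10,
) -> PromoterTable:
    """Sign-stable, frequent attributes across >= 3 optimization runs.

    Attributes whose weights are nonzero with the same sign in every run
    and which occur in at least *min_frequency* compounds of each of the
    active, passive and calibration blocks are classified as increase
    (all positive) or decrease (all negative) promoters; sign-unstable or
    rare attributes are omitted.  Rows are sorted by active-set frequency,
    descending.
    """
    if len(runs) < 3:
        raise ConfigurationError(
            f"promoter extraction needs >= 3 runs, got {len(runs)}"
        )
    defects = attribute_defects(dictionary)
    rows: list[PromoterRow] = []
    for attr in dictionary.non_blocked():
        ws = tuple(r.weight_of(attr) for r in runs)
        if all(w > 0 for w in ws):
            role = "increase"
        elif all(w < 0 for w in ws):
            role = "decrease"
        else:
            continue
        stats = dictionary[attr]
        if min(
            stats.count_active, stats.count_passive, stats.count_calibration
        ) < min_frequency:
            continue
        rows.append(
            PromoterRow(
                attr,
                role,
                ws,
                stats.count_active,
                stats.count_passive,
                stats.count_calibration,
                defects[attr],
            )
        )
    rows.sort(key=lambda r: (-r.count_active, r.attribute))
    return PromoterTable(rows)
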
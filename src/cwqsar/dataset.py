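"""Compound tables and model files.

Input is a flat CSV/TSV table with header columns ``id``, ``smiles``,
``endpoint`` and an optional ``set`` column carrying the four-way partition
as A/P/C/V codes (or full label words).  The endpoint is consumed already
log-transformed (pNOAEL = -log10 of NOAEL in mg/kg bw/day for the intended
use case); :func:`to_pnoael` converts raw doses.

Model files are plain YAML: regression coefficients, run configuration,
and the attribute -> weight table together with per-set attribute counts,
so a model file alone supports prediction and applicability-domain
assessment.  Floats are written in shortest round-trip decimal form, so
read(write(model)) is bit-exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import yaml

from .attributes import Attribute, AttributeDictionary, AttributeStats
from .errors import ConfigurationError, FormatError, InputError
from .labels import LABEL_ALIASES, LABEL_CODES, SET_LABELS, UNASSIGNED
from .model import CorrelationWeights, ModelConfig, QsarModel

MODEL_FORMAT = "cwqsar-model/1"


@dataclass
class CompoundRecord:
    """One compound: identifier, SMILES text, endpoint, partition label."""

    id: str
    smiles: str
    endpoint: Optional[float] = None
    set_label: str = UNASSIGNED

    def __post_init__(self):
        if not self.smiles:
            raise InputError(f"record {self.id!r}: empty SMILES")
        if self.endpoint is not None and not math.isfinite(self.endpoint):
            raise InputError(f"record {self.id!r}: non-finite endpoint")
        if self.set_label not in (*SET_LABELS, UNASSIGNED):
            raise InputError(
                f"record {self.id!r}: unknown set label {self.set_label!r}"
            )


class Dataset:
    """Ordered collection of compound records with unique identifiers."""

    def __init__(self, records):
        self.records: list[CompoundRecord] = list(records)
        seen_ids: set[str] = set()
        seen_smiles: set[str] = set()
        dup_smiles = []
        for r in self.records:
            if r.id in seen_ids:
                raise InputError(f"duplicate compound id {r.id!r}")
            seen_ids.add(r.id)
            if r.smiles in seen_smiles:
                dup_smiles.append(r.id)
            seen_smiles.add(r.smiles)
        if dup_smiles:
            warnings.warn(
                f"{len(dup_smiles)} duplicate SMILES in dataset "
                f"(e.g. record {dup_smiles[0]!r}); consider de-duplicating",
                UserWarning,
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> CompoundRecord:
        return self.records[i]

    def subset(self, label: str) -> list[CompoundRecord]:
        return [r for r in self.records if r.set_label == label]

    def endpoints(self) -> np.ndarray:
        vals = [r.endpoint for r in self.records]
        if any(v is None for v in vals):
            raise InputError("dataset contains records without endpoint")
        return np.asarray(vals, dtype=float)

    def with_labels(self, assignment: dict[str, str]) -> "Dataset":
        """New dataset with set labels taken from an id -> label mapping."""
        return Dataset(
            [
                replace(r, set_label=assignment.get(r.id, r.set_label))
                for r in self.records
            ]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "smiles": [r.smiles for r in self.records],
                "endpoint": [r.endpoint for r in self.records],
                "set": [LABEL_CODES.get(r.set_label, "") for r in self.records],
            }
        )


def canonicalize_smiles(smiles: str) -> str:
    """Optional canonicalization hook (requires the ``chem`` extra).

    The modelling pipeline never needs it — attributes are pure text — but
    mixing SMILES dialects across compounds changes attribute statistics,
    so canonicalizing inputs from heterogeneous sources is good practice.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError(
            "SMILES canonicalization requires rdkit (install the 'chem' extra)"
        ) from exc
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"rdkit could not parse SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


def to_pnoael(dose_mg_kg: float) -> float:
    """Convert a NOAEL in mg/kg bw/day to the modeled endpoint -log10(dose)."""
    if dose_mg_kg <= 0:
        raise InputError(f"dose must be positive, got {dose_mg_kg}")
    return -math.log10(dose_mg_kg)


def _separator(path: Path, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"
    if fmt not in ("csv", "tsv"):
        raise ConfigurationError(f"unknown table format {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def read_dataset(
    path, fmt: Optional[str] = None, convert_from_dose: bool = False
) -> Dataset:
    """Read a compound table; one record per row, in file order.

    ``convert_from_dose`` applies -log10 to the endpoint column (raw
    mg/kg bw/day doses).  Row-level errors carry the 1-based data row
    number.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep=_separator(path, fmt), dtype=str, keep_default_na=False)
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in ("id", "smiles", "endpoint"):
        if col not in df.columns:
            raise FormatError(f"missing required column '{col}' in {path}")
    has_set = "set" in df.columns
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        raw = str(getattr(row, "endpoint")).strip()
        if raw == "":
            endpoint = None
        else:
            try:
                endpoint = float(raw)
            except ValueError:
                raise InputError(
                    f"row {i}: non-numeric endpoint {raw!r}"
                ) from None
        if endpoint is not None and convert_from_dose:
            endpoint = to_pnoael(endpoint)
        label = UNASSIGNED
        if has_set:
            code = str(getattr(row, "set")).strip()
            if code:
                if code not in LABEL_ALIASES:
                    raise InputError(f"row {i}: unknown set code {code!r}")
                label = LABEL_ALIASES[code]
        records.append(
            CompoundRecord(
                id=str(getattr(row, "id")).strip(),
                smiles=str(getattr(row, "smiles")).strip(),
                endpoint=endpoint,
                set_label=label,
            )
        )
    return Dataset(records)


def write_dataset(dataset: Dataset, path, fmt: Optional[str] = None) -> None:
    path = Path(path)
    dataset.to_dataframe().to_csv(path, sep=_separator(path, fmt), index=False)


# ---------------------------------------------------------------------------
# model files


def _attr_to_doc(
    attr: Attribute,
    weight: float,
    blocked: bool,
    stats: Optional[AttributeStats],
):
    doc = {
        "kind": attr.kind,
        "tokens": list(attr.tokens),
        "weight": float(weight),
        "blocked": blocked,
    }
    if stats is not None:
        doc["counts"] = [
            stats.count_active,
            stats.count_passive,
            stats.count_calibration,
            stats.count_validation,
        ]
    return doc


def write_model(model: QsarModel, path) -> None:
    """Serialize a fitted model (weights, coefficients, config, counts)."""
    if not model.fitted:
        raise ConfigurationError("cannot write an unfitted model (missing C0/C1)")
    entries = []
    attrs = sorted(
        set(a for a, _ in model.weights.items()) | set(model.weights.blocked)
    )
    if model.dictionary is not None:
        attrs = sorted(set(attrs) | set(model.dictionary.entries))
    for attr in attrs:
        stats = (
            model.dictionary.entries.get(attr)
            if model.dictionary is not None
            else None
        )
        blocked = (
            stats.blocked if stats is not None else attr in model.weights.blocked
        )
        entries.append(
            _attr_to_doc(attr, model.weights.weight_of(attr), blocked, stats)
        )
    doc = {
        "format": MODEL_FORMAT,
        "c0": float(model.c0),
        "c1": float(model.c1),
        "config": {
            "t": model.config.t,
            "n_epochs": model.config.n_epochs,
            "target_function": model.config.target_function,
            "seed": model.config.seed,
        },
        "d_bar": None if model.d_bar is None else float(model.d_bar),
        "set_sizes": (
            dict(model.dictionary.set_sizes)
            if model.dictionary is not None
            else None
        ),
        "weights": entries,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path) -> QsarModel:
    """Load a model file; round-trips :func:`write_model` bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise FormatError(f"unparseable model file {path}: {exc}") from None
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise FormatError(f"{path} is not a {MODEL_FORMAT} file")
    for key in ("c0", "c1", "config", "weights"):
        if key not in doc or doc[key] is None and key != "weights":
            raise FormatError(f"model file {path} missing field '{key}'")
    cfg = doc["config"]
    config = ModelConfig(
        t=int(cfg["t"]),
        n_epochs=int(cfg["n_epochs"]),
        target_function=str(cfg["target_function"]),
        seed=int(cfg["seed"]),
    )
    weights: dict[Attribute, float] = {}
    blocked: list[Attribute] = []
    entries: dict[Attribute, AttributeStats] = {}
    have_counts = False
    for item in doc["weights"] or []:
        attr = Attribute(str(item["kind"]), tuple(item["tokens"]))
        if item.get("blocked", False):
            blocked.append(attr)
        else:
            weights[attr] = float(item["weight"])
        if "counts" in item:
            have_counts = True
            ca, cp, cc, cv = (int(c) for c in item["counts"])
            entries[attr] = AttributeStats(
                ca, cp, cc, cv, blocked=bool(item.get("blocked", False))
            )
    dictionary = None
    if have_counts and doc.get("set_sizes"):
        dictionary = AttributeDictionary(
            entries, config.t, {k: int(v) for k, v in doc["set_sizes"].items()}
        )
    d_bar = doc.get("d_bar")
    return QsarModel(
        weights=CorrelationWeights(weights, blocked),
        c0=float(doc["c0"]),
        c1=float(doc["c1"]),
        config=config,
        dictionary=dictionary,
        d_bar=None if d_bar is None else float(d_bar),
    )
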
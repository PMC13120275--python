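"""Synthetic SMILES-like datasets with a planted additive endpoint.

The generator emits grammar-valid strings over a small token alphabet
(chains with optional branches and at most one ring closure) and assigns
each compound an endpoint that is affine in the sum of planted
per-attribute weights — exactly the statistical structure the
correlation-weight model assumes.  Strings are *not* chemically
validated: the method consults only token statistics, so chemical realism
is irrelevant to what these fixtures test.  Defaults are sized to mimic a
regulatory-toxicity table: a few hundred compounds, endpoint spanning
several log units, measurement noise well below the endpoint spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .attributes import Attribute, attribute_occurrences, tokenize_smiles
from .dataset import CompoundRecord, Dataset
from .errors import ConfigurationError
from .splitting import EQUAL_PROPORTIONS, random_partition

#: Planted ground-truth weights: singles span the chemistry the promoter
#: analysis expects (sulfur up, oxygen/nitrogen/double bonds down), plus a
#: few pair attributes so both attribute kinds carry signal.
DEFAULT_TRUE_WEIGHTS: dict[Attribute, float] = {
    Attribute.single("C"): 0.30,
    Attribute.single("c"): -0.20,
    Attribute.single("O"): -0.60,
    Attribute.single("N"): -0.55,
    Attribute.single("S"): 0.90,
    Attribute.single("="): -0.45,
    Attribute.single("("): 0.15,
    Attribute.single("1"): 0.10,
    Attribute.single("Cl"): 0.70,
    Attribute.pair("C", "="): -0.25,
    Attribute.pair("c", "O"): -0.30,
    Attribute.pair("S", "C"): 0.40,
}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic benchmark.

    ``length_range`` is the inclusive range of the *backbone* token count;
    branches and ring digits push the final token count slightly higher.
    ``noise_sd`` is the standard deviation of additive Gaussian endpoint
    noise, in endpoint (log) units.
    """

    n_compounds: int = 300
    token_alphabet: tuple = ("C", "c", "O", "N", "S", "=", "(", "1", "Cl")
    length_range: tuple = (6, 14)
    true_weights: Optional[dict[Attribute, float]] = None
    c0_true: float = -0.9
    c1_true: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def resolved_weights(self) -> dict[Attribute, float]:
        return dict(
            DEFAULT_TRUE_WEIGHTS if self.true_weights is None else self.true_weights
        )


def _atoms(alphabet) -> list[str]:
    structural = {"=", "(", ")", "1"}
    atoms = [t for t in alphabet if t not in structural]
    if not atoms:
        raise ConfigurationError("alphabet contains no atom tokens")
    return atoms


def _compound_tokens(rng: np.random.Generator, spec: GeneratorSpec) -> tuple[str, list[str]]:
    """One grammar-generated string plus its emitted-token record.

    The record normalizes ``)`` to ``(`` exactly as the tokenizer does, so
    it can be compared against a fresh tokenization.
    """
    alphabet = spec.token_alphabet
    atoms = _atoms(alphabet)
    lo, hi = spec.length_range
    if lo < 3 or hi < lo:
        raise ConfigurationError(f"invalid length range {spec.length_range}")
    target = int(rng.integers(lo, hi + 1))
    has_bond = "=" in alphabet
    has_branch = "(" in alphabet
    has_ring = "1" in alphabet

    chars: list[str] = []
    tokens: list[str] = []

    def emit(char: str) -> None:
        chars.append(char)
        tokens.append("(" if char == ")" else char)

    def atom() -> str:
        return atoms[int(rng.integers(len(atoms)))]

    emit(atom())
    ring_open = False
    ring_used = False
    since_ring = 0
    while len(tokens) < target:
        r = rng.random()
        since_ring += 1
        if has_bond and r < 0.12 and tokens[-1] not in ("=", "("):
            emit("=")
            emit(atom())
        elif has_branch and r < 0.30:
            emit("(")
            for _ in range(int(rng.integers(1, 3))):
                emit(atom())
            emit(")")
        elif has_ring and not ring_used and r < 0.45:
            emit(atom())
            emit("1")
            ring_open = True
            ring_used = True
            since_ring = 0
        elif has_ring and ring_open and since_ring >= 2 and r < 0.60:
            emit(atom())
            emit("1")
            ring_open = False
        else:
            emit(atom())
    if ring_open:
        emit(atom())
        emit("1")
    return "".join(chars), tokens


def true_descriptor(tokens: list[str], weights: dict[Attribute, float]) -> float:
    """Planted descriptor: per-occurrence sum of true attribute weights."""
    return sum(weights.get(a, 0.0) for a in attribute_occurrences(tokens))


def generate_dataset(spec: GeneratorSpec) -> Dataset:
    """Generate ``n_compounds`` records with the planted affine endpoint.

    ``endpoint = c0_true + c1_true * true_descriptor + N(0, noise_sd)``;
    the same seed reproduces the dataset exactly, and every generated
    string tokenizes back to the generator's own token record.
    """
    if spec.n_compounds < 1:
        raise ConfigurationError("n_compounds must be positive")
    weights = spec.resolved_weights()
    for tok in spec.token_alphabet:
        emitted = tokenize_smiles(tok if tok != "(" else "(C")
        if tok != "(" and emitted != [tok]:
            raise ConfigurationError(f"alphabet token {tok!r} is not atomic")
    rng = np.random.default_rng(spec.seed)
    records = []
    seen: dict[str, int] = {}
    for i in range(spec.n_compounds):
        smiles, tokens = _compound_tokens(rng, spec)
        # re-tokenization must agree with the generator's record
        assert tokenize_smiles(smiles) == tokens
        endpoint = (
            spec.c0_true
            + spec.c1_true * true_descriptor(tokens, weights)
            + float(rng.normal(0.0, spec.noise_sd))
        )
        # ids stay unique even when the grammar repeats a string
        seen[smiles] = seen.get(smiles, 0) + 1
        records.append(
            CompoundRecord(id=f"SYN{i + 1:04d}", smiles=smiles, endpoint=endpoint)
        )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return Dataset(records)


def assign_splits(dataset: Dataset, proportions=EQUAL_PROPORTIONS, seed: int = 0) -> Dataset:
    """Label a dataset with a seeded random four-way partition."""
    return random_partition(dataset, proportions, seed).apply(dataset)
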
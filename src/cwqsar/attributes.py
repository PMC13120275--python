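"""SMILES attribute extraction.

The descriptor treats a SMILES string purely as text: it is cut into
indivisible fragments ("SMILES atoms", ``S_k``) — single characters plus a
small list of multi-character groups such as ``Cl`` or ``@@`` — and into
unordered pairs of adjacent fragments (``SS_k``).  No chemistry is
perceived; the model's information content is entirely the statistics of
these fragments across the training sets.

Closing parentheses are folded into ``(`` before attribute extraction, so a
branch contributes the same attribute whether a fragment sits before the
opening or after the closing bracket.  Pairs are canonicalized
order-independently: ``pair(a, b) == pair(b, a)``, rendered with the
lexicographically larger token first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, TokenizationError
from .labels import SET_LABELS

#: Multi-character fragments that must not be split.
TWO_CHAR_TOKENS = ("Cl", "Br", "Si", "@@")

_PLAIN_CHARS = frozenset(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
    "0123456789"
    "=#+-()./\\@:*"
)


def tokenize_smiles(smiles: str) -> list[str]:
    """Decompose a SMILES string into its indivisible fragments.

    Every character of the input is consumed exactly once.  ``)`` is
    normalized to ``(``; bracket-atom expressions ``[...]`` are one token
    with their content kept verbatim; ``%nn`` ring closures are one token.
    Case is preserved (aromatic lowercase stays distinct from aliphatic
    uppercase).

    Raises
    ------
    TokenizationError
        On an empty string or an unrecognized character (the message names
        the character and its position).
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j < 0:
                raise TokenizationError(
                    f"unclosed bracket atom starting at position {i}"
                )
            tokens.append(smiles[i : j + 1])
            i = j + 1
            continue
        if smiles[i : i + 2] in TWO_CHAR_TOKENS:
            tokens.append(smiles[i : i + 2])
            i += 2
            continue
        if ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise TokenizationError(
                    f"ring closure '%' at position {i} not followed by two digits"
                )
            tokens.append(smiles[i : i + 3])
            i += 3
            continue
        if ch == ")":
            tokens.append("(")
            i += 1
            continue
        if ch == "]":
            raise TokenizationError(f"unmatched ']' at position {i}")
        if ch in _PLAIN_CHARS:
            tokens.append(ch)
            i += 1
            continue
        raise TokenizationError(
            f"unrecognized character {ch!r} at position {i}"
        )
    return tokens


_RENDER_WIDTH = 12
_PAIR_PAD = 4


@dataclass(frozen=True, order=True)
class Attribute:
    """A model attribute: a single fragment or an unordered adjacent pair."""

    kind: str  # "single" or "pair"
    tokens: tuple[str, ...]

    @staticmethod
    def single(token: str) -> "Attribute":
        return Attribute("single", (token,))

    @staticmethod
    def pair(a: str, b: str) -> "Attribute":
        """Canonical unordered pair: larger token (string order) first."""
        hi, lo = (a, b) if a >= b else (b, a)
        return Attribute("pair", (hi, lo))

    @property
    def render(self) -> str:
        """Dot-padded text form (cosmetic, mirrors the software's fixed
        12-column attribute layout, e.g. ``Cl..(.......``)."""
        if self.kind == "single":
            body = self.tokens[0]
        else:
            body = self.tokens[0].ljust(_PAIR_PAD, ".") + self.tokens[1]
        return body.ljust(_RENDER_WIDTH, ".")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render


def pair_attributes(tokens: list[str]) -> list[Attribute]:
    """Unordered pair attributes of adjacent tokens: exactly ``len - 1``."""
    return [Attribute.pair(a, b) for a, b in zip(tokens, tokens[1:])]


def attribute_occurrences(tokens: list[str]) -> list[Attribute]:
    """All attribute occurrences of a token sequence (singles then pairs).

    Repeated attributes appear once per occurrence; descriptor and defect
    sums are per-occurrence.
    """
    return [Attribute.single(t) for t in tokens] + pair_attributes(tokens)


@dataclass
class AttributeStats:
    """Per-set compound counts for one attribute.

    Counts are numbers of *compounds* containing the attribute at least
    once, not total occurrences.
    """

    count_active: int = 0
    count_passive: int = 0
    count_calibration: int = 0
    count_validation: int = 0
    blocked: bool = False

    _FIELD = {
        "active": "count_active",
        "passive": "count_passive",
        "calibration": "count_calibration",
        "validation": "count_validation",
    }

    def count(self, label: str) -> int:
        return getattr(self, self._FIELD[label])

    def increment(self, label: str) -> None:
        f = self._FIELD[label]
        setattr(self, f, getattr(self, f) + 1)


@dataclass
class AttributeDictionary:
    """All attributes seen in a labeled dataset, with rarity blocking.

    An attribute occurring in fewer than ``threshold`` active-training
    compounds is *blocked* (rare): its correlation weight is pinned at zero
    and it never enters the optimization.
    """

    entries: dict[Attribute, AttributeStats] = field(default_factory=dict)
    threshold: int = 3
    set_sizes: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, attr: Attribute) -> bool:
        return attr in self.entries

    def __getitem__(self, attr: Attribute) -> AttributeStats:
        return self.entries[attr]

    def non_blocked(self) -> list[Attribute]:
        """Active (non-rare) attributes in deterministic sorted order."""
        return sorted(a for a, s in self.entries.items() if not s.blocked)

    def blocked(self) -> list[Attribute]:
        return sorted(a for a, s in self.entries.items() if s.blocked)


def build_attribute_dictionary(dataset, threshold: int) -> AttributeDictionary:
    """Collect every attribute in *dataset* with per-set compound counts.

    ``dataset`` is a :class:`~cwqsar.dataset.Dataset` whose records carry
    set labels; unassigned records contribute dictionary entries but no
    counts.  Blocking uses the active-training count only.
    """
    if threshold < 1:
        raise ConfigurationError(f"threshold T must be >= 1, got {threshold}")
    entries: dict[Attribute, AttributeStats] = {}
    set_sizes = {label: 0 for label in SET_LABELS}
    for record in dataset:
        if record.set_label in set_sizes:
            set_sizes[record.set_label] += 1
        present = set(attribute_occurrences(tokenize_smiles(record.smiles)))
        for attr in present:
            stats = entries.setdefault(attr, AttributeStats())
            if record.set_label in AttributeStats._FIELD:
                stats.increment(record.set_label)
    if set_sizes["active"] == 0:
        raise ConfigurationError(
            "no active-training compounds: cannot apply the rarity threshold"
        )
    for stats in entries.values():
        stats.blocked = stats.count_active < threshold
    return AttributeDictionary(entries, threshold, set_sizes)
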
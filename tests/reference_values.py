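"""Frozen reference values used across the test suite.

The worked descriptor example: a phenoxy-propionic-acid-like SMILES whose
published attribute decomposition (23 single fragments, 22 adjacent
pairs, with printed correlation weights) pins down the tokenizer rules:
``Cl`` is one fragment, all six parentheses normalize to ``(``, and pairs
are rendered with the lexicographically larger token first.
"""

WORKED_SMILES = "O=C(O)C(Oc1ccc(cc1C)Cl)C"

#: Tokens of WORKED_SMILES after ')' -> '(' normalization, in order.
WORKED_TOKENS = [
    "O", "=", "C", "(", "O", "(", "C", "(", "O", "c", "1", "c",
    "c", "c", "(", "c", "c", "1", "C", "(", "Cl", "(", "C",
]

#: Canonical (larger-token-first) adjacent pairs of WORKED_SMILES, in order.
WORKED_PAIR_SEQUENCE = [
    ("O", "="), ("C", "="), ("C", "("), ("O", "("), ("O", "("),
    ("C", "("), ("C", "("), ("O", "("), ("c", "O"), ("c", "1"),
    ("c", "1"), ("c", "c"), ("c", "c"), ("c", "("), ("c", "("),
    ("c", "c"), ("c", "1"), ("C", "1"), ("C", "("), ("Cl", "("),
    ("Cl", "("), ("C", "("),
]

#: Published per-attribute correlation weights of the worked example.
WORKED_SINGLE_WEIGHTS = {
    "O": -0.1599,
    "=": 0.1730,
    "C": -0.7553,
    "(": -0.7080,
    "c": -0.0266,
    "1": -0.1888,
    "Cl": 0.2129,
}
WORKED_PAIR_WEIGHTS = {
    ("O", "="): -0.4504,
    ("C", "="): -0.0745,
    ("C", "("): 1.1275,
    ("O", "("): -0.2548,
    ("c", "O"): -0.7650,
    ("c", "1"): 0.2256,
    ("c", "c"): -0.1935,
    ("c", "("): 0.2472,
    ("C", "1"): 0.6797,
    ("Cl", "("): 0.3294,
}

#: Published per-split validation statistics of the TF1 models (five
#: independent data splits): determination coefficient and RMSE.
TF1_VALIDATION_R2 = (0.8221, 0.7703, 0.7817, 0.7351, 0.7212)
TF1_VALIDATION_RMSE = (0.48, 0.45, 0.45, 0.47, 0.48)

#: Published (R2, n, F) triples of the one-descriptor calibration fits.
F_RATIO_CASES = (
    (0.719, 210, 532),
    (0.5556, 210, 260),
    (0.734, 210, 574),
)
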
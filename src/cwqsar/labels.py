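"""Set labels for the four-way data partition.

The training pool is structured into an *active* training set (the weights
are perturbed against it), a *passive* training set (a second, untouched
correlation check), and a *calibration* set (the model is tuned toward it
under the TF1 target function).  The *validation* set is never consulted
until final assessment.
"""

ACTIVE = "active"
PASSIVE = "passive"
CALIBRATION = "calibration"
VALIDATION = "validation"
UNASSIGNED = "unassigned"

#: The four partition blocks, in canonical order.
SET_LABELS = (ACTIVE, PASSIVE, CALIBRATION, VALIDATION)

#: Short codes accepted in the ``set`` column of input tables.
LABEL_ALIASES = {
    "A": ACTIVE,
    "P": PASSIVE,
    "C": CALIBRATION,
    "V": VALIDATION,
    ACTIVE: ACTIVE,
    PASSIVE: PASSIVE,
    CALIBRATION: CALIBRATION,
    VALIDATION: VALIDATION,
    UNASSIGNED: UNASSIGNED,
}

#: Codes written back out, inverse of the alias table.
LABEL_CODES = {ACTIVE: "A", PASSIVE: "P", CALIBRATION: "C", VALIDATION: "V"}
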
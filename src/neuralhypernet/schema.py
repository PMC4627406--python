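"""Cohort schema: the clinical-variable vocabulary of the pulmonary-embolism table.

The raw cohort is one row per patient and one column per clinical variable.
Twenty-six of the 28 columns are clinical indicators; ``ID`` identifies the
patient and ``Final diagnosis`` carries the physicians' conclusive call
(1 = pulmonary embolism confirmed, 0 = ruled out).  Missing entries are the
string/float ``NaN``.

Variable selection for the analysis drops

* ``ID`` (bookkeeping, not clinical);
* ``Troponin``, ``PAS``, ``PAD``, ``PAPS`` (redundant with other indicators,
  or almost entirely unobserved);
* ``Wells score``, ``Revised Geneva score``, ``Wicki score`` (clinical
  prediction rules already synthesising other variables plus physician
  judgement — keeping them would leak the very decision process the
  classifier is meant to replace);

and holds out ``Final diagnosis`` as the label, leaving 19 analysis variables.
"""

from __future__ import annotations

MISSING_SENTINEL = "NaN"

#: The 28 cohort columns, in canonical order.
ALL_COLUMNS: tuple[str, ...] = (
    "ID",
    "Age",
    "N_F_Pred",
    "N_F_Risk",
    "Previous DVT",
    "Palpitations",
    "Cough",
    "dDimer",
    "PAS",
    "PAD",
    "FC",
    "PAPS",
    "WBC",
    "Cancer at diagnosis",
    "Troponin",
    "Shockindex",
    "Cancer",
    "RVD",
    "Wells score",
    "Revised Geneva score",
    "Wicki score",
    "Dyspnea",
    "Chest pain",
    "PCO2",
    "PO2",
    "PH",
    "Hemoptysis",
    "Final diagnosis",
)

ID_COLUMN = "ID"
LABEL_COLUMN = "Final diagnosis"

#: Discarded because redundant or nearly unobserved.
REDUNDANT_VARIABLES: tuple[str, ...] = ("Troponin", "PAS", "PAD", "PAPS")

#: Clinical prediction rules, excluded from every feature matrix.
SCORE_VARIABLES: tuple[str, ...] = (
    "Wells score",
    "Revised Geneva score",
    "Wicki score",
)

#: The 19 analysis variables, in cohort-column order.
RETAINED_VARIABLES: tuple[str, ...] = tuple(
    c
    for c in ALL_COLUMNS
    if c not in (ID_COLUMN, LABEL_COLUMN) + REDUNDANT_VARIABLES + SCORE_VARIABLES
)

#: Variables that are plain 0/1 indicators in the raw table.
BOOLEAN_VARIABLES: tuple[str, ...] = (
    "Previous DVT",
    "Palpitations",
    "Cough",
    "Cancer at diagnosis",
    "Cancer",
    "RVD",
    "Dyspnea",
    "Chest pain",
    "Hemoptysis",
)


def descriptor_name(variable: str, polarity: int) -> str:
    """Name of the vertex (``polarity=1``) or antivertex (``polarity=0``)
    descriptor of *variable*, e.g. ``Age[1]``."""
    if polarity not in (0, 1):
        raise ValueError(f"polarity must be 0 or 1, got {polarity!r}")
    return f"{variable}[{polarity}]"


def descriptor_pair(variable: str) -> tuple[str, str]:
    """The ``(variable[0], variable[1])`` descriptor-column names."""
    return descriptor_name(variable, 0), descriptor_name(variable, 1)
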
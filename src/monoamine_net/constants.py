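"""Literature constants: rest firing rates, membrane-scale time constants,
and the lesion scalings used to derive per-subject target values.

Rates are in Hz.  Time constants are catalogued in milliseconds exactly as
tabulated in the electrophysiology literature and converted to SI seconds at
ingestion; everything downstream of this module works in seconds.
"""

from __future__ import annotations

#: Average activation frequency of each area in healthy (SHAM) animals, Hz.
REST_RATES_HZ: dict[str, float] = {
    "GP": 22.0,
    "StrD1": 10.0,
    "StrD2": 9.0,
    "SNcVTA": 4.47,
    "DRN": 1.41,
    "LC": 2.3,
}

#: Mean time constant per area, milliseconds (literature values).
TAU_MS: dict[str, float] = {
    "GP": 18.0,
    "StrD1": 2.0,
    "StrD2": 2.0,
    "SNcVTA": 1.5,
    "DRN": 3.3,
    "LC": 0.8,
}

#: Reported spread of the tabulated time constants, milliseconds.
TAU_JITTER_MS: float = 0.3

MS_PER_S: float = 1000.0


def tau_seconds(area: str) -> float:
    """Mean time constant of ``area`` in seconds."""
    return TAU_MS[area] / MS_PER_S


#: Multiplicative effect of each single lesion on the areas it was measured
#: in.  Areas not listed are unconstrained model predictions.
LESION_POINT_SCALES: dict[str, dict[str, float]] = {
    "LDA": {"GP": 1.0, "SNcVTA": 0.1, "LC": 0.8},
    "L5HT": {"GP": 0.65, "DRN": 0.3},
    "LNE": {"GP": 1.0, "LC": 0.2},
}

#: GP is only range-constrained in the combined lesions (prediction bands).
COMBINED_RANGE_SCALES: dict[str, dict[str, tuple[float, float]]] = {
    "LDA+L5HT": {"GP": (0.65, 0.75)},
    "LDA+LNE": {"GP": (0.65, 1.0)},
}

#: Ceiling used for "physically impossible" detection, Hz.  Firing rates are
#: also required to be non-negative.
F_MAX_HZ: float = 500.0
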
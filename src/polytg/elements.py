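"""Element data for the supported chemistry.

The descriptor set targets organic polymers; the supported element set is
restricted to the elements that occur in the functional-group census
(C, H, N, O, S, halogens, Si, P).  Anything else raises loudly rather than
silently producing a wrong valence delta.
"""

from __future__ import annotations

from .errors import UnsupportedElementError

# IUPAC standard atomic weights, conventional values to 3 decimals.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Br": 79.904,
}

# Valence-electron counts Zv and atomic numbers Z.
VALENCE_ELECTRONS: dict[str, int] = {
    "C": 4, "N": 5, "O": 6, "F": 7,
    "Si": 4, "P": 5, "S": 6, "Cl": 7, "Br": 7,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "C": 6, "N": 7, "O": 8, "F": 9,
    "Si": 14, "P": 15, "S": 16, "Cl": 17, "Br": 35,
}

SECOND_ROW = frozenset({"C", "N", "O", "F"})

SUPPORTED_ELEMENTS = frozenset(VALENCE_ELECTRONS)


def kier_hall_valence_delta(element: str, h_count: int) -> float:
    """Kier-Hall valence delta for a heavy atom.

    Second-row atoms: delta_v = Zv - h.
    Heavier atoms:    delta_v = (Zv - h) / (Z - Zv - 1).
    """
    if element not in SUPPORTED_ELEMENTS:
        raise UnsupportedElementError(
            f"element {element!r} is outside the supported set "
            f"{sorted(SUPPORTED_ELEMENTS)}"
        )
    zv = VALENCE_ELECTRONS[element]
    if element in SECOND_ROW:
        return float(zv - h_count)
    z = ATOMIC_NUMBERS[element]
    return (zv - h_count) / (z - zv - 1)
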
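"""Van der Waals radii (Å).

Bondi's consistent set for main-group elements; Pd uses 1.63 Å, the value
conventionally adopted for square-planar Pd(II) in cavity-size analysis of
metal-organic cages.
"""

from .errors import ValidationError

BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Br": 1.85,
    "I": 1.98,
    "Pd": 1.63,
    "Pt": 1.75,
}


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Return the vdW radius for *element*, raising if the table lacks it."""
    tab = BONDI_RADII if table is None else table
    try:
        return tab[element]
    except KeyError:
        raise ValidationError(
            f"no van der Waals radius defined for element {element!r}"
        ) from None
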
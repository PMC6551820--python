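"""Atomic masses and element inference from atom names."""
from __future__ import annotations

import warnings

# Standard atomic weights (amu), elements that occur in protein/lipid systems.
MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "ZN": 65.38,
    "FE": 55.845,
}

DEFAULT_MASS = 12.011


def mass_of(element: str) -> float:
    """Mass of *element* in amu; unknown elements get a carbon mass with a warning."""
    m = MASSES.get(element.strip().upper())
    if m is None:
        warnings.warn(
            f"unknown element {element!r}; assuming mass {DEFAULT_MASS}",
            stacklevel=2,
        )
        return DEFAULT_MASS
    return m


def element_from_name(name: str) -> str:
    """Infer the element symbol from an atom name such as 'CA', 'C22' or '1HB'.

    Protein/lipid atom names start with the element letter, possibly preceded
    by a digit (e.g. hydrogens '1HB').  Two-letter ions are not resolvable this
    way; this helper only targets the marker/backbone atoms used here.
    """
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")
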
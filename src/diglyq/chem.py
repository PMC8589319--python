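"""Elemental compositions and monoisotopic masses of peptide modifications.

A composition is a mapping from an element symbol to a signed integer count.
Heavy isotopes are written with a leading mass number (``"13C"``, ``"15N"``),
matching the stable-isotope labels used in TMT reagents and AQUA reference
peptides.  Monoisotopic atomic masses come from the NIST table shipped with
:mod:`pyteomics`.
"""

from __future__ import annotations

from typing import Dict, Mapping

from pyteomics import mass as _pmass

ElementalComposition = Dict[str, int]

_LIGHT_ELEMENTS = ("H", "C", "N", "O", "S", "P")
_ISOTOPES = {"13C": ("C", 13), "15N": ("N", 15)}


def _build_mass_table() -> Dict[str, float]:
    table = {el: _pmass.nist_mass[el][0][0] for el in _LIGHT_ELEMENTS}
    for label, (el, a) in _ISOTOPES.items():
        table[label] = _pmass.nist_mass[el][a][0]
    return table


#: Monoisotopic mass (Da) of every supported element symbol.
ELEMENT_MASS: Mapping[str, float] = _build_mass_table()


def monoisotopic_mass(composition: Mapping[str, int]) -> float:
    """Return the monoisotopic mass (Da) of an elemental composition.

    Counts may be negative (mass losses such as deamidation's ``H: -1``).

    Raises
    ------
    ValueError
        If a symbol is not one of H, C, N, O, S, P, 13C, 15N, or a count is
        not an integer.
    """
    total = 0.0
    for symbol, count in composition.items():
        if symbol not in ELEMENT_MASS:
            raise ValueError(f"unknown element symbol: {symbol!r}")
        if not isinstance(count, (int,)) or isinstance(count, bool):
            raise ValueError(f"count for {symbol!r} must be an integer, got {count!r}")
        total += count * ELEMENT_MASS[symbol]
    return total


#: Compositions of the modifications handled by the pipeline.
#: GlyGly is the remnant left on a ubiquitylated lysine after tryptic
#: digestion; the TMT label is the 10/11-plex isobaric reagent.
MODIFICATIONS: Mapping[str, ElementalComposition] = {
    "glygly": {"C": 4, "H": 6, "N": 2, "O": 2},
    "tmt": {"C": 8, "13C": 4, "H": 20, "N": 1, "15N": 1, "O": 2},
    "carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "oxidation": {"O": 1},
    "phospho": {"H": 1, "P": 1, "O": 3},
    "deamidation": {"H": -1, "N": -1, "O": 1},
}


def modification_mass(name: str) -> float:
    """Monoisotopic mass shift (Da) of a named modification."""
    try:
        comp = MODIFICATIONS[name]
    except KeyError:
        raise ValueError(f"unknown modification: {name!r}") from None
    return monoisotopic_mass(comp)
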
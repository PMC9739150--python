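"""Standard atomic weights (amu), keyed by element symbol.

Center-of-mass computations must work on plain coordinate files without a
force-field topology, so masses are looked up from this table rather than
taken from a parameter set. Values are IUPAC 2021 conventional weights.
"""

from __future__ import annotations

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}

#: Residue names that denote monoatomic ions, for which a two-letter atom
#: name like "CA" or "CL" really is the element (in amino acids "CA" is the
#: alpha carbon).
ION_RESNAMES = {
    "NA", "NA+", "SOD", "CL", "CL-", "CLA", "K", "K+", "POT",
    "MG", "MG2", "CA", "CA2", "CAL", "ZN", "ZN2", "FE", "FE2", "FE3",
}


def guess_element(name: str, residue_name: str = "") -> str:
    """Guess an element symbol from an atom name.

    Two-letter ion/metal symbols are only honoured when the residue itself
    is a monoatomic ion; otherwise the leading letter wins (``CA`` in a
    protein residue is carbon, not calcium).
    """
    stripped = "".join(ch for ch in name if ch.isalpha()).upper()
    if not stripped:
        raise ValueError(f"cannot derive an element from atom name {name!r}")
    if residue_name.strip().upper() in ION_RESNAMES and stripped[:2] in ATOMIC_MASSES:
        return stripped[:2]
    if stripped[0] in ATOMIC_MASSES:
        return stripped[0]
    if stripped[:2] in ATOMIC_MASSES:
        return stripped[:2]
    raise ValueError(f"cannot derive an element from atom name {name!r}")


def mass_of(element: str) -> float:
    """Standard atomic weight of ``element`` (case-insensitive)."""
    try:
        return ATOMIC_MASSES[element.strip().upper()]
    except KeyError:
        raise KeyError(
            f"element {element!r} has no entry in the standard atomic-weight table"
        ) from None
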
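"""Element classification tables used throughout the pipeline.

Covalent radii are the single-bond values of Cordero et al. (Dalton Trans.
2008, 2832), one radius per element (the carbon value is the sp3 one; with
the default 0.40 A offset it covers aromatic and double bonds as well).
"""

from __future__ import annotations

# fmt: off
SYMBOLS = [
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr", "Y", "Zr",
    "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd",
    "Pm", "Sm", "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb",
    "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir", "Pt", "Au", "Hg",
    "Tl", "Pb", "Bi", "Po", "At", "Rn", "Fr", "Ra", "Ac", "Th",
    "Pa", "U", "Np", "Pu", "Am", "Cm",
]
# fmt: on

ATOMIC_NUMBER = {s: i + 1 for i, s in enumerate(SYMBOLS)}

COVALENT_RADIUS = {
    "H": 0.31, "He": 0.28, "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76,
    "N": 0.71, "O": 0.66, "F": 0.57, "Ne": 0.58, "Na": 1.66, "Mg": 1.41,
    "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "Y": 1.90, "Zr": 1.75, "Nb": 1.64, "Mo": 1.54,
    "Tc": 1.47, "Ru": 1.46, "Rh": 1.42, "Pd": 1.39, "Ag": 1.45, "Cd": 1.44,
    "In": 1.42, "Sn": 1.39, "Sb": 1.39, "Te": 1.38, "I": 1.39, "Xe": 1.40,
    "Cs": 2.44, "Ba": 2.15, "La": 2.07, "Ce": 2.04, "Pr": 2.03, "Nd": 2.01,
    "Pm": 1.99, "Sm": 1.98, "Eu": 1.98, "Gd": 1.96, "Tb": 1.94, "Dy": 1.92,
    "Ho": 1.92, "Er": 1.89, "Tm": 1.90, "Yb": 1.87, "Lu": 1.87, "Hf": 1.75,
    "Ta": 1.70, "W": 1.62, "Re": 1.51, "Os": 1.44, "Ir": 1.41, "Pt": 1.36,
    "Au": 1.36, "Hg": 1.32, "Tl": 1.45, "Pb": 1.46, "Bi": 1.48, "Po": 1.40,
    "At": 1.50, "Rn": 1.50, "Fr": 2.60, "Ra": 2.21, "Ac": 2.15, "Th": 2.06,
    "Pa": 2.00, "U": 1.96, "Np": 1.90, "Pu": 1.87, "Am": 1.80, "Cm": 1.69,
}

#: Elements writable without brackets at a standard valence (OpenSMILES).
ORGANIC_SUBSET = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}

#: Standard valences per the OpenSMILES organic-subset rules.
STANDARD_VALENCES = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

#: Maximum valence reachable in the hypervalent oxoanion pass (perchlorate
#: Cl(VII), periodate I(VII), bromate...).  Only consulted for oxo centres.
HYPERVALENT_MAX = {"N": 5, "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
                   "As": 5, "Se": 6}

HALOGENS = {"F", "Cl", "Br", "I", "At"}
ALKALI = {"Li", "Na", "K", "Rb", "Cs", "Fr"}
ALKALINE_EARTH = {"Be", "Mg", "Ca", "Sr", "Ba", "Ra"}

#: d-block transition metals subject to the 2.85/3.0 A metal-metal window
#: (Z 21-30, 39-48, 72-80; La/Ac series excluded).
TRANSITION_METALS = {
    s for s, z in ATOMIC_NUMBER.items()
    if 21 <= z <= 30 or 39 <= z <= 48 or 72 <= z <= 80
}

_NONMETALS = {
    "H", "He", "B", "C", "N", "O", "F", "Ne", "Si", "P", "S", "Cl", "Ar",
    "As", "Se", "Br", "Kr", "Te", "I", "Xe", "At", "Rn", "Ge",
}

#: Everything treated as a metal by the bond model (incl. alkali, alkaline
#: earth, p-block metals, lanthanides/actinides).
METALS = {s for s in SYMBOLS if s not in _NONMETALS}

#: Central atoms recognised by the haloanion charge-redistribution step.
HALOANION_CENTERS = {"B", "P", "S", "As", "Al", "Bi", "Sn", "Si", "Sb"}


def is_element(symbol: str) -> bool:
    return symbol in ATOMIC_NUMBER


def normalize_element(symbol: str) -> str:
    """Map a CIF type symbol to a plain element symbol.

    Deuterium ("D") is treated as H; dummy atoms ("X", "Q") are rejected.
    """
    s = symbol.strip()
    # strip oxidation-state suffixes like "Cu2+" or "O1-"
    core = s.rstrip("0123456789+-")
    core = core[:1].upper() + core[1:].lower() if core else core
    if core == "D":
        return "H"
    if core in ATOMIC_NUMBER:
        return core
    raise ValueError(f"unknown element symbol: {symbol!r}")
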
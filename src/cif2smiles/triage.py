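"""Per-entry triage flags: Z', disorder, cross-unit bonds.

These three flags route an entry to the correct molecule-building
treatment; the fast path (Z' = 1, ordered, all listed bonds internal) can
skip symmetry reconstruction entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .cif import CrystalEntry

#: occupancies this close below 1.0 are treated as full (formatting noise)
OCC_TOL = 1e-6


@dataclass
class EntryFlags:
    zprime: Fraction
    zprime_class: str            # "sub_one" | "one" | "multi"
    disordered: bool
    cross_unit_bonds: bool
    polymer_dimension: int | None = None   # set only after molecule building

    @property
    def fast_path(self) -> bool:
        return (self.zprime_class == "one" and not self.disordered
                and not self.cross_unit_bonds)


def compute_zprime(z: int, n_general_positions: int) -> Fraction:
    """Z' = Z / (number of listed symmetry operators), exact."""
    if z < 1 or n_general_positions < 1:
        raise ValueError("z and n_general_positions must be >= 1")
    return Fraction(z, n_general_positions)


def classify_zprime(zprime: Fraction) -> str:
    if zprime < 1:
        return "sub_one"
    return "one" if zprime == 1 else "multi"


def flag_disorder(entry: CrystalEntry) -> bool:
    """True iff any site occupancy is strictly below one."""
    return any(site.occupancy < 1.0 - OCC_TOL for site in entry.sites)


def flag_cross_unit_bonds(entry: CrystalEntry) -> bool:
    """True iff a listed bond reaches outside the asymmetric unit."""
    return any(b.site_symmetry_2.strip() not in (".", "1_555")
               for b in entry.geom_bonds)


def triage(entry: CrystalEntry) -> EntryFlags:
    zp = compute_zprime(entry.z, len(entry.symops))
    return EntryFlags(
        zprime=zp,
        zprime_class=classify_zprime(zp),
        disordered=flag_disorder(entry),
        cross_unit_bonds=flag_cross_unit_bonds(entry),
    )
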
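"""Entry triage: Z' arithmetic and the three routing flags."""

from fractions import Fraction

import pytest

from cif2smiles.triage import (classify_zprime, compute_zprime, flag_disorder,
                               flag_cross_unit_bonds, triage)


@pytest.mark.parametrize("z,n,expected", [
    (4, 4, Fraction(1)), (2, 4, Fraction(1, 2)), (8, 4, Fraction(2)),
    (4, 192, Fraction(1, 48)), (3, 2, Fraction(3, 2)),
])
def test_zprime_exact(z, n, expected):
    assert compute_zprime(z, n) == expected


def test_zprime_exact_grid():
    for z in range(1, 13):
        for n in range(1, 13):
            zp = compute_zprime(z, n)
            assert zp == Fraction(z, n)
            cls = classify_zprime(zp)
            assert cls == ("sub_one" if z < n else
                           "one" if z == n else "multi")


def test_flags_on_fixtures(entries):
    f = triage(entries["pyrrole"])
    assert f.zprime == 1 and f.fast_path
    assert not f.disordered and not f.cross_unit_bonds

    f = triage(entries["disorder_two_site"])
    assert f.disordered

    f = triage(entries["hemihydrate"])
    assert f.cross_unit_bonds and f.zprime == 1

    f = triage(entries["special_position_trans"])
    assert f.zprime == Fraction(1, 2)
    assert f.zprime_class == "sub_one"

    f = triage(entries["zprime2"])
    assert f.zprime == 2 and f.zprime_class == "multi"

    f = triage(entries["nacl"])
    assert f.zprime == Fraction(4, 192)


def test_occupancy_strictness(entries):
    entry = entries["pyrrole"]
    assert not flag_disorder(entry)
    entry.sites[0].occupancy = 0.999
    try:
        assert flag_disorder(entry)
    finally:
        entry.sites[0].occupancy = 1.0
    entry.sites[0].occupancy = 1.0 - 1e-9      # formatting noise
    try:
        assert not flag_disorder(entry)
    finally:
        entry.sites[0].occupancy = 1.0


def test_cross_unit_codes(entries):
    assert not flag_cross_unit_bonds(entries["pyrrole"])
    assert flag_cross_unit_bonds(entries["hemihydrate"])


def test_triage_is_pure(entries):
    a = triage(entries["pyrrole"])
    b = triage(entries["pyrrole"])
    assert a == b
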
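"""CIF parsing, symmetry-operator arithmetic and P1 writing."""

import random
from fractions import Fraction

import numpy as np
import pytest

from cif2smiles.cif import (CifError, SymOp, UnitCell, fract_to_cartesian,
                            parse_cif, parse_symop, strip_su, write_p1_cif)

MINIMAL = """\
data_test
_cell_length_a 10.0
_cell_length_b 10.0
_cell_length_c 10.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_cell_formula_units_Z 1
loop_
_symmetry_equiv_pos_as_xyz
'x,y,z'
loop_
_atom_site_label
_atom_site_type_symbol
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
{occ_header}O1 O 0.1 0.2 0.3{occ_value}
"""


def test_su_stripping():
    assert strip_su("0.50(2)") == 0.5
    assert strip_su("1.234(5)") == 1.234
    assert strip_su("-3.2") == -3.2


def test_occupancy_su_and_default():
    text = MINIMAL.format(occ_header="_atom_site_occupancy\n",
                          occ_value=" 0.50(2)")
    entry = parse_cif(text)[0]
    assert entry.sites[0].occupancy == 0.5
    text = MINIMAL.format(occ_header="", occ_value="")
    entry = parse_cif(text)[0]
    assert entry.sites[0].occupancy == 1.0


def test_missing_z_is_an_error():
    text = MINIMAL.format(occ_header="", occ_value="").replace(
        "_cell_formula_units_Z 1\n", "")
    with pytest.raises(CifError, match="_cell_formula_units_Z"):
        parse_cif(text)


def test_unknown_element_rejected_deuterium_accepted():
    bad = MINIMAL.format(occ_header="", occ_value="").replace("O1 O", "X1 X")
    with pytest.raises(CifError, match="X1"):
        parse_cif(bad)
    deut = MINIMAL.format(occ_header="", occ_value="").replace("O1 O", "D1 D")
    assert parse_cif(deut)[0].sites[0].element == "H"


def test_nacl_fixture_sites_and_symops(entries):
    entry = entries["nacl"]
    assert len(entry.sites) == 2
    assert len(entry.symops) == 192


@pytest.mark.parametrize("jones,rot,trans", [
    ("x,y,z", np.eye(3), (0, 0, 0)),
    ("-x,-y,-z", -np.eye(3), (0, 0, 0)),
    ("-x,y+1/2,-z", np.diag([-1, 1, -1]), (0, Fraction(1, 2), 0)),
])
def test_parse_symop(jones, rot, trans):
    op = parse_symop(jones)
    assert np.array_equal(np.array(op.rotation), rot.astype(int))
    assert op.translation == tuple(Fraction(t) for t in trans)


def test_symop_apply_and_wrap():
    assert np.allclose(parse_symop("x,y,z").apply((0.1, 0.2, 0.3)),
                       (0.1, 0.2, 0.3))
    assert np.allclose(parse_symop("-x,-y,-z").apply((0.1, 0.2, 0.3),
                                                     wrap=True),
                       (0.9, 0.8, 0.7))
    assert np.allclose(parse_symop("x+1/2,y,z").apply((0.7, 0, 0),
                                                      wrap=True),
                       (0.2, 0, 0))


def test_symop_parse_errors():
    for bad in ("x,y", "x+y*z,y,z", "2x,y,z", "q,y,z"):
        with pytest.raises(CifError):
            parse_symop(bad)


try:
    from hypothesis import given, settings, strategies as st

    _perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1),
              (2, 1, 0)]

    @settings(derandomize=True, max_examples=200)
    @given(perm=st.sampled_from(_perms),
           signs=st.tuples(*[st.sampled_from((1, -1))] * 3),
           trans=st.tuples(*[st.integers(0, 11)] * 3))
    def test_symop_roundtrip_property(perm, signs, trans):
        """Jones-faithful serialization round-trips exactly."""
        rot = [[0] * 3 for _ in range(3)]
        for i in range(3):
            rot[i][perm[i]] = signs[i]
        op = SymOp(tuple(tuple(r) for r in rot),
                   tuple(Fraction(t, 12) for t in trans))
        assert parse_symop(op.to_jones()) == op
except ImportError:      # pragma: no cover - hypothesis is a test extra
    pass


def test_symop_serialize_roundtrip_random():
    rng = random.Random(42)
    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    for _ in range(1000):
        perm = rng.choice(perms)
        rot = [[0] * 3 for _ in range(3)]
        for i in range(3):
            rot[i][perm[i]] = rng.choice((1, -1))
        trans = tuple(Fraction(rng.randrange(12), 12) for _ in range(3))
        op = SymOp(tuple(tuple(r) for r in rot), trans)
        assert parse_symop(op.to_jones()) == op


def test_symop_closure_on_fixture_sets(entries):
    for name in ("nacl", "special_position_trans", "hemihydrate"):
        ops = entries[name].symops
        opset = {(op.rotation, op.translation) for op in ops}
        for a in ops[:20]:
            for b in ops[:20]:
                c = a.compose(b)
                assert (c.rotation, c.translation) in opset


def test_fract_to_cartesian():
    cubic = UnitCell(10, 10, 10, 90, 90, 90)
    assert np.allclose(fract_to_cartesian(cubic, (0.5, 0.5, 0.5)), (5, 5, 5))
    d = np.linalg.norm(fract_to_cartesian(cubic, (0.1, 0, 0))
                       - fract_to_cartesian(cubic, (0.2, 0, 0)))
    assert d == pytest.approx(1.0)
    mono = UnitCell(10, 10, 10, 90, 120, 90)
    cart = fract_to_cartesian(mono, (0, 0, 1))
    # beta=120 puts c at -5 along x with the a-along-x convention
    assert cart[0] == pytest.approx(-5.0)
    assert np.linalg.norm(cart) == pytest.approx(10.0)


def test_degenerate_cell_rejected():
    with pytest.raises(CifError):
        UnitCell(10, 10, 10, 10, 10, 170)


def test_p1_roundtrip(entries):
    entry = entries["pyrrole"]

    class Row:
        def __init__(self, s):
            self.label, self.element, self.fract = s.label, s.element, s.fract
            self.occupancy = s.occupancy

    text = write_p1_cif("rt", [Row(s) for s in entry.sites], entry.cell)
    back = parse_cif(text)[0]
    assert len(back.sites) == len(entry.sites)
    assert [s.label for s in back.sites] == [s.label for s in entry.sites]
    for a, b in zip(back.sites, entry.sites):
        assert np.allclose(a.fract, b.fract, atol=1e-9)
    empty = write_p1_cif("empty", [], entry.cell)
    assert parse_cif(empty)[0].sites == []
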
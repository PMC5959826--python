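"""Discrepancy taxonomy classification."""

import pytest

from cif2smiles.compare import (DiscrepancyCategory as D,
                                classify_discrepancy, summarize)


@pytest.mark.parametrize("s", [
    "CCO", "c1ccccc1", "[Na+].[Cl-]", "C[C@H](N)C(=O)O",
    "[Ni](C#[O])(C#[O])(C#[O])C#[O]",
])
def test_self_is_identical(s):
    assert classify_discrepancy(s, s) == D.identical


def test_isomorphic_strings_identical():
    assert classify_discrepancy("OCC", "CCO") == D.identical


def test_nitro_pair():
    ours = "CCN(=O)=O"
    other = "CC[N+](=O)[O-]"
    assert classify_discrepancy(ours, other) == D.nitro_representation


def test_racemate_pair():
    one = "C[C@H](O)[C@@H](N)F"
    from cif2smiles.smiles import invert_stereo_marks
    two = one + "." + invert_stereo_marks(one)
    assert classify_discrepancy(two, one) == D.racemate_representation


def test_explicit_h_difference():
    # imidazole-like tautomeric H placement on ring nitrogens
    assert classify_discrepancy("c1ccc[nH]1", "c1ccc[n]1") == \
        D.different_explicit_H_count


def test_missing_chirality_direction():
    assert classify_discrepancy("C[C@H](N)C(=O)O",
                                "CC(N)C(=O)O") == D.missing_chirality_in_other
    assert classify_discrepancy("CC(N)C(=O)O",
                                "C[C@H](N)C(=O)O") == D.missing_chirality_in_ours


def test_chiral_config_differs():
    assert classify_discrepancy("C[C@H](O)[C@@H](N)F",
                                "C[C@H](O)[C@H](N)F") == D.chiral_config_differs


def test_charge_settings():
    assert classify_discrepancy("CC(=O)[O-]", "CC(=O)O") in (
        D.charge_settings, D.different_explicit_H_count)


def test_aromaticity_settings():
    assert classify_discrepancy("c1ccc[cH-]1", "C1=CC=C[CH-]1") == \
        D.aromaticity_settings


def test_bond_orders():
    assert classify_discrepancy("CC=CC=C", "CC=CC-C".replace("-", "")) == \
        D.bond_orders


def test_ring_count():
    assert classify_discrepancy("C1CCCCC1", "CCCCCC") == D.ring_count


def test_moiety_count():
    assert classify_discrepancy("CCO.O", "OCCO") == D.moiety_count


def test_connectivity():
    assert classify_discrepancy("CCCO", "CC(C)O") == D.different_connectivity


def test_missing_c():
    assert classify_discrepancy("CCCO", "CCO") == D.missing_C_in_other
    assert classify_discrepancy("CCO", "CCCO") == D.missing_C_in_ours


def test_stoichiometry_vs_composition():
    assert classify_discrepancy("CCO.CCO", "CCO") == D.stoichiometry
    assert classify_discrepancy("CCO", "CCN") == D.chemical_composition


def test_parse_failure_is_other():
    assert classify_discrepancy("C1CC", "CCO") == D.other_reason


def test_severity_monotonicity():
    """Injecting a composition change never lowers the category."""
    pairs = [("CCO", "CCO"), ("CCN(=O)=O", "CC[N+](=O)[O-]"),
             ("C[C@H](N)C(=O)O", "CC(N)C(=O)O")]
    for ours, other in pairs:
        base = classify_discrepancy(ours, other)
        injected = classify_discrepancy(ours, other + ".[Se]")
        assert injected >= base


def test_summarize():
    df = summarize([])
    assert df["count"].sum() == 0
    df = summarize([D.identical, D.identical, D.chemical_composition,
                    D.chemical_composition])
    row = df.set_index("category")
    assert row.loc["identical", "percent"] == 50.0
    assert row.loc["chemical_composition", "percent"] == 50.0
    df = summarize([D.identical] * 5)
    assert df.set_index("category").loc["identical", "percent"] == 100.0
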
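"""Fixture catalog integrity and geometry self-consistency."""

import numpy as np
import pytest

from cif2smiles.bonds import BondPolicy, perceive_bonds
from cif2smiles.cif import parse_cif
from cif2smiles.fixtures import build_fixture, catalog
from cif2smiles.smiles import parse_smiles
from cif2smiles.triage import triage


def test_catalog_deterministic():
    assert catalog() == catalog()
    a = build_fixture("pyrrole").cif_text
    b = build_fixture("pyrrole").cif_text
    assert a == b


def test_catalog_minimum_contents():
    names = set(catalog())
    required = {"pyrrole", "thiophene", "cyclopentadiene",
                "cyclopentadienone", "pyridone2", "uracil", "quinone",
                "anthraquinone", "caffeine", "en_ni", "zn_aqua",
                "co_phenolate", "cu_py2cl2", "mn_imidazole",
                "mn_imidazolate", "cd_acetate", "gd_acac", "ni_co4",
                "co2_bridged", "pb_et4", "pd_allyl", "ferrocene",
                "carborane", "nacl", "cu_metal", "crown_k", "pf6_salt",
                "disorder_two_site", "hemihydrate",
                "special_position_trans", "zprime2", "chain_1d", "sheet_2d",
                "sohncke_single", "racemic_two", "meso"}
    assert required <= names


def test_every_fixture_parses_and_triages():
    for name in catalog():
        fx = build_fixture(name)
        entry = parse_cif(fx.cif_text)[0]
        flags = triage(entry)
        assert flags.zprime > 0, name
        if fx.expected_smiles is not None:
            parse_smiles(fx.expected_smiles)


def test_tags_cover_pipeline_branches():
    tags = set()
    for name in catalog():
        tags |= build_fixture(name).tags
    assert {"aromatic", "coordination", "carbonyl", "borane", "metallocene",
            "ionic", "disorder", "special_position", "zprime2", "polymer_1d",
            "racemic", "sohncke", "meso", "haloanion"} <= tags


def test_no_accidental_contacts():
    """All intended chemistry is local: no bond between moiety atoms and
    the far-apart counter-ion placements."""
    fx = build_fixture("pf6_salt")
    entry = parse_cif(fx.cif_text)[0]

    class P:
        def __init__(self, s, cell):
            self.element = s.element
            self.cart = cell.orthogonalization_matrix() @ s.fract

    atoms = [P(s, entry.cell) for s in entry.sites]
    pairs = perceive_bonds(atoms)
    import networkx as nx
    g = nx.Graph(pairs)
    g.add_nodes_from(range(len(atoms)))
    comps = list(nx.connected_components(g))
    assert len(comps) == 2       # PF6 and NMe4 stay separate


def test_metallocene_tag_exists():
    fx = build_fixture("ferrocene")
    assert "metallocene" in fx.tags
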
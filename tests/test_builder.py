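"""Molecule building: expansion, disorder, stoichiometry, polymers."""

import numpy as np
import pytest

from cif2smiles.bonds import BondPolicy
from cif2smiles.builder import (build_molecule, expand_to_p1,
                                infer_missing_hydrogens, p1_cell_contents,
                                select_disorder, UnsupportedPolymerError)
from cif2smiles.canon import canonical_form
from cif2smiles.cif import parse_cif
from cif2smiles.smiles import GraphAtom, MolecularGraph
from cif2smiles.triage import triage


def test_isolated_molecule_expansion_is_identity(entries):
    entry = entries["pyrrole"]
    placements, translations = expand_to_p1(entry, flags=triage(entry))
    assert len(placements) == len(entry.sites)
    assert translations == []


def test_special_position_completes_molecule(entries):
    entry = entries["special_position_trans"]
    placements, translations = expand_to_p1(entry, flags=triage(entry))
    # full molecule = 2 x asymmetric unit - shared Cu
    assert len(placements) == 2 * len(entry.sites) - 1
    assert translations == []


def test_expansion_site_order_invariance(entries):
    entry = entries["special_position_trans"]
    base = build_molecule(entry)
    base_smiles = ".".join(m.canonical for m in base.moieties)
    import copy
    shuffled = copy.deepcopy(entry)
    shuffled.sites = shuffled.sites[::-1]
    alt = build_molecule(shuffled)
    assert ".".join(m.canonical for m in alt.moieties) == base_smiles


def test_disorder_group_selection(entries):
    entry = entries["disorder_two_site"]
    placements, _ = expand_to_p1(entry, flags=triage(entry))
    kept, log = select_disorder(placements, entry)
    groups = {p.disorder_group for p in kept}
    assert groups == {None, "1"}
    assert any("kept group 1" in line for line in log)


def test_disorder_tie_break_is_lexicographic():
    class Site:
        pass

    placements = []
    for group, occ in (("2", 0.5), ("1", 0.5)):
        p = type("P", (), {})()
        p.disorder_group = group
        p.disorder_assembly = "A"
        p.occupancy = occ
        placements.append(p)
    kept, _ = select_disorder(placements, None)
    assert [p.disorder_group for p in kept] == ["1"]


def test_low_occupancy_moiety_dropped():
    text = None
    from cif2smiles.fixtures import Mol, make_cif
    mol = Mol()
    mol.add("C", (0, 0, 0))
    for k, h in enumerate(((1.09, 0, 0), (-0.36, 1.03, 0),
                           (-0.36, -0.51, 0.89), (-0.36, -0.51, -0.89))):
        mol.add("H", h)
    mol.add("Xe", (6.0, 0, 0), occ=0.05, group="1")
    text = make_cif("lowocc", mol, a=20.0)
    entry = parse_cif(text)[0]
    built = build_molecule(entry)
    elements = {a.element for a in built.graph.atoms}
    assert "Xe" not in elements


def test_water_inference():
    g = MolecularGraph()
    g.add_atom(GraphAtom("O"))
    log = infer_missing_hydrogens(g, counter_ion_context=False)
    assert g.atoms[0].explicit_h == 2 and log


def test_hydroxyl_inference_distance_rule():
    for d, expected_h in ((1.43, 1), (1.22, 0)):
        g = MolecularGraph()
        g.add_atom(GraphAtom("C", explicit_h=3,
                             cart=np.array([0.0, 0.0, 0.0])))
        g.add_atom(GraphAtom("O", cart=np.array([d, 0.0, 0.0])))
        g.add_bond(0, 1, 1)
        infer_missing_hydrogens(g, counter_ion_context=False)
        assert g.atoms[1].explicit_h == expected_h, d


def test_hemihydrate_multiplicities(pipeline_results):
    res = pipeline_results["hemihydrate"]
    mults = sorted((m.canonical, m.multiplicity) for m in res.built.moieties)
    assert [m for _, m in mults] == [1, 1]
    assert res.record.smiles.count(".") == 1


def test_zprime2_reduced(pipeline_results):
    res = pipeline_results["zprime2"]
    assert len(res.built.moieties) == 1
    assert res.built.moieties[0].multiplicity == 1


def test_polymer_dimensions(entries):
    entry = entries["nacl"]
    placements, translations = expand_to_p1(entry, flags=triage(entry))
    assert np.linalg.matrix_rank(np.array(translations)) == 3
    entry = entries["chain_1d"]
    _, translations = expand_to_p1(entry, flags=triage(entry))
    assert np.linalg.matrix_rank(np.array(translations)) == 1


def test_chain_extended_once(pipeline_results):
    res = pipeline_results["chain_1d"]
    assert res.built.moieties[0].is_polymer_fragment
    assert len(res.built.moieties[0].atom_indices) == 4   # unit doubled


def test_sheet_is_unsupported(entries):
    from cif2smiles.pipeline import ConversionError, run_entry
    with pytest.raises(ConversionError) as err:
        run_entry(entries["sheet_2d"])
    assert err.value.stage == "molecule"


def test_stoichiometry_proportional_to_p1(entries, pipeline_results,
                                          fixture_set):
    """Reduced moiety element ratios match the full P1 cell contents
    (excluding rounded solvents and inferred H) on non-disordered fixtures."""
    from cif2smiles.builder import SOLVENT_SMILES, _solvent_set
    solvents = _solvent_set()
    for name, res in pipeline_results.items():
        if isinstance(res, Exception) or res.built is None:
            continue
        tags = fixture_set[name].tags
        if tags & {"disorder", "polymer_1d", "ionic", "solvent"}:
            continue
        counts: dict[str, int] = {}
        g = res.built.graph
        for m in res.built.moieties:
            if m.canonical in solvents:
                continue
            for i in m.atom_indices:
                el = g.atoms[i].element
                counts[el] = counts.get(el, 0) + m.multiplicity
        if not counts:          # all-solvent entry: nothing to compare
            continue
        cell = p1_cell_contents(entries[name])
        cell.pop("H", None)
        ratios = set()
        for el, n in counts.items():
            assert el in cell, (name, el)
            ratios.add(cell[el] / n)
        assert len(ratios) == 1, (name, counts, cell)


def test_nacl_and_metal(pipeline_results):
    assert pipeline_results["nacl"].record.smiles == canonical_form(
        "[Na+].[Cl-]")
    assert pipeline_results["cu_metal"].record.smiles == "[Cu]"
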
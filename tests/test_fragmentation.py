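"""Cleaving, conjugate caps and link-hydrogen placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pymfcc import CapScheme, cleave_and_cap, fragment_model, place_link_hydrogen
from pymfcc.errors import FragmentationError, GeometryError
from pymfcc.structure import Atom, Residue, StructureModel


def _atom(i, element, coords, key=("A", 1)):
    return Atom(id=i, element=element, name=element, coords=np.array(coords, float),
                residue_key=key)


def test_link_hydrogen_colinear_examples():
    scheme = CapScheme()
    n = _atom(0, "N", [0, 0, 0])
    c = _atom(1, "C", [1.33, 0, 0])
    h = place_link_hydrogen(n, c, scheme)
    assert np.allclose(h.coords, [1.01, 0, 0], atol=1e-12)
    h2 = place_link_hydrogen(c, _atom(2, "N", [1.33, 1.33, 0]), scheme)
    assert np.allclose(h2.coords, [1.33, 1.09, 0], atol=1e-12)
    assert h.partial_charge == scheme.link_h_charge and h.is_link


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    kept=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    direction=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
    element=st.sampled_from(["N", "C", "S"]),
)
def test_link_hydrogen_length_and_direction(kept, direction, element):
    d = np.array(direction)
    if np.linalg.norm(d) < 1e-3:
        return
    scheme = CapScheme()
    kept_atom = _atom(0, element, kept)
    removed = _atom(1, "C", np.array(kept) + 1.4 * d / np.linalg.norm(d))
    h = place_link_hydrogen(kept_atom, removed, scheme)
    length = {"N": 1.01, "C": 1.09, "S": 1.34}[element]
    assert np.linalg.norm(h.coords - kept_atom.coords) == pytest.approx(length, abs=1e-9)
    cos = np.dot(
        h.coords - kept_atom.coords, removed.coords - kept_atom.coords
    ) / (length * 1.4)
    assert cos == pytest.approx(1.0, abs=1e-9)


def test_coincident_atoms_rejected():
    with pytest.raises(GeometryError):
        place_link_hydrogen(_atom(0, "N", [1, 2, 3]), _atom(1, "C", [1, 2, 3]), CapScheme())


def test_scheme_validation():
    with pytest.raises(ValueError):
        CapScheme(nh_bond_length=2.5)
    with pytest.raises(ValueError):
        CapScheme(cap_extent="everything")


def test_interior_residue_quadruple_invariants(toy10):
    model, _ = toy10
    res = model.residues[4]
    quad = cleave_and_cap(model, res.key)

    # capped-residue atoms identical between the two CRC systems
    crc_ids = [a.id for a in quad.sys_crc.atoms]
    l_crc_ids = [a.id for a in quad.sys_l_crc.atoms if a.residue_key != ("LIG", 0)]
    assert crc_ids == l_crc_ids
    for a, b in zip(quad.sys_crc.atoms, quad.sys_l_crc.atoms):
        assert a is b  # shared by reference ⇒ bit-identical coordinates

    # caps-plus-link-H identical between the two CC systems
    cc_ids = [a.id for a in quad.sys_cc.atoms]
    l_cc_ids = [a.id for a in quad.sys_l_cc.atoms if a.residue_key != ("LIG", 0)]
    assert cc_ids == l_cc_ids

    # ligand atoms identical between the two ligand systems
    lig_a = [a.id for a in quad.sys_l_crc.atoms if a.residue_key == ("LIG", 0)]
    lig_b = [a.id for a in quad.sys_l_cc.atoms if a.residue_key == ("LIG", 0)]
    assert lig_a == lig_b == model.ligand.atom_ids

    # link-H bookkeeping: cc has the crc hydrogens plus one per cap–R cut
    assert len(quad.link_hydrogens["cc"]) == len(quad.link_hydrogens["crc"]) + 2
    assert [h.id for h in quad.link_hydrogens["l_crc"]] == [
        h.id for h in quad.link_hydrogens["crc"]
    ]
    assert [h.id for h in quad.link_hydrogens["l_cc"]] == [
        h.id for h in quad.link_hydrogens["cc"]
    ]


def test_terminal_residues_have_single_cap(toy10):
    model, _ = toy10
    first = cleave_and_cap(model, model.residues[0].key)
    keys = {a.residue_key for a in first.sys_crc.atoms if not a.is_link}
    assert keys == {model.residues[0].key, model.residues[1].key}
    # one distal cut in crc, plus one cap–R cut in cc
    assert len(first.link_hydrogens["crc"]) == 1
    assert len(first.link_hydrogens["cc"]) == 2


def test_every_cut_bond_capped_once(toy10):
    model, _ = toy10
    quad = cleave_and_cap(model, model.residues[3].key)
    for name, system in quad.systems().items():
        frag_ids = {a.id for a in system.atoms if not a.is_link
                    and a.residue_key != ("LIG", 0)}
        cut = sum(
            1
            for i in frag_ids
            for j in model.bonds[i]
            if j not in frag_ids and j not in model.ligand.atom_ids
        )
        assert cut == len(quad.link_hydrogens[name])


def test_fragmenting_all_residues_partitions_receptor(toy10):
    model, _ = toy10
    quads = list(fragment_model(model))
    assert len(quads) == len(model.residues)
    seen: list[int] = []
    for quad, res in zip(quads, model.residues):
        ids = [
            a.id for a in quad.sys_crc.atoms
            if not a.is_link and a.residue_key == res.key
        ]
        assert sorted(ids) == sorted(res.atom_ids)
        seen.extend(ids)
    assert sorted(seen) == sorted(model.receptor_atom_ids())


def test_ligand_cannot_be_fragmented(toy10):
    model, _ = toy10
    with pytest.raises(FragmentationError):
        cleave_and_cap(model, ("LIG", 0))


def test_isolated_residue_warns_with_empty_caps():
    atoms = {
        0: _atom(0, "N", [0, 0, 0]),
        1: _atom(1, "C", [1.4, 0, 0]),
    }
    model = StructureModel(atoms, [Residue("A", 1, "GLY", [0, 1])], None)
    model.perceive_bonds()
    with pytest.warns(UserWarning, match="no neighbours"):
        quad = cleave_and_cap(model, ("A", 1))
    assert quad.sys_cc.atoms == []


def _disulfide_model():
    """Two chains whose CYS residues are disulfide-bonded across chains."""
    atoms, residues = {}, []
    layout = [
        ("A", 1, "CYS", {"N": [0, 0, 0], "CA": [1.45, 0, 0], "C": [2.0, 1.4, 0],
                         "CB": [1.45, -1.5, 0], "SG": [1.45, -3.3, 0]}),
        ("A", 2, "GLY", {"N": [3.33, 1.4, 0], "CA": [4.78, 1.4, 0],
                         "C": [5.33, 2.8, 0]}),
        ("B", 1, "CYS", {"N": [0.0, -8.65, 0], "CA": [1.45, -8.65, 0],
                         "C": [2.35, -9.8, 0], "CB": [1.45, -7.15, 0],
                         "SG": [1.45, -5.35, 0]}),
    ]
    i = 0
    for chain, seq, name, atom_map in layout:
        res = Residue(chain, seq, name)
        for aname, xyz in atom_map.items():
            atoms[i] = Atom(id=i, element=aname[0], name=aname,
                            coords=np.array(xyz, float), residue_key=(chain, seq))
            res.atom_ids.append(i)
            i += 1
        residues.append(res)
    model = StructureModel(atoms, residues, None)
    model.perceive_bonds()
    model.link_residue_neighbors()
    sg1 = next(a for a in atoms.values() if a.name == "SG" and a.residue_key == ("A", 1))
    sg3 = next(a for a in atoms.values() if a.name == "SG" and a.residue_key == ("B", 1))
    assert sg3.id in model.bonds[sg1.id], "fixture should perceive the S-S bond"
    return model


def test_disulfide_cut_and_capped_at_sulfur():
    model = _disulfide_model()
    quad = cleave_and_cap(model, ("A", 1), CapScheme(cut_disulfides=True))
    # the S-S cut is terminated on SG at the S-H bond length
    sg = next(a for a in quad.sys_crc.atoms if a.name == "SG" and not a.is_link)
    sh = [h for h in quad.link_hydrogens["crc"]
          if np.linalg.norm(h.coords - sg.coords) < 1.5]
    assert len(sh) == 1
    assert np.linalg.norm(sh[0].coords - sg.coords) == pytest.approx(1.34, abs=1e-9)


def test_disulfide_cut_refused_when_disabled():
    model = _disulfide_model()
    with pytest.raises(FragmentationError, match="disulfide"):
        cleave_and_cap(model, ("A", 1), CapScheme(cut_disulfides=False))


def test_backbone_only_caps_are_smaller(toy10):
    model, _ = toy10
    res = model.residues[4]
    whole = cleave_and_cap(model, res.key, CapScheme())
    slim = cleave_and_cap(model, res.key, CapScheme(cap_extent="backbone_only"))
    assert len(slim.sys_crc.atoms) <= len(whole.sys_crc.atoms)
    own = [a for a in slim.sys_crc.atoms if a.residue_key == res.key and not a.is_link]
    assert sorted(a.id for a in own) == sorted(res.atom_ids)
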
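"""Per-residue driver: distances, sweep, convergence, ranking, regions."""

import numpy as np
import pandas as pd
import pytest

from pymfcc import (
    ClassicalBackend,
    RegionMap,
    ToyComplexSpec,
    aggregate_regional_energies,
    assign_region,
    cleave_and_cap,
    detect_convergence,
    generate_toy_complex,
    mfcc_residue_energy,
    radius_schedule,
    radius_sweep,
    rank_residues,
    residue_min_distance,
)
from pymfcc.analysis import ResidueEnergyRecord
from pymfcc.errors import SelectionError
from pymfcc.synthetic import TOY_REGIONS

from conftest import make_point_charge_model


# ---------------------------------------------------------------------------
# distances


def test_min_distance_matches_exhaustive_scan(toy10):
    model, _ = toy10
    lig = model.ligand_atoms()
    for res in model.residues:
        d, _, _ = residue_min_distance(model, res.key)
        brute = min(
            np.linalg.norm(a.coords - b.coords)
            for a in model.residue_atoms(res.key)
            for b in lig
        )
        assert d == pytest.approx(brute, abs=1e-12)


def test_min_distance_simple_and_tie_break():
    model = make_point_charge_model(
        positions=[[3, 0, 0], [5, 0, 0], [0, 0, 0]],
        charges=[0.0, 0.0, 0.0],
        ligand_idx=(0, 1),
    )
    d, res_atom, lig_atom = residue_min_distance(model, ("A", 1))
    assert d == pytest.approx(3.0)
    assert lig_atom == "X0"  # nearer ligand atom, not the one at 5 Å

    # exact tie: two ligand atoms at the same distance → lowest id wins
    tie = make_point_charge_model(
        positions=[[3, 0, 0], [-3, 0, 0], [0, 0, 0]],
        charges=[0.0, 0.0, 0.0],
        ligand_idx=(0, 1),
    )
    _, _, lig_atom = residue_min_distance(tie, ("A", 1))
    assert lig_atom == "X0"


def test_min_distance_hydrogen_toggle(toy10):
    model, _ = toy10
    key = model.residues[0].key
    with_h, _, _ = residue_min_distance(model, key, include_hydrogens=True)
    heavy, _, _ = residue_min_distance(model, key, include_hydrogens=False)
    assert with_h <= heavy


def test_radius_schedule():
    radii = radius_schedule(10.0, 0.5)
    assert len(radii) == 20 and radii[0] == 0.5 and radii[-1] == 10.0
    assert np.allclose(np.diff(radii), 0.5)
    assert list(radius_schedule(1.0, 0.5)) == [0.5, 1.0]
    assert list(radius_schedule(0.5, 0.5)) == [0.5]
    with pytest.raises(ValueError):
        radius_schedule(0.4, 0.5)
    with pytest.raises(ValueError):
        radius_schedule(10.0, -1.0)


# ---------------------------------------------------------------------------
# the four-term combination


class _StubBackend:
    def __init__(self, values):
        self.values = values

    def evaluate(self, system):
        return self.values[system.label.split("/")[-1]]

    @property
    def metadata(self):
        return {"backend": "stub", "epsilon": None}


def test_four_term_arithmetic(toy10):
    model, _ = toy10
    quad = cleave_and_cap(model, model.residues[1].key)
    stub = _StubBackend({"l_crc": 10.0, "l_cc": 4.0, "crc": 3.0, "cc": 1.0})
    assert mfcc_residue_energy(quad, stub) == pytest.approx(4.0)


def test_energy_vanishes_for_distant_ligand(toy10):
    model, _ = toy10
    backend = ClassicalBackend(40.0)
    shift = np.array([1.0e7, 0.0, 0.0])
    for i in model.ligand.atom_ids:
        model.atoms[i].coords = model.atoms[i].coords + shift
    try:
        for res in model.residues[:3]:
            quad = cleave_and_cap(model, res.key)
            assert abs(mfcc_residue_energy(quad, backend)) < 1e-6
    finally:
        for i in model.ligand.atom_ids:
            model.atoms[i].coords = model.atoms[i].coords - shift


# ---------------------------------------------------------------------------
# sweep


@pytest.fixture(scope="module")
def sweep12():
    model, truth = generate_toy_complex(ToyComplexSpec(seed=3, n_residues=12))
    region_map = RegionMap(TOY_REGIONS)
    sweep = radius_sweep(model, ClassicalBackend(40.0), region_map=region_map)
    return model, truth, sweep


def test_sweep_inclusion_follows_min_distance(sweep12):
    _, truth, sweep = sweep12
    dist = {t.residue_key: t.min_distance for t in truth}
    for r, keys in zip(sweep.radii, sweep.included_residues):
        expected = {k for k, d in dist.items() if d <= r}
        assert set(keys) == expected


def test_sweep_sets_nested_and_cumulative_consistent(sweep12):
    _, _, sweep = sweep12
    for a, b in zip(sweep.included_residues, sweep.included_residues[1:]):
        assert set(a) <= set(b)
    for keys, energy in zip(sweep.included_residues, sweep.cumulative_energy):
        total = sum(r.energy for r in sweep.records if r.residue_key in set(keys))
        assert energy == pytest.approx(total, abs=1e-9)
    assert sweep.total_energy == pytest.approx(
        sum(r.energy for r in sweep.records), abs=1e-9
    )


def test_sweep_frames_and_summary(sweep12):
    _, _, sweep = sweep12
    frame = sweep.to_frame()
    assert list(frame.columns) == ["radius", "n_residues", "cumulative_energy"]
    assert len(frame) == len(sweep.radii)
    assert "total energy" in sweep.summary()


# ---------------------------------------------------------------------------
# convergence


@pytest.mark.parametrize(
    "energies,expected_index",
    [
        ([-5.0, -5.0, -5.0, -5.0], 1),  # constant series → second radius
        ([-10.0, -30.0, -33.0, -33.5], 2),  # 3/33 ≈ 9.1% then 1.5%
        ([-10.0, -10.5, -30.0, -31.0], 3),  # early dip does not count
        ([0.0, 0.0, 0.0], 1),  # zero total with zero change is stable
    ],
)
def test_convergence_rule(energies, expected_index):
    radii = 0.5 * np.arange(1, len(energies) + 1)
    assert detect_convergence((radii, energies)) == pytest.approx(radii[expected_index])


def test_convergence_zero_total_with_change_is_not_convergent():
    radii = [0.5, 1.0, 1.5]
    assert detect_convergence((radii, [-5.0, 0.0, 0.0])) == pytest.approx(1.5)
    assert detect_convergence((radii, [-5.0, 5.0, 0.0])) is None


def test_convergence_never_reached():
    radii = [0.5, 1.0, 1.5, 2.0]
    assert detect_convergence((radii, [-1.0, -2.0, -4.0, -8.0])) is None
    with pytest.raises(ValueError):
        detect_convergence(([0.5], [-1.0]))


# ---------------------------------------------------------------------------
# ranking and regions


def _record(label, num, energy, region=None, closest="N"):
    return ResidueEnergyRecord(
        residue_key=("A", num), label=label, energy=energy, min_distance=3.0,
        closest_residue_atom="CA", closest_ligand_atom=closest, region=region,
    )


def test_ranking_most_attractive_first():
    records = [
        _record("MET292", 292, 1.40),
        _record("ASP106", 106, -8.32),
        _record("VAL107", 107, -4.50),
    ]
    assert [r.label for r in rank_residues(records)] == ["ASP106", "VAL107", "MET292"]


def test_ranking_ties_by_residue_number_and_empty_rejected():
    records = [_record("B2", 2, -1.0), _record("A1", 1, -1.0)]
    assert [r.label for r in rank_residues(records)] == ["A1", "B2"]
    with pytest.raises(ValueError):
        rank_residues([])


def test_assign_region_direct_and_hydrogen_delegation(toy10):
    model, _ = toy10
    region_map = RegionMap(TOY_REGIONS)
    region_map.validate_partition(model)
    rec = _record("X", 1, -1.0, closest="N")
    assert assign_region(rec, region_map, model) == "ii"
    # a closest amine hydrogen maps to its bonded nitrogen's region
    rec_h = _record("X", 1, -1.0, closest="HN2")
    assert assign_region(rec_h, region_map, model) == "ii"
    rec_oh = _record("X", 1, -1.0, closest="HO")
    assert assign_region(rec_oh, region_map, model) == "i"
    with pytest.raises(SelectionError):
        assign_region(_record("X", 1, -1.0, closest="ZZ"), region_map, model)


def test_region_map_from_json_shapes(tmp_path):
    flat = tmp_path / "flat.json"
    flat.write_text('{"N": "ii", "O": "i"}')
    grouped = tmp_path / "grouped.json"
    grouped.write_text('{"ii": ["N"], "i": ["O"]}')
    assert RegionMap.from_json(flat).assignment == RegionMap.from_json(grouped).assignment
    dup = tmp_path / "dup.json"
    dup.write_text('{"i": ["N"], "ii": ["N"]}')
    with pytest.raises(ValueError, match="twice"):
        RegionMap.from_json(dup)


def test_regional_sums_match_groupby(sweep12):
    _, _, sweep = sweep12
    sums = aggregate_regional_energies(sweep.records)
    df = pd.DataFrame({"region": [r.region for r in sweep.records],
                       "energy": [r.energy for r in sweep.records]})
    expected = df.groupby("region")["energy"].sum()
    for region, value in sums.items():
        if region in expected.index:
            assert value == pytest.approx(expected[region], abs=1e-9)
        else:
            assert value == 0.0  # region with no residues
    assert sum(sums.values()) == pytest.approx(
        sum(r.energy for r in sweep.records), abs=1e-9
    )


def test_unassigned_record_without_map_rejected():
    with pytest.raises(ValueError):
        aggregate_regional_energies([_record("X", 1, -1.0, region=None)])
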
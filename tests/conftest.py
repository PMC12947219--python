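import numpy as np
import pytest

from pymfcc import ClassicalBackend, ToyComplexSpec, generate_toy_complex
from pymfcc.structure import Atom, Ligand, Residue, StructureModel


@pytest.fixture(scope="session")
def toy10():
    """A mid-sized toy complex with its independent ground truth."""
    return generate_toy_complex(ToyComplexSpec(seed=1, n_residues=10))


@pytest.fixture(scope="session")
def toy3_paths(tmp_path_factory):
    """A 3-residue complex emitted as PDB + parameter CSV + regions JSON."""
    from pymfcc.synthetic import emit_toy_complex

    outdir = tmp_path_factory.mktemp("toy3")
    return emit_toy_complex(
        ToyComplexSpec(seed=7, n_residues=3, distance_range=(3.0, 7.0)), outdir
    )


@pytest.fixture()
def backend():
    return ClassicalBackend(40.0)


def make_point_charge_model(
    positions, charges, lj=None, ligand_idx=(0,), epsilon=40.0
):
    """Minimal hand-built model: point atoms split into one 'residue' and a
    ligand, with no covalent bonds. Used for closed-form energy checks."""
    atoms = {}
    res = Residue(chain="A", seq_number=1, name="GLY")
    lig = Ligand(code="LIG", formal_charge=0)
    for i, (p, q) in enumerate(zip(positions, charges)):
        eps, rmin = (0.0, 0.0) if lj is None else lj[i]
        atoms[i] = Atom(
            id=i, element="C", name=f"X{i}", coords=np.asarray(p, dtype=float),
            partial_charge=q, lj_epsilon=eps, lj_rmin_half=rmin,
            residue_key=("LIG", 0) if i in ligand_idx else res.key,
        )
        if i in ligand_idx:
            lig.atom_ids.append(i)
        else:
            res.atom_ids.append(i)
    model = StructureModel(atoms, [res], lig, dielectric_default=epsilon)
    return model
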
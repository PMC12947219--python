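"""Deterministic toy receptor–ligand complexes with known ground truth.

The generator emulates a small binding pocket: a short peptide chain curving
around a polar ligand with a protonated amine (an ethanolamine-like het
group, code ``ETA``), residue nearest approaches spanning roughly 2–10 Å,
and a mix of charged (ASP/LYS) and neutral residues so per-residue energies
take both signs. Geometry is plausible (tetrahedral centres, 1.2–1.6 Å
bonded distances) but deliberately unrelaxed — the classical backend only
needs finite, non-singular coordinates.

``brute_force_reference`` is the independent oracle: by direct pair
enumeration and inline vector arithmetic only (no fragmentation code), it
computes the quantity the four-term capped-fragment decomposition must equal
under a strictly pairwise-additive backend.
"""

from __future__ import annotations

import math
import shutil
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import COULOMB_K
from .errors import GenerationError
from .fragmentation import CapScheme
from .structure import (
    Atom,
    Ligand,
    Residue,
    ResidueKey,
    StructureModel,
    assign_parameters,
    write_pdb,
)

# Alternating tetrahedral bond directions of a zig-zag chain along +x.
_B1 = np.array([0.8165, 0.5774, 0.0])
_B2 = np.array([0.8165, -0.5774, 0.0])

_NEUTRAL_POOL = ("GLY", "ALA", "SER", "VAL", "CYS")

#: Ligand heavy-atom regions: protonated-amine end (ii) vs hydroxyl end (i).
TOY_REGIONS = {"N": "ii", "C1": "ii", "C2": "i", "O": "i"}


@dataclass
class ToyComplexSpec:
    """Study conditions for one synthetic complex."""

    seed: int = 0
    n_residues: int = 12
    ligand_n_atoms: int = 12
    distance_range: tuple[float, float] = (2.0, 10.0)
    charge_profile: float = 0.5
    epsilon: float = 40.0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        lo, hi = self.distance_range
        if not (1.5 < lo < hi < 12.0):
            raise ValueError("distance_range must lie within (1.5, 12) Å")
        if not 0.0 <= self.charge_profile <= 1.0:
            raise ValueError("charge_profile is a fraction")
        if self.ligand_n_atoms != 12:
            raise GenerationError("the toy ligand template has exactly 12 atoms")


@dataclass
class GroundTruthRecord:
    """Independently computed per-residue reference values."""

    residue_key: ResidueKey
    label: str
    direct_energy: float  # ligand–residue cross energy, kcal/mol
    min_distance: float  # Å


# ---------------------------------------------------------------------------
# geometry helpers


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _tetra_dirs(bond: np.ndarray) -> list[np.ndarray]:
    """Three unit vectors completing a tetrahedron around one existing bond."""
    b = _unit(bond)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(b @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(b, ref))
    v = np.cross(b, u)
    k = 2.0 * math.sqrt(2.0) / 3.0
    return [
        -b / 3.0 + k * (math.cos(phi) * u + math.sin(phi) * v)
        for phi in (0.0, 2.0 * math.pi / 3.0, 4.0 * math.pi / 3.0)
    ]


def _complete_tetra(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors completing a tetrahedron around two existing bonds."""
    m = -_unit(_unit(a) + _unit(b))
    n = _unit(np.cross(a, b))
    half = math.radians(109.471 / 2.0)
    return (
        math.cos(half) * m + math.sin(half) * n,
        math.cos(half) * m - math.sin(half) * n,
    )


def _sp2_pair(bond_in: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors at ±120° from an incoming bond (planar centre)."""
    b = _unit(bond_in)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(b @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(np.cross(b, ref), b))
    c, s = math.cos(math.radians(120.0)), math.sin(math.radians(120.0))
    return (c * (-b) + s * u, c * (-b) - s * u)


# ---------------------------------------------------------------------------
# templates

_XH = {"C": 1.09, "N": 1.01, "O": 0.96, "S": 1.34}

# Linear side-chain specs: (atom, element, bond length, hydrogens on it).
_SIDE_CHAINS: dict[str, list[tuple[str, str, float, tuple[str, ...]]]] = {
    "GLY": [],
    "ALA": [("CB", "C", 1.53, ("HB1", "HB2", "HB3"))],
    "SER": [("CB", "C", 1.53, ("HB2", "HB3")), ("OG", "O", 1.41, ("HG",))],
    "CYS": [("CB", "C", 1.53, ("HB2", "HB3")), ("SG", "S", 1.81, ("HG",))],
    "VAL": [("CB", "C", 1.53, ("HB",))],
    "ASP": [("CB", "C", 1.53, ("HB2", "HB3")), ("CG", "C", 1.52, ())],
    "GLU": [
        ("CB", "C", 1.53, ("HB2", "HB3")),
        ("CG", "C", 1.53, ("HG2", "HG3")),
        ("CD", "C", 1.52, ()),
    ],
    "LYS": [
        ("CB", "C", 1.53, ("HB2", "HB3")),
        ("CG", "C", 1.53, ("HG2", "HG3")),
        ("CD", "C", 1.53, ("HD2", "HD3")),
        ("CE", "C", 1.53, ("HE2", "HE3")),
        ("NZ", "N", 1.49, ("HZ1", "HZ2", "HZ3")),
    ],
}


def ligand_template() -> list[tuple[str, str, np.ndarray, int]]:
    """(name, element, coords, formal charge) for the ETA ligand, centred."""
    n = np.zeros(3)
    c1 = n + 1.49 * _B1
    c2 = c1 + 1.53 * _B2
    o = c2 + 1.41 * _B1
    ho = o + 0.96 * _B2
    atoms: dict[str, tuple[str, np.ndarray, int]] = {
        "N": ("N", n, 1),
        "C1": ("C", c1, 0),
        "C2": ("C", c2, 0),
        "O": ("O", o, 0),
        "HO": ("H", ho, 0),
    }
    for name, d in zip(("HN1", "HN2", "HN3"), _tetra_dirs(c1 - n)):
        atoms[name] = ("H", n + 1.01 * d, 0)
    for name, d in zip(("H11", "H12"), _complete_tetra(n - c1, c2 - c1)):
        atoms[name] = ("H", c1 + 1.09 * d, 0)
    for name, d in zip(("H21", "H22"), _complete_tetra(c1 - c2, o - c2)):
        atoms[name] = ("H", c2 + 1.09 * d, 0)
    order = ["N", "HN1", "HN2", "HN3", "C1", "H11", "H12", "C2", "H21", "H22", "O", "HO"]
    centroid = sum(atoms[k][1] for k in order) / len(order)
    return [(k, atoms[k][0], atoms[k][1] - centroid, atoms[k][2]) for k in order]


_BACKBONE_NAMES = {"N", "H", "CA", "HA", "HA2", "HA3", "C", "O"}


def _rotate_about(p: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of a point about a line (origin, axis)."""
    k = _unit(axis)
    v = p - origin
    return (
        origin
        + v * math.cos(angle)
        + np.cross(k, v) * math.sin(angle)
        + k * (k @ v) * (1.0 - math.cos(angle))
    )


def _residue_template(
    resname: str, parity: int, chi: float = 0.0
) -> tuple[list[tuple[str, str, np.ndarray]], np.ndarray]:
    """Atoms of one residue in its local frame, plus the offset to the next
    residue's backbone nitrogen.

    The backbone zig-zags along +x (N at origin); ``parity`` swaps the two
    alternating bond directions so consecutive residues chain with exact
    1.33 Å peptide bonds. The side chain grows toward +z, which placement
    maps to "radially away from the ligand".
    """
    d1, d2 = (_B1, _B2) if parity == 0 else (_B2, _B1)
    n = np.zeros(3)
    ca = n + 1.46 * d1
    c = ca + 1.52 * d2
    o = c + 1.23 * _unit(d2 - d1)
    h = n + 1.01 * _unit(d2 - d1)
    atoms: list[tuple[str, str, np.ndarray]] = [
        ("N", "N", n),
        ("H", "H", h),
        ("CA", "C", ca),
    ]

    up, down = _complete_tetra(n - ca, c - ca)
    if up[2] < down[2]:
        up, down = down, up
    if resname == "GLY":
        atoms += [("HA2", "H", ca + 1.09 * up), ("HA3", "H", ca + 1.09 * down)]
    else:
        atoms.append(("HA", "H", ca + 1.09 * down))
        prev_pos, grow_dir = ca, up
        spec = _SIDE_CHAINS[resname]
        for idx, (name, element, blen, hnames) in enumerate(spec):
            pos = prev_pos + blen * grow_dir
            atoms.append((name, element, pos))
            back = prev_pos - pos
            last = idx == len(spec) - 1
            if not last:
                dirs = _tetra_dirs(back)
                next_dir = max(dirs, key=lambda v: float(v[2]))
                rest = [d for d in dirs if d is not next_dir]
                for hname, hd in zip(hnames, rest):
                    atoms.append((hname, "H", pos + 1.09 * hd))
                prev_pos, grow_dir = pos, next_dir
            elif resname in ("ASP", "GLU"):
                da, db = _sp2_pair(-back)
                oa, ob = ("OD1", "OD2") if resname == "ASP" else ("OE1", "OE2")
                atoms += [(oa, "O", pos + 1.25 * da), (ob, "O", pos + 1.25 * db)]
            elif resname == "VAL":
                dirs = _tetra_dirs(back)
                atoms.append(("HB", "H", pos + 1.09 * dirs[2]))
                for gname, gd in (("CG1", dirs[0]), ("CG2", dirs[1])):
                    gpos = pos + 1.53 * gd
                    atoms.append((gname, "C", gpos))
                    hbase = f"H{gname[1:]}"
                    for hname, hd in zip(
                        (hbase + "1", hbase + "2", hbase + "3"),
                        _tetra_dirs(pos - gpos),
                    ):
                        atoms.append((hname, "H", gpos + 1.09 * hd))
            else:
                for hname, hd in zip(hnames, _tetra_dirs(back)):
                    atoms.append((hname, "H", pos + _XH[element] * hd))

    if chi and resname != "GLY":
        by_name = {a[0]: a[2] for a in atoms}
        cb = by_name.get("CB")
        if cb is not None:
            atoms = [
                (nm, el, p)
                if (nm in _BACKBONE_NAMES or nm == "CB")
                else (nm, el, _rotate_about(p, ca, cb - ca, chi))
                for nm, el, p in atoms
            ]

    atoms += [("C", "C", c), ("O", "O", o)]
    next_n_offset = c + 1.33 * d1
    return atoms, next_n_offset


# ---------------------------------------------------------------------------
# generator


def _residue_names(spec: ToyComplexSpec, rng: np.random.Generator) -> list[str]:
    n = spec.n_residues
    n_charged = int(round(spec.charge_profile * n))
    charged_types = ["ASP" if j % 2 == 0 else "LYS" for j in range(n_charged)]
    positions = rng.choice(n, size=n_charged, replace=False)
    names = [str(rng.choice(_NEUTRAL_POOL)) for _ in range(n)]
    for pos, t in zip(sorted(positions), charged_types):
        names[pos] = t
    return names


def _rotate_vec(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    k = _unit(axis)
    return (
        v * math.cos(angle)
        + np.cross(k, v) * math.sin(angle)
        + k * (k @ v) * (1.0 - math.cos(angle))
    )


def _chain_intact(model: StructureModel) -> bool:
    """Neighbour graph is one simple chain with no extra inter-residue bonds."""
    inter = 0
    for i, nbrs in model.bonds.items():
        for j in nbrs:
            if j > i and model.atoms[i].residue_key != model.atoms[j].residue_key:
                inter += 1
    if inter != len(model.residues) - 1:
        return False
    for prev, curr in zip(model.residues, model.residues[1:]):
        if prev.c_neighbor != curr.key or curr.n_neighbor != prev.key:
            return False
    return True


def generate_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[StructureModel, list[GroundTruthRecord]]:
    """Build a parameterized toy complex and its ground truth.

    The chain coils around the ligand on an outward spherical spiral so
    residue nearest approaches sweep ``distance_range`` from the inside out.
    Identical specs produce identical models; placement that cannot satisfy
    the distance and topology constraints after bounded retries raises
    :class:`GenerationError`.
    """
    lo, hi = spec.distance_range
    margin = min(1.1, (hi - lo) / 2 - 0.3)
    for attempt in range(300):
        rng = np.random.default_rng([spec.seed, attempt])
        jitter = rng.uniform(-0.25, 0.25, size=spec.n_residues)
        targets = np.sort(
            np.linspace(lo + margin, hi - margin, spec.n_residues) + jitter
        )
        model = _build_model(spec, rng, targets)
        if model is None:
            continue
        truth = _ground_truth(model, spec.epsilon)
        if (
            all(lo <= t.min_distance <= hi for t in truth)
            and _no_clash(model)
            and _chain_intact(model)
        ):
            return model, truth
    raise GenerationError(
        f"could not place {spec.n_residues} residues within {spec.distance_range} Å"
    )


def _fatal_contact(
    world: np.ndarray,
    template: list,
    placed_coords: list[np.ndarray],
    placed_elems: list[list[str]],
) -> bool:
    """Would this placement create a contact that distance-based bond
    perception could mistake for a covalent bond (or a near-singular pair)?

    The cutoff tracks the perception rule (tolerance x sum of covalent
    radii) with a small safety margin; the covalently attached previous
    residue is exempt for the new backbone N/H, whose short contacts are
    the peptide bond itself.
    """
    from scipy.spatial import cKDTree

    from .constants import COVALENT_RADII

    if not placed_coords:
        return False
    tree = cKDTree(np.vstack(placed_coords))
    elems = [e for lst in placed_elems for e in lst]
    n_prev_start = len(elems) - len(placed_elems[-1])
    neighbours = tree.query_ball_point(world, r=3.0)
    for ai, hits in enumerate(neighbours):
        name_a, elem_a = template[ai][0], template[ai][1]
        for pj in hits:
            if pj >= n_prev_start and name_a in ("N", "H"):
                continue  # legitimate peptide-bond proximity
            elem_b = elems[pj]
            cut = 1.35 * (COVALENT_RADII[elem_a] + COVALENT_RADII[elem_b]) + 0.1
            if elem_a == "H" and elem_b == "H":
                cut = 0.95
            d = float(np.linalg.norm(world[ai] - tree.data[pj]))
            if d < cut:
                return True
    return False


_ALPHAS = tuple(math.radians(a) for a in (-60, -45, -30, -15, 0, 15, 30, 45, 60))
# radial blend of the heading; curving along a sphere of radius ~6 Å takes
# ~0.6 rad of inward turn per residue, so the grid reaches further inward
_BETAS = (-1.0, -0.75, -0.55, -0.38, -0.24, -0.12, 0.0, 0.12, 0.25, 0.40)


def _build_model(
    spec: ToyComplexSpec,
    rng: np.random.Generator,
    targets: np.ndarray,
) -> StructureModel | None:
    """Greedy self-avoiding placement of the chain around the ligand.

    Each residue's frame is chosen from a small grid of candidate headings
    (azimuthal turns of the running direction plus a radial blend), scored by
    how close its nearest approach lands to the target distance, how far its
    atoms stay from everything already placed, and how gently the chain
    turns. The peptide bond to the previous carbonyl carbon is exact by
    construction for every candidate.
    """
    from scipy.spatial import cKDTree

    atoms: dict[int, Atom] = {}
    next_id = 0

    ligand = Ligand(code="ETA", formal_charge=1)
    for name, element, coords, fc in ligand_template():
        atoms[next_id] = Atom(
            id=next_id, element=element, name=name, coords=coords,
            formal_charge=fc,
        )
        ligand.atom_ids.append(next_id)
        next_id += 1

    names = _residue_names(spec, rng)
    lig_coords = np.array([atoms[i].coords for i in ligand.atom_ids])

    placed_coords: list[np.ndarray] = []
    placed_elems: list[list[str]] = []
    residues: list[Residue] = []
    prev_c: np.ndarray | None = None
    # first backbone N: radially out along +x, forward tangential
    pos = (targets[0] + 2.55) * np.array([1.0, 0.0, 0.0])
    forward = np.array([0.0, 1.0, 0.0])

    for i, resname in enumerate(names):
        template, _ = _residue_template(resname, i % 2)
        locals_mat = np.array([t[2] for t in template])
        skip_clash = np.array([t[0] in ("N", "H") for t in template])
        # the previous residue is covalently attached, so its (legitimate)
        # short contacts are scored separately and only for side-chain atoms
        side_only = np.array([t[0] not in _BACKBONE_NAMES for t in template])
        idx_ca = next(k for k, t in enumerate(template) if t[0] == "CA")
        idx_h = next(k for k, t in enumerate(template) if t[0] == "H")
        far_tree = (
            cKDTree(np.vstack(placed_coords[:-1])) if len(placed_coords) > 1 else None
        )
        adj_tree = cKDTree(placed_coords[-1]) if placed_coords else None
        r_hat = _unit(pos)
        az_jit = rng.uniform(-0.1, 0.1)
        lo, hi = spec.distance_range

        rots = []
        for alpha in _ALPHAS:
            base = _rotate_vec(forward, r_hat, alpha + az_jit)
            for beta in _BETAS:
                x_hat = _unit(base + beta * r_hat)
                z_hat = r_hat - (r_hat @ x_hat) * x_hat
                nz = np.linalg.norm(z_hat)
                if nz < 0.3:  # heading too radial; side chain ill-defined
                    continue
                z_hat = z_hat / nz
                y_hat = np.cross(z_hat, x_hat)
                rots.append(np.column_stack([x_hat, y_hat, z_hat]))
        if not rots:
            return None
        R = np.stack(rots)  # (m, 3, 3)
        worlds = pos + np.einsum("mij,nj->mni", R, locals_mat)  # (m, n, 3)
        if prev_c is not None:
            # final amide-H position (trans to the previous carbonyl) so
            # scoring sees exactly what will be committed
            n_w = worlds[:, 0, :]
            d_ca_dir = worlds[:, idx_ca, :] - n_w
            d_ca_dir /= np.linalg.norm(d_ca_dir, axis=1, keepdims=True)
            d_pc = prev_c - n_w
            d_pc /= np.linalg.norm(d_pc, axis=1, keepdims=True)
            h_dir = -(d_ca_dir + d_pc)
            h_dir /= np.linalg.norm(h_dir, axis=1, keepdims=True)
            worlds[:, idx_h, :] = n_w + 1.01 * h_dir
        m = len(R)
        diff = worlds[:, :, None, :] - lig_coords[None, None, :, :]
        dmin = np.sqrt((diff**2).sum(-1).reshape(m, -1).min(1))
        clash = np.zeros(m)
        if far_tree is not None:
            near, _ = far_tree.query(worlds[:, ~skip_clash, :].reshape(-1, 3), k=1)
            clash += (
                np.clip(2.8 - near.reshape(m, -1), 0.0, None) ** 2
            ).sum(1)
        if adj_tree is not None and side_only.any():
            near, _ = adj_tree.query(worlds[:, side_only, :].reshape(-1, 3), k=1)
            clash += (
                np.clip(2.3 - near.reshape(m, -1), 0.0, None) ** 2
            ).sum(1)
        if prev_c is not None:
            # keep the C(i-1)–N(i)–CA(i) angle open: CA must stay well
            # outside covalent range of the previous carbonyl
            d_ca = np.linalg.norm(worlds[:, idx_ca, :] - prev_c, axis=1)
            clash += np.clip(2.35 - d_ca, 0.0, None) ** 2
        smooth = 1.0 - R[:, :, 0] @ forward
        scores = (
            4.0 * (dmin - targets[i]) ** 2
            + 200.0 * clash
            + 200.0 * np.clip(lo + 0.3 - dmin, 0.0, None) ** 2
            + 200.0 * np.clip(dmin - (hi - 0.3), 0.0, None) ** 2
            + 0.5 * smooth
        )
        candidates = [(float(scores[j]), float(clash[j]), R[j], worlds[j]) for j in range(m)]
        # stochastic pick among the leading candidates decorrelates retries,
        # which is what rescues the occasional boxed-in walk
        candidates.sort(key=lambda c: c[0])
        k = min(4, len(candidates))
        probs = {4: (0.5, 0.25, 0.15, 0.10), 3: (0.6, 0.25, 0.15)}.get(k)
        pick = int(rng.choice(k, p=probs))
        chosen = None
        order = list(range(k))
        order.remove(pick)
        for idx in [pick] + order:
            _, _, rot_c, world_c = candidates[idx]
            if not _fatal_contact(world_c, template, placed_coords, placed_elems):
                chosen = (rot_c, world_c)
                break
        if chosen is None:
            return None  # boxed in — abandon this walk early and re-roll
        rot, world = chosen

        residue = Residue(chain="A", seq_number=i + 1, name=resname)
        placed: dict[str, int] = {}
        for (name, element, _), coords in zip(template, world):
            atoms[next_id] = Atom(
                id=next_id, element=element, name=name,
                coords=coords, residue_key=("A", i + 1),
            )
            residue.atom_ids.append(next_id)
            placed[name] = next_id
            next_id += 1
        residues.append(residue)
        n_w, ca_w = atoms[placed["N"]].coords, atoms[placed["CA"]].coords
        c_world = atoms[placed["C"]].coords
        if prev_c is not None:
            # amide H trans to the actual previous carbonyl carbon
            h_dir = -_unit(_unit(ca_w - n_w) + _unit(prev_c - n_w))
            atoms[placed["H"]].coords = n_w + 1.01 * h_dir
        placed_coords.append(
            np.array([atoms[j].coords for j in residue.atom_ids])
        )
        placed_elems.append([atoms[j].element for j in residue.atom_ids])
        d1 = _B1 if i % 2 == 0 else _B2
        pos = c_world + 1.33 * (rot @ d1)  # next backbone N, natural direction
        forward = rot[:, 0]
        prev_c = c_world

    model = StructureModel(atoms, residues, ligand, dielectric_default=spec.epsilon)
    model.perceive_bonds()
    model.link_residue_neighbors()
    assign_parameters(model)
    return model


def _no_clash(model: StructureModel, min_dist: float = 0.8) -> bool:
    """No non-bonded atom pair closer than ``min_dist`` Å."""
    ids = sorted(model.atoms)
    coords = np.array([model.atoms[i].coords for i in ids])
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    for a, b in tree.query_pairs(r=min_dist):
        i, j = ids[a], ids[b]
        if j not in model.bonds[i]:
            return False
    return True


def _ground_truth(model: StructureModel, epsilon: float) -> list[GroundTruthRecord]:
    """Direct per-residue cross energies and contact distances, computed with
    explicit double loops so the pipeline has an independent yardstick."""
    lig = model.ligand_atoms()
    records = []
    for res in model.residues:
        res_atoms = model.residue_atoms(res.key)
        energy = 0.0
        dmin = math.inf
        for a in res_atoms:
            for b in lig:
                r = math.dist(a.coords, b.coords)
                dmin = min(dmin, r)
                energy += COULOMB_K * a.partial_charge * b.partial_charge / (epsilon * r)
                eps_ij = math.sqrt(a.lj_epsilon * b.lj_epsilon)
                x6 = ((a.lj_rmin_half + b.lj_rmin_half) / r) ** 6
                energy += eps_ij * (x6 * x6 - 2.0 * x6)
        records.append(
            GroundTruthRecord(
                residue_key=res.key, label=res.label,
                direct_energy=energy, min_distance=dmin,
            )
        )
    return records


# ---------------------------------------------------------------------------
# oracle


def brute_force_reference(
    model: StructureModel,
    residue_key: ResidueKey,
    scheme: CapScheme | None = None,
    epsilon: float | None = None,
) -> float:
    """Reference value for one residue's capped-fragment energy.

    Under a strictly pairwise-additive backend the four-term combination
    reduces to: (ligand–residue cross energy) + (ligand × link hydrogens of
    the capped-residue system) − (ligand × link hydrogens of the caps-only
    system). Link-hydrogen positions are re-derived here by plain vector
    arithmetic from the peptide topology.
    """
    scheme = scheme or CapScheme()
    epsilon = model.dielectric_default if epsilon is None else epsilon
    residue = model.residue(residue_key)
    lig = model.ligand_atoms()

    def named(res, name):
        for i in res.atom_ids:
            if model.atoms[i].name == name:
                return model.atoms[i]
        raise KeyError(name)

    def link_h(kept: Atom, removed: Atom) -> tuple[np.ndarray, float, float, float]:
        length = scheme.bond_length_for(kept.element)
        coords = kept.coords + length * _unit(removed.coords - kept.coords)
        return (coords, scheme.link_h_charge, scheme.link_h_epsilon, scheme.link_h_rmin_half)

    h_crc: list[tuple] = []
    h_cc: list[tuple] = []
    if residue.n_neighbor is not None:
        cap = model.residue(residue.n_neighbor)
        if cap.n_neighbor is not None:
            distal = model.residue(cap.n_neighbor)
            h = link_h(named(cap, "N"), named(distal, "C"))
            h_crc.append(h)
            h_cc.append(h)
        h_cc.append(link_h(named(cap, "C"), named(residue, "N")))
    if residue.c_neighbor is not None:
        cap = model.residue(residue.c_neighbor)
        if cap.c_neighbor is not None:
            distal = model.residue(cap.c_neighbor)
            h = link_h(named(cap, "C"), named(distal, "N"))
            h_crc.append(h)
            h_cc.append(h)
        h_cc.append(link_h(named(cap, "N"), named(residue, "C")))

    def cross_res() -> float:
        e = 0.0
        for a in model.residue_atoms(residue_key):
            for b in lig:
                r = math.dist(a.coords, b.coords)
                e += COULOMB_K * a.partial_charge * b.partial_charge / (epsilon * r)
                eps_ij = math.sqrt(a.lj_epsilon * b.lj_epsilon)
                x6 = ((a.lj_rmin_half + b.lj_rmin_half) / r) ** 6
                e += eps_ij * (x6 * x6 - 2.0 * x6)
        return e

    def cross_h(hs: list[tuple]) -> float:
        e = 0.0
        for coords, q, lj_eps, lj_rmin in hs:
            for b in lig:
                r = math.dist(coords, b.coords)
                e += COULOMB_K * q * b.partial_charge / (epsilon * r)
                eps_ij = math.sqrt(lj_eps * b.lj_epsilon)
                x6 = ((lj_rmin + b.lj_rmin_half) / r) ** 6
                e += eps_ij * (x6 * x6 - 2.0 * x6)
        return e

    return cross_res() + cross_h(h_crc) - cross_h(h_cc)


# ---------------------------------------------------------------------------
# emission through the standard readers


def emit_toy_complex(spec: ToyComplexSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a toy complex as PDB + parameter CSV + regions JSON.

    These files exercise exactly the same readers as real data.
    """
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, _ = generate_toy_complex(spec)
    paths = {
        "pdb": outdir / "toy_complex.pdb",
        "params": outdir / "params.csv",
        "regions": outdir / "regions.json",
    }
    write_pdb(model, paths["pdb"])
    with resources.as_file(resources.files("pymfcc.data") / "default_params.csv") as p:
        shutil.copy(p, paths["params"])
    paths["regions"].write_text(json.dumps(TOY_REGIONS, indent=1))
    return paths
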
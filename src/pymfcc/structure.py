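"""Structure containers and I/O: atoms, residues, ligand, bond perception,
protonation checks and force-field parameter assignment.

Coordinates are Å throughout and PDB residue numbering is preserved verbatim,
so residues can be reported with the labels crystallographers use (ASP106).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .constants import BOND_TOLERANCE, COVALENT_RADII
from .errors import ParameterizationError, SelectionError, StructureFormatError

logger = logging.getLogger(__name__)

#: Residue key: (chain id, residue sequence number).
ResidueKey = tuple[str, int]

#: Sentinel residue_key for ligand atoms.
LIGAND_KEY = ("LIG", 0)

#: Formal charges of standard residue templates at pH ~7.5 (HIS neutral).
RESIDUE_FORMAL_CHARGES = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

WATER_NAMES = {"HOH", "WAT", "TIP3", "H2O", "DOD"}
ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "SO4", "PO4"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class Atom:
    """A point atom with classical nonbonded parameters.

    ``partial_charge`` is in elementary-charge units, ``lj_epsilon`` in
    kcal·mol⁻¹ and ``lj_rmin_half`` in Å (half the pair-minimum distance,
    CHARMM convention). Parameters are ``None`` until assigned.
    """

    id: int
    element: str
    name: str
    coords: np.ndarray
    partial_charge: float | None = None
    lj_epsilon: float | None = None
    lj_rmin_half: float | None = None
    residue_key: ResidueKey = LIGAND_KEY
    is_link: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.id}: coordinates must be a finite 3-vector")
        self.element = self.element.strip().upper()
        if self.element not in COVALENT_RADII:
            raise ValueError(f"atom {self.id}: unknown element {self.element!r}")

    @property
    def parameterized(self) -> bool:
        return self.partial_charge is not None and self.lj_epsilon is not None


@dataclass
class Residue:
    chain: str
    seq_number: int
    name: str
    atom_ids: list[int] = field(default_factory=list)
    n_neighbor: ResidueKey | None = None
    c_neighbor: ResidueKey | None = None

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.seq_number)

    @property
    def label(self) -> str:
        """Paper-style label, e.g. ``ASP106``."""
        return f"{self.name}{self.seq_number}"


@dataclass
class Ligand:
    code: str
    atom_ids: list[int] = field(default_factory=list)
    formal_charge: int = 0


@dataclass
class AtomSystem:
    """A standalone atom set with its own covalent topology.

    This is what energy backends evaluate: fragment systems carry copies or
    references of model atoms plus any link hydrogens, and an adjacency map
    restricted to the system so 1-2/1-3 exclusions can be derived locally.
    """

    atoms: list[Atom]
    bonds: dict[int, set[int]] = field(default_factory=dict)
    label: str = ""
    formal_charge: int = 0

    @property
    def atom_ids(self) -> set[int]:
        return {a.id for a in self.atoms}


class StructureModel:
    """A receptor (ordered residues) plus one ligand, with covalent topology."""

    def __init__(
        self,
        atoms: dict[int, Atom],
        residues: list[Residue],
        ligand: Ligand | None = None,
        dielectric_default: float = 40.0,
    ) -> None:
        self.atoms = atoms
        self.residues = residues
        self.ligand = ligand
        self.dielectric_default = dielectric_default
        self.bonds: dict[int, set[int]] = {i: set() for i in atoms}
        self._residue_index: dict[ResidueKey, Residue] = {r.key: r for r in residues}
        if len(self._residue_index) != len(residues):
            raise ValueError("duplicate residue keys")

    # -- lookups ---------------------------------------------------------

    def residue(self, key: ResidueKey) -> Residue:
        return self._residue_index[key]

    def residue_atoms(self, key: ResidueKey) -> list[Atom]:
        return [self.atoms[i] for i in self.residue(key).atom_ids]

    def ligand_atoms(self) -> list[Atom]:
        if self.ligand is None:
            return []
        return [self.atoms[i] for i in self.ligand.atom_ids]

    def receptor_atom_ids(self) -> list[int]:
        return [i for r in self.residues for i in r.atom_ids]

    # -- topology --------------------------------------------------------

    def add_bond(self, i: int, j: int) -> None:
        self.bonds[i].add(j)
        self.bonds[j].add(i)

    def bonded_heavy_neighbor(self, atom_id: int) -> int | None:
        """First heavy-atom neighbor (lowest id) of an atom, or None."""
        heavy = sorted(
            j for j in self.bonds.get(atom_id, ()) if self.atoms[j].element != "H"
        )
        return heavy[0] if heavy else None

    def perceive_bonds(self) -> None:
        """Distance-based covalent bond perception.

        Two atoms are bonded when their separation is below ``BOND_TOLERANCE``
        times the sum of covalent radii. Hydrogens keep only their nearest
        heavy-atom bond; receptor–ligand contacts are never covalent.
        """
        ids = sorted(self.atoms)
        self.bonds = {i: set() for i in self.atoms}
        if not ids:
            return
        coords = np.array([self.atoms[i].coords for i in ids])
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=2.9)
        ligand_ids = set(self.ligand.atom_ids) if self.ligand else set()
        candidates: dict[int, list[tuple[float, int]]] = {}
        for a, b in pairs:
            i, j = ids[a], ids[b]
            ai, aj = self.atoms[i], self.atoms[j]
            if (i in ligand_ids) != (j in ligand_ids):
                continue
            cutoff = BOND_TOLERANCE * (
                COVALENT_RADII[ai.element] + COVALENT_RADII[aj.element]
            )
            d = float(np.linalg.norm(ai.coords - aj.coords))
            if d > cutoff:
                continue
            if ai.element == "H" and aj.element == "H":
                continue
            if ai.element == "H":
                candidates.setdefault(i, []).append((d, j))
            elif aj.element == "H":
                candidates.setdefault(j, []).append((d, i))
            else:
                self.add_bond(i, j)
        for h, opts in candidates.items():
            _, partner = min(opts)
            self.add_bond(h, partner)

    def link_residue_neighbors(self, max_cn: float = 1.8) -> None:
        """Set n_neighbor/c_neighbor for consecutive bonded residues."""
        by_chain: dict[str, list[Residue]] = {}
        for r in self.residues:
            by_chain.setdefault(r.chain, []).append(r)
        for chain_residues in by_chain.values():
            for prev, curr in zip(chain_residues, chain_residues[1:]):
                c = self._named_atom(prev, "C")
                n = self._named_atom(curr, "N")
                if c is None or n is None:
                    continue
                if np.linalg.norm(c.coords - n.coords) <= max_cn:
                    prev.c_neighbor = curr.key
                    curr.n_neighbor = prev.key
                    self.add_bond(c.id, n.id)

    def _named_atom(self, residue: Residue, name: str) -> Atom | None:
        for i in residue.atom_ids:
            if self.atoms[i].name == name:
                return self.atoms[i]
        return None

    # -- convenience -----------------------------------------------------

    def total_charge(self) -> float:
        return sum(a.partial_charge or 0.0 for a in self.atoms.values())

    def __repr__(self) -> str:
        lig = self.ligand.code if self.ligand else "none"
        return (
            f"<StructureModel {len(self.residues)} residues, "
            f"{len(self.atoms)} atoms, ligand={lig}>"
        )


# ---------------------------------------------------------------------------
# Reading


def read_structure(
    path: str | Path,
    format_hint: str = "auto",
    ligand_code: str | None = None,
    model_index: int | None = None,
    dielectric_default: float = 40.0,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Waters, ions and het groups other than the selected ligand are dropped
    (logged). Alternate locations are resolved to the highest-occupancy
    conformer. ``ligand_code`` selects the ligand het code explicitly; when
    omitted, a single unambiguous non-water het group is used if present.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(format_hint)
    if fmt is None:
        raise ValueError(f"unknown format hint {format_hint!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")
    if len(st) > 1 and model_index is None:
        raise StructureFormatError(
            f"{path}: {len(st)} models present; pass model_index to choose one"
        )
    gmodel = st[model_index or 0]

    atoms: dict[int, Atom] = {}
    residues: list[Residue] = []
    ligand: Ligand | None = None
    het_groups: dict[str, list] = {}
    next_id = 0

    def _dedupe_altlocs(res) -> list:
        best: dict[str, tuple[float, object]] = {}
        order: list[str] = []
        for at in res:
            occ = at.occ if at.occ else 1.0
            if at.name not in best:
                order.append(at.name)
                best[at.name] = (occ, at)
            elif occ > best[at.name][0]:
                logger.info(
                    "dropping altloc %s of %s/%s (lower occupancy)",
                    best[at.name][1].altloc, res.name, at.name,
                )
                best[at.name] = (occ, at)
            else:
                logger.info("dropping altloc %s of %s/%s", at.altloc, res.name, at.name)
        return [best[n][1] for n in order]

    for chain in gmodel:
        for res in chain:
            is_het = res.het_flag == "H"
            if is_het:
                if res.name in WATER_NAMES or res.name in ION_NAMES:
                    logger.info("dropping het group %s (water/ion)", res.name)
                    continue
                het_groups.setdefault(res.name, []).append((chain.name, res))
                continue
            residue = Residue(chain=chain.name, seq_number=res.seqid.num, name=res.name)
            for at in _dedupe_altlocs(res):
                atom = Atom(
                    id=next_id,
                    element=at.element.name,
                    name=at.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_key=residue.key,
                    formal_charge=at.charge,
                )
                atoms[next_id] = atom
                residue.atom_ids.append(next_id)
                next_id += 1
            residues.append(residue)

    if ligand_code is not None and ligand_code not in het_groups:
        raise SelectionError(
            f"ligand {ligand_code!r} not found; het groups present: "
            f"{sorted(het_groups) or 'none'}"
        )
    if ligand_code is None:
        if len(het_groups) > 1:
            raise SelectionError(
                f"multiple het groups {sorted(het_groups)}; pass ligand_code"
            )
        ligand_code = next(iter(het_groups), None)

    if ligand_code is not None:
        ligand = Ligand(code=ligand_code)
        formal = 0
        for _, res in het_groups[ligand_code]:
            for at in _dedupe_altlocs(res):
                atom = Atom(
                    id=next_id,
                    element=at.element.name,
                    name=at.name,
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_key=LIGAND_KEY,
                    formal_charge=at.charge,
                )
                atoms[next_id] = atom
                ligand.atom_ids.append(next_id)
                formal += at.charge
                next_id += 1
        ligand.formal_charge = formal
        for name in het_groups:
            if name != ligand_code:
                logger.info("dropping het group %s (not the selected ligand)", name)

    model = StructureModel(atoms, residues, ligand, dielectric_default)
    model.perceive_bonds()
    model.link_residue_neighbors()
    return model


# ---------------------------------------------------------------------------
# Writing


def write_pdb(target: StructureModel | AtomSystem, path: str | Path) -> None:
    """Write a model or fragment system as a normalized PDB file.

    Link hydrogens are flagged with a ``+1`` style empty charge column left
    blank and residue name ``LNK`` so capped systems can be inspected in any
    viewer.
    """
    path = Path(path)
    lines: list[str] = []
    serial = 0

    def _record(atom: Atom, resname: str, chain: str, resnum: int, het: bool) -> str:
        nonlocal serial
        serial += 1
        name = atom.name if len(atom.name) >= 4 else f" {atom.name}"
        rec = "HETATM" if het else "ATOM  "
        x, y, z = atom.coords
        fc = atom.formal_charge
        charge_col = f"{abs(fc)}{'+' if fc > 0 else '-'}" if fc else "  "
        return (
            f"{rec}{serial:>5} {name:<4} {resname:<3} {chain:1}{resnum:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{atom.element:>2}{charge_col}"
        )

    if isinstance(target, StructureModel):
        for res in target.residues:
            for i in res.atom_ids:
                lines.append(_record(target.atoms[i], res.name, res.chain, res.seq_number, False))
        if target.ligand is not None:
            for i in target.ligand.atom_ids:
                lines.append(_record(target.atoms[i], target.ligand.code, "L", 1, True))
    else:
        for atom in target.atoms:
            if atom.is_link:
                lines.append(_record(atom, "LNK", "X", 999, True))
            elif atom.residue_key == LIGAND_KEY:
                lines.append(_record(atom, "LIG", "L", 1, True))
            else:
                chain, num = atom.residue_key
                lines.append(_record(atom, "UNK", chain, num, False))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Protonation validation


@dataclass
class ProtonationReport:
    passed: bool
    missing_hydrogens: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def validate_protonation(
    model: StructureModel, table: "ParameterTable | None" = None
) -> ProtonationReport:
    """Check each residue against its template's hydrogen inventory.

    A residue whose template (from the parameter table) lists hydrogens that
    the structure lacks fails validation with those atoms named. Residues
    without a template produce a warning, not a failure — inputs must arrive
    pre-protonated and this check only catches obvious omissions.
    """
    table = table or default_parameter_table()
    missing: list[str] = []
    warnings: list[str] = []
    for res in model.residues:
        template = table.residue_atom_names(res.name)
        if template is None:
            kind = "no template for" if res.name in STANDARD_AA else "nonstandard residue"
            warnings.append(f"{res.label}: {kind} {res.name!r}")
            continue
        present = {model.atoms[i].name for i in res.atom_ids}
        for name in sorted(template):
            if name.startswith("H") and name not in present:
                missing.append(f"{res.label}: missing hydrogen {name}")
    return ProtonationReport(passed=not missing, missing_hydrogens=missing, warnings=warnings)


# ---------------------------------------------------------------------------
# Parameter tables


class ParameterTable:
    """Charge/LJ lookup keyed by (residue-or-ligand code, atom name).

    CSV columns: ``residue,atom,charge,epsilon,rmin_half``. The special
    residue code ``LNK`` supplies the generic link-hydrogen parameters.
    """

    def __init__(self, entries: dict[tuple[str, str], tuple[float, float, float]]):
        self.entries = entries

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterTable":
        entries: dict[tuple[str, str], tuple[float, float, float]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                key = (row["residue"].strip(), row["atom"].strip())
                entries[key] = (
                    float(row["charge"]),
                    float(row["epsilon"]),
                    float(row["rmin_half"]),
                )
        return cls(entries)

    def residue_atom_names(self, resname: str) -> set[str] | None:
        names = {a for (r, a) in self.entries if r == resname}
        return names or None

    def lookup(self, resname: str, atom_name: str) -> tuple[float, float, float]:
        try:
            return self.entries[(resname, atom_name)]
        except KeyError:
            raise ParameterizationError(
                f"no parameters for atom {atom_name!r} in residue {resname!r}"
            ) from None

    @property
    def link_hydrogen(self) -> tuple[float, float, float]:
        return self.lookup("LNK", "H")


def default_parameter_table() -> ParameterTable:
    """The compact additive charge/LJ set shipped with the package."""
    with resources.as_file(
        resources.files("pymfcc.data") / "default_params.csv"
    ) as p:
        return ParameterTable.from_csv(p)


def assign_parameters(
    model: StructureModel,
    table: ParameterTable | None = None,
    check_charge_sums: bool = True,
) -> StructureModel:
    """Attach partial charges and LJ parameters to every atom, in place.

    Residue charge sums are checked against template formal charges to 1e-6 e
    so a typo in a user-supplied table fails loudly rather than biasing every
    downstream energy.
    """
    table = table or default_parameter_table()
    for res in model.residues:
        total = 0.0
        for i in res.atom_ids:
            atom = model.atoms[i]
            q, eps, rmin = table.lookup(res.name, atom.name)
            atom.partial_charge, atom.lj_epsilon, atom.lj_rmin_half = q, eps, rmin
            total += q
        expected = RESIDUE_FORMAL_CHARGES.get(res.name, 0)
        if check_charge_sums and abs(total - expected) > 1e-6:
            raise ParameterizationError(
                f"{res.label}: charge sum {total:+.6f} != template formal "
                f"charge {expected:+d}"
            )
    if model.ligand is not None:
        total = 0.0
        for i in model.ligand.atom_ids:
            atom = model.atoms[i]
            q, eps, rmin = table.lookup(model.ligand.code, atom.name)
            atom.partial_charge, atom.lj_epsilon, atom.lj_rmin_half = q, eps, rmin
            total += q
        if check_charge_sums and abs(total - model.ligand.formal_charge) > 1e-6:
            raise ParameterizationError(
                f"ligand {model.ligand.code}: charge sum {total:+.6f} != formal "
                f"charge {model.ligand.formal_charge:+d}"
            )
    return model
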
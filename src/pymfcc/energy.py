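"""Energy backends.

The decomposition only needs one contract: ``evaluate(AtomSystem) -> float``
in kcal·mol⁻¹. Two implementations are provided:

* :class:`ClassicalBackend` — a pairwise Coulomb + Lennard-Jones evaluator
  with uniform dielectric screening. Uniform ε stands in for a continuum
  solvent model; it is a desk-scale evaluator, not an approximation claim
  about any particular QM protocol. Its strict pairwise additivity is what
  makes the four-term decomposition exactly equal to the direct
  ligand–residue cross energy (plus link-hydrogen terms), which the test
  suite exploits as an oracle.
* :class:`CachedQMBackend` — writes input decks for an external
  quantum-chemistry engine and serves energies from a CSV cache, so a real
  DFT campaign can be scripted, resumed and merged without this package ever
  executing the engine.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_K, HARTREE_TO_KCAL, MIN_PAIR_DISTANCE
from .errors import EnergyParseError, GeometryError, ParameterizationError
from .structure import Atom, AtomSystem


@dataclass
class DielectricModel:
    """Uniform relative permittivity screening the Coulomb term."""

    epsilon: float = 40.0

    def __post_init__(self) -> None:
        if self.epsilon < 1:
            raise ValueError("relative permittivity must be >= 1")


class EnergyBackend(Protocol):
    def evaluate(self, system: AtomSystem) -> float: ...

    @property
    def metadata(self) -> dict: ...


def _gather(atoms: list[Atom]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    for a in atoms:
        if not a.parameterized:
            raise ParameterizationError(
                f"atom {a.id} ({a.name}) has no charge/LJ parameters"
            )
    coords = np.array([a.coords for a in atoms], dtype=float)
    q = np.array([a.partial_charge for a in atoms], dtype=float)
    eps = np.array([a.lj_epsilon for a in atoms], dtype=float)
    rmin = np.array([a.lj_rmin_half for a in atoms], dtype=float)
    return coords, q, eps, rmin


def _pair_energy_matrix(
    ca, qa, ea, ra, cb, qb, eb, rb, epsilon: float, self_matrix: bool = False
) -> np.ndarray:
    r = cdist(ca, cb)
    if self_matrix:
        np.fill_diagonal(r, np.inf)
    if np.any(r < MIN_PAIR_DISTANCE):
        raise GeometryError(
            f"atom pair closer than {MIN_PAIR_DISTANCE} Å — near-singular geometry"
        )
    coulomb = COULOMB_K * np.outer(qa, qb) / (epsilon * r)
    eps_ij = np.sqrt(np.outer(ea, eb))
    rmin_ij = ra[:, None] + rb[None, :]
    x6 = (rmin_ij / r) ** 6
    lj = eps_ij * (x6 * x6 - 2.0 * x6)
    return coulomb + lj


def pairwise_interaction_energy(
    set_a: list[Atom] | AtomSystem,
    set_b: list[Atom] | AtomSystem,
    model: DielectricModel | float = 40.0,
) -> float:
    """Cross interaction energy between two disjoint atom sets.

    Sum over all A×B pairs of screened Coulomb plus 12-6 Lennard-Jones with
    Lorentz–Berthelot-style combination (geometric-mean well depth, summed
    half-rmins). No bonded exclusions apply — the sets must not be covalently
    linked.
    """
    epsilon = model.epsilon if isinstance(model, DielectricModel) else float(model)
    atoms_a = set_a.atoms if isinstance(set_a, AtomSystem) else list(set_a)
    atoms_b = set_b.atoms if isinstance(set_b, AtomSystem) else list(set_b)
    if not atoms_a or not atoms_b:
        return 0.0
    if {a.id for a in atoms_a} & {b.id for b in atoms_b}:
        raise ValueError("atom sets overlap")
    ca, qa, ea, ra = _gather(atoms_a)
    cb, qb, eb, rb = _gather(atoms_b)
    return float(_pair_energy_matrix(ca, qa, ea, ra, cb, qb, eb, rb, epsilon).sum())


def _excluded_pairs(system: AtomSystem, policy: str) -> set[tuple[int, int]]:
    """Index pairs (i<j into system.atoms) excluded by bonded topology."""
    if policy == "none":
        return set()
    idx = {a.id: k for k, a in enumerate(system.atoms)}
    excluded: set[tuple[int, int]] = set()

    def _add(i: int, j: int) -> None:
        a, b = idx[i], idx[j]
        if a != b:
            excluded.add((min(a, b), max(a, b)))

    for i, nbrs in system.bonds.items():
        if i not in idx:
            continue
        for j in nbrs:
            if j not in idx:
                continue
            _add(i, j)  # 1-2
            if policy == "1-3":
                for k in system.bonds.get(j, ()):
                    if k in idx and k != i:
                        _add(i, k)
    return excluded


def total_energy(
    system: AtomSystem | list[Atom],
    model: DielectricModel | float = 40.0,
    exclusion_policy: str = "1-3",
) -> float:
    """Total nonbonded energy of one atom set.

    All within-set pairs are summed except those excluded by covalent
    topology: directly bonded (1-2) and geminal (1-3) pairs by default. No
    1-4 scaling is applied.
    """
    if not isinstance(system, AtomSystem):
        system = AtomSystem(atoms=list(system))
    atoms = system.atoms
    if len(atoms) < 2:
        return 0.0
    epsilon = model.epsilon if isinstance(model, DielectricModel) else float(model)
    c, q, e, r = _gather(atoms)
    mat = _pair_energy_matrix(c, q, e, r, c, q, e, r, epsilon, self_matrix=True)
    mask = np.triu(np.ones(mat.shape, dtype=bool), k=1)
    for i, j in _excluded_pairs(system, exclusion_policy):
        mask[i, j] = False
    return float(mat[mask].sum())


class ClassicalBackend:
    """Pairwise Coulomb + LJ evaluator with uniform dielectric screening."""

    def __init__(
        self,
        dielectric: DielectricModel | float = 40.0,
        exclusion_policy: str = "1-3",
    ) -> None:
        self.dielectric = (
            dielectric
            if isinstance(dielectric, DielectricModel)
            else DielectricModel(float(dielectric))
        )
        self.exclusion_policy = exclusion_policy

    def evaluate(self, system: AtomSystem) -> float:
        return total_energy(system, self.dielectric, self.exclusion_policy)

    @property
    def metadata(self) -> dict:
        return {
            "backend": "classical",
            "epsilon": self.dielectric.epsilon,
            "level": f"Coulomb/LJ, uniform ε={self.dielectric.epsilon:g}, "
            f"exclusions {self.exclusion_policy}",
        }


# ---------------------------------------------------------------------------
# QM deck I/O

DEFAULT_LEVEL = "B97D/6-311+G(d,p)"

_SCF_RE = re.compile(r"SCF Done:[^=\n]*(?:=)?\s*(-?\d+\.\d+)")


def write_qm_deck(
    system: AtomSystem,
    level: str = DEFAULT_LEVEL,
    model: DielectricModel | float = 40.0,
    charge: int | None = None,
    multiplicity: int = 1,
    title: str | None = None,
) -> str:
    """Render a Gaussian-dialect single-point input deck for one system.

    The route line carries the functional/basis from ``level`` plus CPCM
    continuum-solvent keywords; the dielectric is written in the appended
    solvent block. Output is byte-stable for a fixed system.
    """
    epsilon = model.epsilon if isinstance(model, DielectricModel) else float(model)
    if charge is None:
        charge = system.formal_charge
    if charge != int(charge):
        raise ValueError(f"total formal charge must be an integer, got {charge}")
    lines = [
        "%nprocshared=1",
        f"#P {level} SCRF=(CPCM,Read) NoSymm",
        "",
        title or f"pymfcc fragment {system.label or 'system'}",
        "",
        f"{int(charge)} {int(multiplicity)}",
    ]
    for atom in system.atoms:
        x, y, z = atom.coords
        el = atom.element.capitalize()
        lines.append(f"{el:<2} {x:14.8f} {y:14.8f} {z:14.8f}")
    lines += ["", f"Eps={epsilon:g}", "", ""]
    return "\n".join(lines)


def parse_qm_energy(text: str) -> float:
    """Last converged SCF energy of a QM engine log, in kcal·mol⁻¹.

    The engine prints hartree; the return value is converted with the
    package's fixed hartree→kcal·mol⁻¹ factor.
    """
    matches = list(_SCF_RE.finditer(text))
    if not matches:
        raise EnergyParseError("no 'SCF Done' energy line found")
    last = matches[-1]
    tail = text[last.end():]
    if "Convergence failure" in tail or "Error termination" in tail:
        raise EnergyParseError("run did not converge after the last SCF energy")
    return float(last.group(1)) * HARTREE_TO_KCAL


class EnergyCache:
    """CSV-backed energy store keyed by (complex, system label, ε)."""

    COLUMNS = ("complex", "system", "epsilon", "energy_kcal_mol")

    def __init__(self) -> None:
        self._data: dict[tuple[str, str, float], float] = {}

    @classmethod
    def load(cls, path: str | Path) -> "EnergyCache":
        cache = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                cache.put(
                    row["complex"],
                    row["system"],
                    float(row["epsilon"]),
                    float(row["energy_kcal_mol"]),
                )
        return cache

    def save(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(self.COLUMNS)
            for (cx, system, eps), e in sorted(self._data.items()):
                w.writerow([cx, system, repr(eps), repr(e)])

    def put(self, complex_id: str, system: str, epsilon: float, energy: float) -> None:
        self._data[(complex_id, system, float(epsilon))] = energy

    def get(self, complex_id: str, system: str, epsilon: float) -> float | None:
        return self._data.get((complex_id, system, float(epsilon)))

    def __len__(self) -> int:
        return len(self._data)


class CachedQMBackend:
    """Serve fragment energies from an :class:`EnergyCache`; write decks for
    anything missing.

    ``evaluate`` raises ``KeyError`` for an uncached system after writing its
    input deck to ``deck_dir`` (if set), so a campaign driver can submit the
    decks, parse the logs into the cache and re-run.
    """

    def __init__(
        self,
        cache: EnergyCache,
        complex_id: str,
        dielectric: DielectricModel | float = 40.0,
        level: str = DEFAULT_LEVEL,
        deck_dir: str | Path | None = None,
    ) -> None:
        self.cache = cache
        self.complex_id = complex_id
        self.dielectric = (
            dielectric
            if isinstance(dielectric, DielectricModel)
            else DielectricModel(float(dielectric))
        )
        self.level = level
        self.deck_dir = Path(deck_dir) if deck_dir else None

    def evaluate(self, system: AtomSystem) -> float:
        hit = self.cache.get(self.complex_id, system.label, self.dielectric.epsilon)
        if hit is not None:
            return hit
        if self.deck_dir is not None:
            self.deck_dir.mkdir(parents=True, exist_ok=True)
            name = system.label.replace("/", "_") or "system"
            deck = write_qm_deck(system, self.level, self.dielectric)
            (self.deck_dir / f"{name}.gjf").write_text(deck)
        raise KeyError(
            f"no cached energy for {self.complex_id}/{system.label} "
            f"(ε={self.dielectric.epsilon:g})"
        )

    @property
    def metadata(self) -> dict:
        return {
            "backend": "qm-decks",
            "epsilon": self.dielectric.epsilon,
            "level": self.level,
        }
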
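"""Per-residue energy decomposition, radius sweep, convergence, ranking and
ligand-region aggregation.

The driver computes each residue's four-term capped-fragment energy once,
measures its nearest approach to the ligand, then accumulates total binding
energy over concentric nearest-approach shells (0.5 Å steps by default).
Convergence is declared at the smallest radius from which the step-to-step
change in cumulative energy stays below 10% of the running total all the way
to the outer radius — the "stable from here onward" reading, not a one-off
dip below threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energy import ClassicalBackend, EnergyBackend
from .errors import SelectionError
from .fragmentation import CapScheme, FragmentQuadruple, cleave_and_cap
from .structure import ResidueKey, StructureModel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Records and results


@dataclass
class ResidueEnergyRecord:
    """One residue's interaction energy and ligand contact geometry."""

    residue_key: ResidueKey
    label: str
    energy: float
    min_distance: float
    closest_residue_atom: str
    closest_ligand_atom: str
    region: str | None = None
    epsilon: float | None = None


@dataclass
class RadiusSweepResult:
    """Cumulative binding energy as a function of pocket radius.

    ``included_residues[k]`` is the set of residue keys whose nearest approach
    to the ligand is within ``radii[k]``; the sets are nested by construction.
    """

    radii: np.ndarray
    included_residues: list[list[ResidueKey]]
    cumulative_energy: np.ndarray
    convergence_radius: float | None
    records: list[ResidueEnergyRecord]
    metadata: dict = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        """Total binding energy over every residue within the outer radius."""
        return float(self.cumulative_energy[-1]) if len(self.radii) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius": self.radii,
                "n_residues": [len(s) for s in self.included_residues],
                "cumulative_energy": self.cumulative_energy,
            }
        )

    def records_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": r.residue_key[0],
                "residue": r.label,
                "seq_number": r.residue_key[1],
                "energy": r.energy,
                "min_distance": r.min_distance,
                "closest_residue_atom": r.closest_residue_atom,
                "closest_ligand_atom": r.closest_ligand_atom,
                "region": r.region,
                "epsilon": r.epsilon,
            }
            for r in rank_residues(self.records)
        ]
        return pd.DataFrame(rows)

    def summary(self, top: int = 10) -> str:
        lines = [
            "Radius sweep summary",
            "--------------------",
            f"residues evaluated : {len(self.records)}",
            f"outer radius       : {self.radii[-1]:.1f} Å" if len(self.radii) else "",
            f"total energy       : {self.total_energy:.2f} kcal/mol",
            f"convergence radius : "
            + (f"{self.convergence_radius:.1f} Å" if self.convergence_radius else "not reached"),
            "",
            f"top {top} residues by attraction:",
        ]
        for rec in rank_residues(self.records)[:top]:
            region = f"  region {rec.region}" if rec.region else ""
            lines.append(
                f"  {rec.label:<8} {rec.energy:8.2f} kcal/mol   "
                f"{rec.min_distance:5.2f} Å{region}"
            )
        return "\n".join(x for x in lines if x != "")


# ---------------------------------------------------------------------------
# Geometry


def residue_min_distance(
    model: StructureModel,
    residue_key: ResidueKey,
    include_hydrogens: bool = True,
) -> tuple[float, str, str]:
    """Nearest approach between a residue and the ligand.

    Returns (distance Å, residue atom name, ligand atom name); exact ties
    resolve to the lowest atom ids. Hydrogens count by default — contact
    distances are meant to reflect the closest atoms actually present.
    """
    res_atoms = sorted(model.residue_atoms(residue_key), key=lambda a: a.id)
    lig_atoms = sorted(model.ligand_atoms(), key=lambda a: a.id)
    if not include_hydrogens:
        res_atoms = [a for a in res_atoms if a.element != "H"]
        lig_atoms = [a for a in lig_atoms if a.element != "H"]
    if not res_atoms or not lig_atoms:
        raise ValueError("empty atom set in minimum-distance computation")
    d = cdist(
        np.array([a.coords for a in res_atoms]),
        np.array([a.coords for a in lig_atoms]),
    )
    flat = int(np.argmin(d))  # row-major ⇒ lowest residue id, then ligand id
    i, j = divmod(flat, d.shape[1])
    return float(d[i, j]), res_atoms[i].name, lig_atoms[j].name


def radius_schedule(r_max: float, step: float = 0.5) -> np.ndarray:
    """Radii [step, 2·step, …] up to and including r_max."""
    if step <= 0 or r_max < step:
        raise ValueError("need r_max >= step > 0")
    n = int(np.floor(r_max / step + 1e-9))
    return step * np.arange(1, n + 1)


# ---------------------------------------------------------------------------
# Core decomposition


def mfcc_residue_energy(quadruple: FragmentQuadruple, backend: EnergyBackend) -> float:
    """Four-term capped-fragment interaction energy for one residue.

    E(L·C⁻RC⁺) − E(L·C⁻C⁺) − E(C⁻RC⁺) + E(C⁻C⁺): the caps' self-energy and
    their interaction with the ligand cancel, leaving the ligand–residue
    interaction with the residue in its native bonding environment.
    """
    e1 = backend.evaluate(quadruple.sys_l_crc)
    e2 = backend.evaluate(quadruple.sys_l_cc)
    e3 = backend.evaluate(quadruple.sys_crc)
    e4 = backend.evaluate(quadruple.sys_cc)
    return e1 - e2 - e3 + e4


def compute_residue_records(
    model: StructureModel,
    backend: EnergyBackend | None = None,
    scheme: CapScheme | None = None,
    region_map: "RegionMap | None" = None,
    include_hydrogens: bool = True,
) -> list[ResidueEnergyRecord]:
    """One energy/contact record per receptor residue."""
    backend = backend or ClassicalBackend(model.dielectric_default)
    scheme = scheme or CapScheme()
    epsilon = backend.metadata.get("epsilon")
    records = []
    for res in model.residues:
        quad = cleave_and_cap(model, res.key, scheme)
        energy = mfcc_residue_energy(quad, backend)
        dist, res_atom, lig_atom = residue_min_distance(
            model, res.key, include_hydrogens
        )
        rec = ResidueEnergyRecord(
            residue_key=res.key,
            label=res.label,
            energy=energy,
            min_distance=dist,
            closest_residue_atom=res_atom,
            closest_ligand_atom=lig_atom,
            epsilon=epsilon,
        )
        if region_map is not None:
            rec.region = assign_region(rec, region_map, model)
        logger.info(
            "fragment %s: E=%.6f kcal/mol, dmin=%.3f Å (%s–%s)",
            res.label, energy, dist, res_atom, lig_atom,
        )
        records.append(rec)
    return records


def radius_sweep(
    model: StructureModel,
    backend: EnergyBackend | None = None,
    scheme: CapScheme | None = None,
    r_max: float = 10.0,
    step: float = 0.5,
    region_map: "RegionMap | None" = None,
    include_hydrogens: bool = True,
    convergence_threshold: float = 0.10,
) -> RadiusSweepResult:
    """Incremental-radius accumulation of per-residue energies.

    Every residue's energy is computed once; a residue joins the running sum
    at the first radius at least as large as its nearest approach to the
    ligand.
    """
    backend = backend or ClassicalBackend(model.dielectric_default)
    records = compute_residue_records(
        model, backend, scheme, region_map, include_hydrogens
    )
    radii = radius_schedule(r_max, step)
    included: list[list[ResidueKey]] = []
    cumulative = np.zeros(len(radii))
    for k, r in enumerate(radii):
        keys = [rec.residue_key for rec in records if rec.min_distance <= r]
        included.append(keys)
        cumulative[k] = sum(rec.energy for rec in records if rec.min_distance <= r)
    result = RadiusSweepResult(
        radii=radii,
        included_residues=included,
        cumulative_energy=cumulative,
        convergence_radius=None,
        records=records,
        metadata=dict(backend.metadata, r_max=r_max, step=step),
    )
    result.convergence_radius = detect_convergence(result, convergence_threshold)
    return result


def detect_convergence(
    sweep: RadiusSweepResult | tuple,
    threshold: float = 0.10,
) -> float | None:
    """Smallest radius from which consecutive-step energy changes stay below
    ``threshold`` of the running total through the last radius.

    A step with zero total is non-convergent unless the change is also zero.
    Returns None when the criterion is never satisfied persistently.
    """
    if isinstance(sweep, RadiusSweepResult):
        radii, energies = np.asarray(sweep.radii), np.asarray(sweep.cumulative_energy)
    else:
        radii, energies = (np.asarray(x, dtype=float) for x in sweep)
    if len(radii) < 2:
        raise ValueError("need at least two radii")

    def _ok(k: int) -> bool:
        diff = abs(energies[k] - energies[k - 1])
        if diff == 0.0:
            return True
        return diff < threshold * abs(energies[k])

    ok = [_ok(k) for k in range(1, len(radii))]
    # last False step, if any, blocks everything before it
    for k in range(len(ok)):
        if all(ok[k:]):
            return float(radii[k + 1])
    return None


def rank_residues(records: list[ResidueEnergyRecord]) -> list[ResidueEnergyRecord]:
    """Stable sort: most attractive (most negative) first, repulsive last;
    ties broken by residue number."""
    if not records:
        raise ValueError("no records to rank")
    return sorted(records, key=lambda r: (r.energy, r.residue_key[1]))


# ---------------------------------------------------------------------------
# Ligand regions


class RegionMap:
    """Partition of the ligand's heavy atoms into labelled chemical regions."""

    def __init__(self, assignment: dict[str, str]):
        self.assignment = dict(assignment)

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionMap":
        """JSON of either {atom: region} or {region: [atoms]} shape."""
        raw = json.loads(Path(path).read_text())
        first = next(iter(raw.values()), None)
        if isinstance(first, (list, tuple)):
            flat: dict[str, str] = {}
            for region, atoms in raw.items():
                for name in atoms:
                    if name in flat:
                        raise ValueError(f"ligand atom {name!r} assigned twice")
                    flat[name] = region
            return cls(flat)
        return cls(raw)

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def region_of(self, atom_name: str) -> str:
        try:
            return self.assignment[atom_name]
        except KeyError:
            raise SelectionError(f"ligand atom {atom_name!r} has no region") from None

    def validate_partition(self, model: StructureModel) -> None:
        heavy = [a for a in model.ligand_atoms() if a.element != "H"]
        missing = [a.name for a in heavy if a.name not in self.assignment]
        if missing:
            raise SelectionError(f"ligand heavy atoms without a region: {missing}")


def assign_region(
    record: ResidueEnergyRecord,
    region_map: RegionMap,
    model: StructureModel,
) -> str:
    """Region of the ligand atom nearest the residue; a closest hydrogen
    delegates to its bonded heavy atom."""
    atom = next(
        (a for a in model.ligand_atoms() if a.name == record.closest_ligand_atom),
        None,
    )
    if atom is None:
        raise SelectionError(
            f"ligand atom {record.closest_ligand_atom!r} not found in model"
        )
    if atom.element == "H":
        heavy_id = model.bonded_heavy_neighbor(atom.id)
        if heavy_id is None:
            raise SelectionError(f"hydrogen {atom.name} has no bonded heavy atom")
        atom = model.atoms[heavy_id]
    return region_map.region_of(atom.name)


def aggregate_regional_energies(
    records: list[ResidueEnergyRecord],
    region_map: RegionMap | None = None,
    model: StructureModel | None = None,
) -> dict[str, float]:
    """Per-region sums of residue energies; Σ over regions equals Σ over
    records exactly (plain float accumulation in ranked order)."""
    sums: dict[str, float] = {}
    if region_map is not None:
        sums = {label: 0.0 for label in region_map.labels}
    for rec in records:
        region = rec.region
        if region is None:
            if region_map is None or model is None:
                raise ValueError(
                    f"record {rec.label} has no region and no map/model given"
                )
            region = assign_region(rec, region_map, model)
        sums[region] = sums.get(region, 0.0) + rec.energy
    return sums
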
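"""Peptide-bond cleavage, conjugate caps and link-hydrogen placement.

For a residue Rᵢ the decomposition needs four capped systems: the ligand with
the capped residue (L·Cᵢ₋₁RᵢCᵢ₊₁), the ligand with the caps alone
(L·Cᵢ₋₁Cᵢ₊₁), the capped residue alone, and the caps alone. Every covalent
bond cut when carving these systems out of the receptor is saturated by one
hydrogen placed along the cut bond. Cap atoms are *shared by reference*
between the paired systems, so their coordinates are identical bit-for-bit —
the property that makes the four-term combination cancel exactly under a
pairwise-additive backend.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import FragmentationError, GeometryError
from .structure import Atom, AtomSystem, LIGAND_KEY, ResidueKey, Residue, StructureModel
from .structure import RESIDUE_FORMAL_CHARGES

BACKBONE_NAMES = {"N", "H", "CA", "HA", "HA2", "HA3", "C", "O"}


@dataclass
class CapScheme:
    """How conjugate caps are built and dangling valences saturated.

    ``cap_extent='whole_adjacent_residue'`` uses the full neighbouring residue
    as each cap (cut at its distal peptide bond); ``'backbone_only'`` keeps
    just the neighbour's backbone atoms, a cheaper variant. Link-hydrogen bond
    lengths depend on the kept (fragment-side) atom's element. The link-H
    partial charge/LJ parameters default to a generic aliphatic hydrogen; they
    cancel in the four-term combination only approximately for real backends,
    so they are explicit and configurable here.
    """

    cap_extent: str = "whole_adjacent_residue"
    nh_bond_length: float = 1.01
    ch_bond_length: float = 1.09
    sh_bond_length: float = 1.34
    cut_disulfides: bool = True
    link_h_charge: float = 0.09
    link_h_epsilon: float = 0.022
    link_h_rmin_half: float = 1.32

    def __post_init__(self) -> None:
        for L in (self.nh_bond_length, self.ch_bond_length, self.sh_bond_length):
            if not 0.8 < L < 1.8:
                raise ValueError(f"link-H bond length {L} outside (0.8, 1.8) Å")
        if self.cap_extent not in ("whole_adjacent_residue", "backbone_only"):
            raise ValueError(f"unknown cap_extent {self.cap_extent!r}")

    def bond_length_for(self, element: str) -> float:
        return {
            "N": self.nh_bond_length,
            "C": self.ch_bond_length,
            "S": self.sh_bond_length,
        }.get(element, self.ch_bond_length)


@dataclass
class FragmentQuadruple:
    """The four capped atom systems entering the per-residue energy."""

    sys_l_crc: AtomSystem
    sys_l_cc: AtomSystem
    sys_crc: AtomSystem
    sys_cc: AtomSystem
    link_hydrogens: dict[str, list[Atom]] = field(default_factory=dict)
    residue_key: ResidueKey | None = None

    def systems(self) -> dict[str, AtomSystem]:
        return {
            "l_crc": self.sys_l_crc,
            "l_cc": self.sys_l_cc,
            "crc": self.sys_crc,
            "cc": self.sys_cc,
        }


def place_link_hydrogen(
    kept_atom: Atom,
    removed_neighbor: Atom,
    scheme: CapScheme,
    new_id: int = -1,
) -> Atom:
    """Hydrogen on the segment kept→removed at the scheme's bond length."""
    vec = removed_neighbor.coords - kept_atom.coords
    norm = float(np.linalg.norm(vec))
    if norm < 1e-6:
        raise GeometryError(
            f"cannot place link hydrogen: atoms {kept_atom.id} and "
            f"{removed_neighbor.id} are coincident"
        )
    length = scheme.bond_length_for(kept_atom.element)
    return Atom(
        id=new_id,
        element="H",
        name="HL",
        coords=kept_atom.coords + (length / norm) * vec,
        partial_charge=scheme.link_h_charge,
        lj_epsilon=scheme.link_h_epsilon,
        lj_rmin_half=scheme.link_h_rmin_half,
        residue_key=kept_atom.residue_key,
        is_link=True,
    )


class _Fragmenter:
    """Carves capped systems out of one model, caching link hydrogens by cut
    bond so systems that share a cut share the identical hydrogen atom."""

    def __init__(self, model: StructureModel, scheme: CapScheme):
        self.model = model
        self.scheme = scheme
        self._next_id = (max(model.atoms) + 1) if model.atoms else 0
        self._link_cache: dict[tuple[int, int], Atom] = {}

    def link_h(self, kept_id: int, removed_id: int) -> Atom:
        key = (kept_id, removed_id)
        if key not in self._link_cache:
            h = place_link_hydrogen(
                self.model.atoms[kept_id],
                self.model.atoms[removed_id],
                self.scheme,
                new_id=self._next_id,
            )
            self._next_id += 1
            self._link_cache[key] = h
        return self._link_cache[key]

    def _residue_fragment_ids(self, residue: Residue, as_cap: bool) -> list[int]:
        ids = residue.atom_ids
        if as_cap and self.scheme.cap_extent == "backbone_only":
            ids = [
                i for i in ids if self.model.atoms[i].name in BACKBONE_NAMES
            ]
        return list(ids)

    def build_system(
        self,
        residue_sets: list[tuple[Residue, bool]],
        include_ligand: bool,
        label: str,
    ) -> tuple[AtomSystem, list[Atom]]:
        """Assemble an AtomSystem from (residue, is_cap) picks, saturating
        every bond cut at the selection boundary; returns the link-H list."""
        model, scheme = self.model, self.scheme
        frag_ids: list[int] = []
        for res, as_cap in residue_sets:
            frag_ids.extend(self._residue_fragment_ids(res, as_cap))
        frag_set = set(frag_ids)
        ligand_ids = set(model.ligand.atom_ids) if (include_ligand and model.ligand) else set()

        atoms = [model.atoms[i] for i in frag_ids]
        link_hs: list[Atom] = []
        bonds: dict[int, set[int]] = {i: set() for i in frag_ids}
        for i in frag_ids:
            for j in model.bonds[i]:
                if j in frag_set:
                    bonds[i].add(j)
                elif j not in ligand_ids:
                    ai, aj = model.atoms[i], model.atoms[j]
                    if ai.element == "S" and aj.element == "S" and not scheme.cut_disulfides:
                        raise FragmentationError(
                            f"disulfide {i}-{j} crosses the fragment boundary "
                            "and cut_disulfides is false"
                        )
                    link_hs.append(self.link_h(i, j))
        # de-duplicate (an atom pair produces one cut per direction seen)
        seen: set[int] = set()
        link_hs = [h for h in link_hs if not (h.id in seen or seen.add(h.id))]
        for h in link_hs:
            atoms.append(h)
            kept_id = next(k for (k, r), a in self._link_cache.items() if a.id == h.id)
            bonds.setdefault(h.id, set()).add(kept_id)
            bonds.setdefault(kept_id, set()).add(h.id)

        formal = 0
        for res, as_cap in residue_sets:
            if not (as_cap and self.scheme.cap_extent == "backbone_only"):
                formal += RESIDUE_FORMAL_CHARGES.get(res.name, 0)
        if include_ligand and model.ligand is not None:
            for i in model.ligand.atom_ids:
                atoms.append(model.atoms[i])
            for i in ligand_ids:
                bonds[i] = {j for j in model.bonds[i] if j in ligand_ids}
            formal += model.ligand.formal_charge
        return AtomSystem(atoms=atoms, bonds=bonds, label=label, formal_charge=formal), link_hs


def cleave_and_cap(
    model: StructureModel,
    residue_key: ResidueKey,
    scheme: CapScheme | None = None,
) -> FragmentQuadruple:
    """Build the four capped systems for one residue.

    Chain-interior residues get both conjugate caps; terminal residues only
    the existing-side cap. A residue with no neighbours at all yields empty
    cap systems (with a warning) — its energy reduces to the direct
    ligand–residue term.
    """
    scheme = scheme or CapScheme()
    if model.ligand is not None and residue_key == LIGAND_KEY:
        raise FragmentationError("the ligand cannot be fragmented as a residue")
    residue = model.residue(residue_key)
    frag = _Fragmenter(model, scheme)

    caps: list[tuple[Residue, bool]] = []
    for nb in (residue.n_neighbor, residue.c_neighbor):
        if nb is not None:
            caps.append((model.residue(nb), True))
    if not caps:
        warnings.warn(
            f"residue {residue.label} has no neighbours; caps are empty",
            stacklevel=2,
        )

    crc_sets = [(residue, False)] + caps
    lab = residue.label
    sys_l_crc, h_l_crc = frag.build_system(crc_sets, True, f"{lab}/l_crc")
    sys_crc, h_crc = frag.build_system(crc_sets, False, f"{lab}/crc")
    sys_l_cc, h_l_cc = frag.build_system(caps, True, f"{lab}/l_cc")
    sys_cc, h_cc = frag.build_system(caps, False, f"{lab}/cc")
    return FragmentQuadruple(
        sys_l_crc=sys_l_crc,
        sys_l_cc=sys_l_cc,
        sys_crc=sys_crc,
        sys_cc=sys_cc,
        link_hydrogens={"l_crc": h_l_crc, "l_cc": h_l_cc, "crc": h_crc, "cc": h_cc},
        residue_key=residue_key,
    )


def fragment_model(
    model: StructureModel, scheme: CapScheme | None = None
) -> Iterator[FragmentQuadruple]:
    """Quadruples for every receptor residue, in chain order."""
    scheme = scheme or CapScheme()
    for res in model.residues:
        yield cleave_and_cap(model, res.key, scheme)
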
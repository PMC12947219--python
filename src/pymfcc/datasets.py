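"""Bundled reference data.

``load_alpha1a_rankings`` returns the published per-residue interaction
energies (ε = 40, kcal·mol⁻¹) for the α1A-adrenoceptor bound to
noradrenaline, oxymetazoline and tamsulosin, together with the ligand-region
assignment of each residue (region labels i/ii/iii refer to the ligands'
chemical moieties — e.g. noradrenaline's catechol ring (i) and
β-hydroxyethylamine group (ii)). These are inputs for regional aggregation
and ranking, not values this package computes: the underlying DFT campaign
is external to it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .analysis import ResidueEnergyRecord

COMPLEXES = ("noradrenaline", "oxymetazoline", "tamsulosin")


def load_alpha1a_rankings_frame() -> pd.DataFrame:
    with resources.as_file(
        resources.files("pymfcc.data") / "alpha1a_rankings.csv"
    ) as p:
        return pd.read_csv(p)


def load_alpha1a_rankings() -> dict[str, list[ResidueEnergyRecord]]:
    """Per-complex lists of residue energy records, regions pre-assigned.

    Contact distances are not published numerically, so ``min_distance`` is
    NaN in these records.
    """
    df = load_alpha1a_rankings_frame()
    out: dict[str, list[ResidueEnergyRecord]] = {}
    for complex_name, grp in df.groupby("complex", sort=False):
        out[complex_name] = [
            ResidueEnergyRecord(
                residue_key=("A", int(row.seq_number)),
                label=row.residue,
                energy=float(row.energy),
                min_distance=float("nan"),
                closest_residue_atom="",
                closest_ligand_atom="",
                region=row.region,
                epsilon=40.0,
            )
            for row in grp.itertuples()
        ]
    return out
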
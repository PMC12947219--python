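"""Report rendering and run manifests.

Machine outputs (CSV/JSON) carry full precision so totals re-summed from
disk equal in-memory totals; only the human-readable summary rounds to two
decimals. The manifest records everything needed to re-run a classical
sweep bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .analysis import RadiusSweepResult, RegionMap, aggregate_regional_energies, radius_sweep
from .energy import ClassicalBackend
from .fragmentation import CapScheme


@dataclass
class RunManifest:
    """Provenance of one decomposition run."""

    structure_source: dict
    ligand_code: str
    backend: str
    level: str
    epsilon: float
    cap_scheme: dict
    r_max: float
    step: float
    include_hydrogens: bool = True
    region_map: dict | None = None
    version: str = "0.1.0"
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))


def build_manifest(
    sweep: RadiusSweepResult,
    structure_source: dict,
    ligand_code: str,
    scheme: CapScheme | None = None,
    region_map: RegionMap | None = None,
) -> RunManifest:
    scheme = scheme or CapScheme()
    meta = sweep.metadata
    return RunManifest(
        structure_source=structure_source,
        ligand_code=ligand_code,
        backend=meta.get("backend", "classical"),
        level=meta.get("level", ""),
        epsilon=meta.get("epsilon", 40.0),
        cap_scheme=dataclasses.asdict(scheme),
        r_max=meta.get("r_max", float(sweep.radii[-1])),
        step=meta.get("step", float(sweep.radii[0])),
        region_map=region_map.assignment if region_map else None,
    )


def write_reports(
    sweep: RadiusSweepResult,
    outdir: str | Path,
    regional_sums: dict[str, float] | None = None,
    manifest: RunManifest | None = None,
    plot: bool = False,
) -> dict[str, Path]:
    """Write per-residue, sweep and regional CSVs plus manifest and summary.

    Returns the written paths. ``plot=True`` additionally renders the
    cumulative-energy-vs-radius curve with the convergence radius marked.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["residues"] = outdir / "residues.csv"
    sweep.records_frame().to_csv(paths["residues"], index=False)

    paths["sweep"] = outdir / "sweep.csv"
    sweep.to_frame().to_csv(paths["sweep"], index=False)

    if regional_sums is None and any(r.region for r in sweep.records):
        regional_sums = aggregate_regional_energies(sweep.records)
    if regional_sums is not None:
        paths["regional"] = outdir / "regional.csv"
        pd.DataFrame(
            {"region": list(regional_sums), "energy": list(regional_sums.values())}
        ).to_csv(paths["regional"], index=False)

    if manifest is not None:
        paths["manifest"] = outdir / "manifest.json"
        paths["manifest"].write_text(manifest.to_json())

    paths["summary"] = outdir / "summary.txt"
    paths["summary"].write_text(sweep.summary() + "\n")

    if plot:
        paths["plot"] = outdir / "sweep.png"
        _plot_sweep(sweep, paths["plot"])
    return paths


def _plot_sweep(sweep: RadiusSweepResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(sweep.radii, sweep.cumulative_energy, "o-", ms=3)
    if sweep.convergence_radius is not None:
        ax.axvline(sweep.convergence_radius, ls="--", color="grey")
        ax.annotate(
            f"converged at {sweep.convergence_radius:g} Å",
            (sweep.convergence_radius, ax.get_ylim()[1]),
            fontsize=8, ha="left", va="top",
        )
    ax.set_xlabel("pocket radius r (Å)")
    ax.set_ylabel("total interaction energy (kcal/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rerun_from_manifest(manifest_path: str | Path, outdir: str | Path) -> dict[str, Path]:
    """Re-execute a classical run recorded in a manifest and write reports.

    Supports toy-complex sources (regenerated from their spec) and structure
    files read through the standard readers.
    """
    manifest = RunManifest.from_json(Path(manifest_path).read_text())
    if manifest.backend != "classical":
        raise ValueError("only classical-backend runs can be re-executed directly")
    scheme = CapScheme(**manifest.cap_scheme)
    src = manifest.structure_source
    if src.get("kind") == "toy":
        from .synthetic import ToyComplexSpec, generate_toy_complex

        spec_kwargs = dict(src["spec"])
        if isinstance(spec_kwargs.get("distance_range"), list):
            spec_kwargs["distance_range"] = tuple(spec_kwargs["distance_range"])
        model, _ = generate_toy_complex(ToyComplexSpec(**spec_kwargs))
    else:
        from .structure import ParameterTable, assign_parameters, read_structure

        model = read_structure(
            src["path"],
            format_hint=src.get("format", "auto"),
            ligand_code=manifest.ligand_code or None,
        )
        table = ParameterTable.from_csv(src["params"]) if src.get("params") else None
        assign_parameters(model, table)
    region_map = RegionMap(manifest.region_map) if manifest.region_map else None
    sweep = radius_sweep(
        model,
        backend=ClassicalBackend(manifest.epsilon),
        scheme=scheme,
        r_max=manifest.r_max,
        step=manifest.step,
        region_map=region_map,
        include_hydrogens=manifest.include_hydrogens,
    )
    return write_reports(sweep, outdir, manifest=manifest)
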
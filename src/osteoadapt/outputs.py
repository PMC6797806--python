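"""Run artifact writing: trajectory CSV, VTK snapshots, density PNG maps,
config echo and a checksummed manifest.

Density maps use one fixed color scale over [rho_min, rho_max] across all
iterations of a run, so snapshot panels are directly comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .geometry import Mesh
from .remodeling import RemodelingParams
from .simulate import Trajectory
from .vtkio import write_vtk

__all__ = ["write_outputs"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _density_png(path, mesh: Mesh, rho_trab, vmin, vmax, title):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    full = np.full(mesh.n_elements, np.nan)
    full[mesh.trabecular_mask] = rho_trab
    verts = mesh.nodes[mesh.elements]
    fig, ax = plt.subplots(figsize=(7, 5))
    pc = PolyCollection(verts, array=full, cmap="jet", edgecolors="none")
    pc.set_clim(vmin, vmax)
    ax.add_collection(pc)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(title)
    fig.colorbar(pc, ax=ax, label=r"apparent density (g/cm$^3$)")
    fig.savefig(path, dpi=110)
    plt.close(fig)


def write_outputs(
    trajectory: Trajectory,
    mesh: Mesh,
    out_dir,
    formats=("csv", "vtk", "png"),
    params: RemodelingParams | None = None,
    config_echo: dict | None = None,
) -> dict:
    """Write run artifacts and return a manifest {relative path: sha256}.

    A partial write leaves a ``.failed`` marker file in the directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / ".failed"
    marker.write_text("write in progress\n")
    params = params or RemodelingParams()
    written: list[Path] = []
    try:
        if "csv" in formats:
            csv_path = out_dir / "trajectory.csv"
            trajectory.to_dataframe().to_csv(
                csv_path, index=False, float_format="%.10g")
            written.append(csv_path)
        if "vtk" in formats:
            for it, snap in sorted(trajectory.snapshots.items()):
                density = np.full(mesh.n_elements, np.nan)
                stim = np.full(mesh.n_elements, np.nan)
                density[mesh.trabecular_mask] = snap["density"]
                stim[mesh.trabecular_mask] = snap["stimulus"]
                p = write_vtk(
                    out_dir / f"snapshot_{it:04d}.vtk", mesh,
                    cell_data={
                        "region": mesh.region.astype(int),
                        "density": np.nan_to_num(density, nan=-1.0),
                        "stimulus": np.nan_to_num(stim, nan=-1.0),
                    },
                )
                written.append(p)
        if "png" in formats:
            for it, snap in sorted(trajectory.snapshots.items()):
                p = out_dir / f"density_{it:04d}.png"
                _density_png(p, mesh, snap["density"], params.rho_min,
                             params.rho_max, f"apparent density, iteration {it}")
                written.append(p)
        if config_echo is not None:
            import yaml

            p = out_dir / "config_echo.yaml"
            p.write_text(yaml.safe_dump(config_echo, sort_keys=True))
            written.append(p)
        log = out_dir / "run.log"
        log.write_text(
            f"iterations: {trajectory.iterations}\n"
            f"termination: {trajectory.termination_reason}\n"
            f"final mean density: {trajectory.mean_density[-1]:.6g} g/cm^3\n")
        written.append(log)
        manifest = {p.name: _sha256(p) for p in written}
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except BaseException:
        marker.write_text("write failed\n")
        raise
    marker.unlink()
    return manifest
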
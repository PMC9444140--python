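"""Reduction of fields to reported quantities and standard outputs.

Region statistics are volume weighted with the axisymmetric cell
measure 2*pi*r*dr*dz; "mean +/- SD" is the weighted mean and weighted
standard deviation over the cells of a region at one instant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import Mesh, REGION_CODES, LUMEN, TISSUE
from .transport import ConcentrationField
from .hemodynamics import FlowField
from . import vtkio


@dataclass(frozen=True)
class RegionSummary:
    """Volume-weighted concentration statistics of one region."""

    region: str
    mean: float     # mol/m^3
    sd: float       # mol/m^3
    time: float     # s


def _weighted_stats(values: np.ndarray, weights: np.ndarray):
    mean = float(np.average(values, weights=weights))
    var = float(np.average((values - mean) ** 2, weights=weights))
    return mean, np.sqrt(max(var, 0.0))


def _region_code(region) -> int:
    if isinstance(region, str):
        if region not in REGION_CODES:
            raise ValueError(f"unknown region '{region}'")
        return REGION_CODES[region]
    return int(region)


def region_average(c: ConcentrationField, mesh: Mesh,
                   region) -> RegionSummary:
    """Volume-weighted mean and SD of concentration over a region."""
    code = _region_code(region)
    m = mesh.region_mask(code)
    if not m.any():
        raise ValueError(f"region '{region}' has no cells on this mesh")
    mean, sd = _weighted_stats(c.c[m], mesh.cell_volumes[m])
    name = region if isinstance(region, str) else \
        {v: k for k, v in REGION_CODES.items()}[code]
    return RegionSummary(region=str(name), mean=mean, sd=sd, time=c.timestamp)


def velocity_stats(flow: FlowField, mesh: Mesh, region) -> tuple[float, float]:
    """Volume-weighted mean and SD of the speed |u| over a region."""
    code = _region_code(region)
    m = mesh.region_mask(code)
    if not m.any():
        raise ValueError(f"region '{region}' has no cells on this mesh")
    return _weighted_stats(flow.speed()[m], mesh.cell_volumes[m])


def axial_profile(c: ConcentrationField, mesh: Mesh
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Concentration along the mid-axis and radially at mid-length.

    Returns two tables: ``axial`` samples the innermost cell ring
    (r -> 0) along z; ``radial`` samples all layers at the axial
    mid-plane.  Distances in micrometres, concentrations in mM.
    """
    axial = pd.DataFrame({
        "z_um": mesh.z_centers * 1e6,
        "c_mM": c.c[0, :],
    })
    j_mid = mesh.nz // 2
    radial = pd.DataFrame({
        "r_um": mesh.r_centers * 1e6,
        "region": [str(r) for r in mesh.region_of_ring],
        "c_mM": c.c[:, j_mid],
    })
    return axial, radial


def radial_velocity_profile(flow: FlowField, mesh: Mesh,
                            z: float | None = None) -> pd.DataFrame:
    """Radial profile of u_z at an axial station (mid-plane by default)."""
    j = mesh.nz // 2 if z is None else int(np.argmin(np.abs(mesh.z_centers - z)))
    return pd.DataFrame({"r_um": mesh.r_centers * 1e6,
                         "u_z_m_s": flow.u_z[:, j]})


# ---------------------------------------------------------------------------
# result export / reload

_CSV_NAME = "result.csv"
_META_NAME = "metadata.json"


def export_result(result, out_dir: str | Path) -> Path:
    """Write CSV diagnostics, VTK snapshots and JSON metadata.

    Layout: ``result.csv`` (time series of scalar diagnostics with
    columns time_s, mean_lumen_speed_m_s, mean_cII_mM, sd_cII_mM and
    per-region mean/sd columns), ``fields/c_*.vtk`` snapshots,
    ``fields/flow.vtk`` and ``metadata.json``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        cols = {"time_s": result.times,
                "mean_lumen_speed_m_s": result.mean_lumen_speed,
                "mean_cII_mM": result.region_mean["parenchyma"],
                "sd_cII_mM": result.region_sd["parenchyma"]}
        for name in result.region_mean:
            cols[f"mean_c_{name}_mM"] = result.region_mean[name]
            cols[f"sd_c_{name}_mM"] = result.region_sd[name]
        pd.DataFrame(cols).to_csv(out / _CSV_NAME, index=False)
        with open(out / _META_NAME, "w") as fh:
            json.dump(result.metadata, fh, indent=2, default=float)
        fdir = out / "fields"
        fdir.mkdir(exist_ok=True)
        for t, snap in zip(result.snapshot_times, result.snapshots):
            vtkio.write_structured_grid(
                fdir / f"c_{t:07.3f}s.vtk", result.mesh,
                cell_data={"glucose_mM": snap.c,
                           "region": result.mesh.cell_region.astype(float)})
        vtkio.write_structured_grid(
            fdir / "flow.vtk", result.mesh,
            cell_data={"u_r": result.flow_final.u_r,
                       "u_z": result.flow_final.u_z,
                       "p": result.flow_final.p,
                       "region": result.mesh.cell_region.astype(float)})
    except OSError as exc:
        raise OSError(f"failed writing results to '{out}': {exc}") from exc
    return out


def load_scalar_series(out_dir: str | Path) -> pd.DataFrame:
    """Reload the exported scalar time series (round-trip of result.csv)."""
    path = Path(out_dir) / _CSV_NAME
    if not path.exists():
        raise OSError(f"no exported diagnostics at '{path}'")
    return pd.read_csv(path)


def load_metadata(out_dir: str | Path) -> dict:
    path = Path(out_dir) / _META_NAME
    if not path.exists():
        raise OSError(f"no exported metadata at '{path}'")
    with open(path) as fh:
        return json.load(fh)
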
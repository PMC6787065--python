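"""Serialisation of states, results and time series.

NetCDF output goes through xarray's scipy backend (NetCDF3); small runs
can also be written as flat CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .geometry import BoxGeometry
from .state import TRACERS, TracerState

TRACER_UNITS = {
    "dic": "mmol C m-3", "alk": "meq m-3", "po4": "mmol P m-3",
    "no3": "mmol N m-3", "no3_15": "mmol 15N m-3", "fe": "umol Fe m-3",
    "o2": "mmol O2 m-3", "age": "years",
}


def state_to_dataset(state: TracerState, geom: BoxGeometry,
                     time: float | None = None) -> xr.Dataset:
    """One snapshot as an xarray Dataset with box metadata coordinates."""
    coords = {
        "box": ("box", list(geom.tags)),
        "volume": ("box", geom.volume),
        "mid_depth": ("box", geom.mid_depth),
    }
    data = {name: (("box",), getattr(state, name),
                   {"units": TRACER_UNITS[name]})
            for name in TRACERS}
    ds = xr.Dataset(data, coords=coords)
    if time is not None:
        ds = ds.expand_dims(time=[time])
    return ds


def write_state_netcdf(path: str | Path, state: TracerState,
                       geom: BoxGeometry, time: float | None = None) -> None:
    ds = state_to_dataset(state, geom, time)
    ds.to_netcdf(path, engine="scipy")


def read_state_netcdf(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy")


def state_to_frame(state: TracerState, geom: BoxGeometry) -> pd.DataFrame:
    df = pd.DataFrame({name: getattr(state, name) for name in TRACERS},
                      index=pd.Index(geom.tags, name="box"))
    df.insert(0, "volume_m3", geom.volume)
    return df


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    """Annual diagnostic records (from Model.integrate) as a DataFrame."""
    df = pd.DataFrame(records)
    if "t" in df.columns:
        df = df.set_index("t")
    return df


def write_scalars_csv(path: str | Path, records: list[dict]) -> None:
    records_to_frame(records).to_csv(path)


def results_to_frame(results) -> pd.DataFrame:
    """ScenarioResult list to a tidy summary table."""
    return pd.DataFrame([r.summary() for r in results]).set_index("label")


def write_d15n_csv(path: str | Path, result) -> None:
    """Per-region organic delta-15N of one scenario, keyed by region tag."""
    rows = pd.Series(result.d15n_org_regions, name="d15n_org_permil")
    rows.rename_axis("region").to_csv(path)


def geometry_to_config(geom: BoxGeometry) -> dict:
    """Round-trippable configuration dictionary for a geometry."""
    boxes = []
    for i, tag in enumerate(geom.tags):
        boxes.append([tag, geom.volume[i] / 1e16, geom.area[i] / 1e12,
                      float(geom.mid_depth[i]),
                      float(geom.sediment_contact_fraction[i]),
                      float(geom.seafloor_km[i])])
    columns = {}
    for si, path in geom.columns.items():
        columns[geom.tags[si]] = [[geom.tags[b], zt, zb]
                                  for b, zt, zb in path]
    relax = [geom.tags[i] for i in np.flatnonzero(geom.fe_relax_mask)]
    return {"total_volume": geom.total_volume, "boxes": boxes,
            "columns": columns, "fe_relax_boxes": relax}
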
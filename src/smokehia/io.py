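"""Reading and writing the pipeline's file formats.

Gridded fields travel either as long-format CSV (columns ``day, y, x, value``
for daily fields, ``y, x, value`` for static ones; surfaces carry ``mean`` and
``variance`` columns) or as NetCDF with dims ``(day, y, x)`` when a path ends
in ``.nc``. Tables (county rates, tracts, results) are plain CSV; run
manifests are YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .exposure import BackgroundModel, ExposureSurface
from .synthetic_data import PlumeSource, ScenarioData, ScenarioSpec


def surface_to_dataset(surface: ExposureSurface) -> xr.Dataset:
    dims = ("day", "y", "x")
    return xr.Dataset(
        {"mean": (dims, surface.mean), "variance": (dims, surface.variance)},
        coords={"day": surface.days},
        attrs={"method": surface.method, "cell_size_km": surface.cell_size_km},
    )


def dataset_to_surface(ds: xr.Dataset, method: str | None = None) -> ExposureSurface:
    return ExposureSurface(
        method=method or ds.attrs.get("method", "unknown"),
        mean=ds["mean"].values, variance=ds["variance"].values,
        cell_size_km=float(ds.attrs.get("cell_size_km", 1.0)),
        days=ds["day"].values,
    )


def _surface_frame(surface: ExposureSurface) -> pd.DataFrame:
    nd, ny, nx = surface.shape
    day, y, x = np.meshgrid(surface.days, np.arange(ny), np.arange(nx), indexing="ij")
    return pd.DataFrame({
        "day": day.ravel(), "y": y.ravel(), "x": x.ravel(),
        "mean": surface.mean.ravel(), "variance": surface.variance.ravel(),
    })


def write_surface(surface: ExposureSurface, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".nc":
        surface_to_dataset(surface).to_netcdf(path, engine="scipy")
    else:
        _surface_frame(surface).to_csv(path, index=False)


def read_surface(path: str | Path, method: str | None = None) -> ExposureSurface:
    path = Path(path)
    if path.suffix == ".nc":
        with xr.open_dataset(path, engine="scipy") as ds:
            return dataset_to_surface(ds.load(), method)
    df = pd.read_csv(path)
    days = np.sort(df["day"].unique())
    ny, nx = df["y"].max() + 1, df["x"].max() + 1
    mean = np.zeros((len(days), ny, nx))
    var = np.zeros_like(mean)
    day_pos = {d: i for i, d in enumerate(days)}
    ti = df["day"].map(day_pos).to_numpy()
    mean[ti, df["y"], df["x"]] = df["mean"]
    var[ti, df["y"], df["x"]] = df["variance"]
    return ExposureSurface(method=method or "unknown", mean=mean, variance=var, days=days)


def write_field(arr: np.ndarray, path: str | Path) -> None:
    """Write a bare 2-D or 3-D field as long CSV."""
    arr = np.asarray(arr)
    path = Path(path)
    if arr.ndim == 3:
        nd, ny, nx = arr.shape
        day, y, x = np.meshgrid(np.arange(nd), np.arange(ny), np.arange(nx), indexing="ij")
        pd.DataFrame({"day": day.ravel(), "y": y.ravel(), "x": x.ravel(),
                      "value": arr.ravel()}).to_csv(path, index=False)
    elif arr.ndim == 2:
        ny, nx = arr.shape
        y, x = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        pd.DataFrame({"y": y.ravel(), "x": x.ravel(),
                      "value": arr.ravel()}).to_csv(path, index=False)
    else:
        raise ValueError("only 2-D or 3-D fields are supported")


def read_field(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    ny, nx = df["y"].max() + 1, df["x"].max() + 1
    if "day" in df.columns:
        nd = df["day"].max() + 1
        arr = np.zeros((nd, ny, nx))
        arr[df["day"], df["y"], df["x"]] = df["value"]
    else:
        arr = np.zeros((ny, nx))
        arr[df["y"], df["x"]] = df["value"]
    return arr


def spec_to_dict(spec: ScenarioSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["plume_sources"] = [dataclasses.asdict(p) for p in spec.plume_sources]
    return d


def spec_from_dict(d: dict) -> ScenarioSpec:
    d = dict(d)
    plumes = tuple(
        PlumeSource(
            origin=tuple(p["origin"]), start_day=p["start_day"], peak=p["peak"],
            drift=tuple(p["drift"]), spread_km=p["spread_km"],
            decay_days=p.get("decay_days", 7.0),
        )
        for p in d.pop("plume_sources", [])
    ) or None
    kwargs = {k: v for k, v in d.items()}
    if plumes is not None:
        kwargs["plume_sources"] = plumes
    return ScenarioSpec(**kwargs)


def write_scenario(scenario: ScenarioData, out_dir: str | Path) -> None:
    """Write every generated input of a scenario to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, surface in scenario.surfaces.items():
        write_surface(surface, out / f"surface_{name}.csv")
    write_field(scenario.fire_field, out / "fire_field.csv")
    write_field(scenario.nonfire_field, out / "nonfire_field.csv")
    write_field(scenario.ratio_bg.cmaq_fire, out / "cmaq_fire.csv")
    write_field(scenario.ratio_bg.cmaq_back, out / "cmaq_back.csv")
    write_field(scenario.baseline_bg.baseline, out / "baseline.csv")
    write_field(scenario.county_map, out / "county_map.csv")
    scenario.rates.to_csv(out / "rates.csv", index=False)
    scenario.tracts.to_csv(out / "tracts.csv", index=False)
    write_field(scenario.population, out / "population.csv")
    manifest = {"spec": spec_to_dict(scenario.spec),
                "total_population": scenario.total_population}
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_scenario(in_dir: str | Path) -> ScenarioData:
    """Reconstruct a scenario from a directory written by :func:`write_scenario`."""
    src = Path(in_dir)
    manifest = yaml.safe_load((src / "manifest.yaml").read_text())
    spec = spec_from_dict(manifest["spec"])
    surfaces = {}
    for name in spec.method_variance_scale:
        path = src / f"surface_{name}.csv"
        if path.exists():
            surfaces[name] = read_surface(path, method=name)
    fire = read_field(src / "fire_field.csv")
    nonfire = read_field(src / "nonfire_field.csv")
    county_map = read_field(src / "county_map.csv").astype(int)
    population = read_field(src / "population.csv")
    return ScenarioData(
        spec=spec, fire_field=fire, nonfire_field=nonfire,
        truth_total=fire + nonfire, surfaces=surfaces,
        ratio_bg=BackgroundModel(kind="ratio",
                                 cmaq_fire=read_field(src / "cmaq_fire.csv"),
                                 cmaq_back=read_field(src / "cmaq_back.csv")),
        baseline_bg=BackgroundModel(kind="baseline",
                                    baseline=read_field(src / "baseline.csv")),
        county_map=county_map,
        rates=pd.read_csv(src / "rates.csv"),
        tracts=pd.read_csv(src / "tracts.csv"),
        population=population,
        total_population=int(manifest["total_population"]),
    )
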
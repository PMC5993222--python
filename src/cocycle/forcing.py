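"""Synthetic environmental forcing for archetypal water columns.

Stands in for the host ecosystem/circulation model: generates depth-resolved
temperature, oxygen, PAR, bacterial biomass, silicic acid, phytoplankton
biomass and rate fields, plus boundary fluxes, for four archetypes —
an eastern-boundary OMZ margin, an oligotrophic gyre, a cold Arctic shelf,
and a closed well-mixed box.  Profiles use smooth analytic shapes
(exponential PAR decay, Gaussian O2 minimum) so the defining inequalities of
each scenario hold exactly; generation is a pure function of
(name, grid_spec, seed).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import xarray as xr

from .params import ColumnGrid
from .sources import BoundaryForcing

__all__ = [
    "EnvForcing",
    "GridSpec",
    "SCENARIOS",
    "make_scenario",
    "seasonal_factor",
    "seasonally_modulated",
    "write_forcing",
    "read_forcing",
]

SCENARIOS = ("omz_margin", "oligotrophic_gyre", "arctic_shelf", "closed_box")

_ENV_FIELDS = (
    "t", "o2", "par", "bact", "si", "nano_biomass", "diat_biomass",
    "mu_nano", "mu_diat", "graze_rate", "mort_rate", "agg_rate", "remin_rate_c",
)

_UNITS = {
    "t": "degC", "o2": "uM", "par": "W m-2", "bact": "uM C", "si": "uM",
    "nano_biomass": "uM P", "diat_biomass": "uM P",
    "mu_nano": "d-1", "mu_diat": "d-1", "graze_rate": "d-1",
    "mort_rate": "d-1", "agg_rate": "d-1", "remin_rate_c": "d-1",
    "dust_dep": "g m-2 d-1", "river_c_flux": "mol C m-2 d-1",
    "o2_bw": "uM", "sed_fe_flux": "mol Fe m-2 d-1",
    "z_interface": "m", "kz": "m2 d-1", "depth": "m",
}


@dataclass
class GridSpec:
    """Requested vertical discretization; None fields fall back to scenario defaults."""

    depth: float | None = None
    n_layers: int | None = None
    kz: float | None = None  # uniform interior diffusivity override (m^2/day)


@dataclass
class EnvForcing:
    """Per-layer environmental drivers plus the boundary fields.

    Biomasses are in uM P so that quota arithmetic (pM Co / uM P =
    umol Co / mol P) needs no conversion factor.
    """

    t: np.ndarray
    o2: np.ndarray
    par: np.ndarray
    bact: np.ndarray
    si: np.ndarray
    nano_biomass: np.ndarray
    diat_biomass: np.ndarray
    mu_nano: np.ndarray
    mu_diat: np.ndarray
    graze_rate: np.ndarray
    mort_rate: np.ndarray
    agg_rate: np.ndarray
    remin_rate_c: np.ndarray
    boundary: BoundaryForcing = field(default_factory=BoundaryForcing)

    FIELDS = _ENV_FIELDS

    def __post_init__(self) -> None:
        for name in _ENV_FIELDS:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_layers(self) -> int:
        return self.t.size

    def validate(self, grid: ColumnGrid | None = None) -> None:
        n = self.n_layers
        for name in _ENV_FIELDS:
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"forcing field {name!r} has shape {arr.shape}, expected ({n},)")
            if np.any(arr < 0):
                raise ValueError(f"forcing field {name!r} contains negative values")
        if np.any(np.diff(self.par) > 1e-12):
            raise ValueError("PAR must decrease monotonically with depth")
        if grid is not None and grid.n_layers != n:
            raise ValueError(f"forcing has {n} layers but grid has {grid.n_layers}")

    def copy(self) -> "EnvForcing":
        kwargs = {name: getattr(self, name).copy() for name in _ENV_FIELDS}
        kwargs["boundary"] = dataclasses.replace(self.boundary)
        return EnvForcing(**kwargs)


def seasonal_factor(day: float, amplitude: float) -> float:
    """Sinusoidal annual modulation peaking near the boreal summer solstice."""
    return 1.0 + amplitude * np.sin(2.0 * np.pi * (day - 81.0) / 365.0)


def seasonally_modulated(env: EnvForcing, day: float, amplitude: float) -> EnvForcing:
    """Scale PAR, phytoplankton biomass and growth rates by the seasonal factor."""
    if amplitude == 0.0:
        return env
    f = seasonal_factor(day, amplitude)
    out = env.copy()
    for name in ("par", "nano_biomass", "diat_biomass", "mu_nano", "mu_diat"):
        setattr(out, name, getattr(env, name) * f)
    return out


# Scenario defaults: (depth m, n_layers)
_DEFAULT_GRIDS = {
    "omz_margin": (600.0, 60),
    "oligotrophic_gyre": (4000.0, 400),
    "arctic_shelf": (100.0, 10),
    "closed_box": (50.0, 1),
}


def _mixing_profile(z_if_interior: np.ndarray, surface: float, deep: float,
                    scale: float = 75.0) -> np.ndarray:
    """Diffusivity decaying from mixed-layer to interior values (m^2/day)."""
    return deep + (surface - deep) * np.exp(-z_if_interior / scale)


def make_scenario(name: str, grid_spec: GridSpec | None = None, seed: int = 0):
    """Generate (ColumnGrid, EnvForcing, BoundaryForcing) for a named archetype.

    Deterministic for fixed (name, grid_spec, seed); the seed applies small
    (+-2%) multiplicative perturbations to biological and boundary-flux fields,
    leaving the fields with strict scenario-defining inequalities (O2,
    temperature, PAR) untouched.
    """
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {', '.join(SCENARIOS)}")
    spec = grid_spec or GridSpec()
    depth_default, n_default = _DEFAULT_GRIDS[name]
    depth = spec.depth if spec.depth is not None else depth_default
    n = spec.n_layers if spec.n_layers is not None else max(1, int(round(n_default * depth / depth_default)))
    rng = np.random.default_rng(seed)

    def jitter() -> float:
        return float(rng.uniform(0.98, 1.02))

    zi = np.linspace(0.0, depth, n + 1)
    z = 0.5 * (zi[:-1] + zi[1:])
    zi_int = zi[1:-1]

    if name == "closed_box":
        grid = ColumnGrid(zi, np.zeros(n - 1))
        env = EnvForcing(
            t=np.full(n, 20.0),
            o2=np.full(n, 150.0),
            par=np.full(n, 10.0),
            bact=np.full(n, 1.0) * jitter(),
            si=np.full(n, 5.0) * jitter(),
            nano_biomass=np.full(n, 0.02) * jitter(),
            diat_biomass=np.full(n, 0.01) * jitter(),
            mu_nano=np.full(n, 0.5) * jitter(),
            mu_diat=np.full(n, 0.5) * jitter(),
            graze_rate=np.full(n, 0.1),
            mort_rate=np.full(n, 0.05),
            agg_rate=np.full(n, 0.01),
            remin_rate_c=np.full(n, 0.05),
            boundary=BoundaryForcing.zeros(),
        )
    elif name == "omz_margin":
        kz = spec.kz if spec.kz is not None else None
        # vigorous effective mixing of an upwelling margin
        grid = ColumnGrid(zi, np.full(n - 1, kz) if kz is not None
                          else _mixing_profile(zi_int, 60.0, 30.0))
        # Oxycline into an O2 minimum (< 20 uM) that reaches the seafloor:
        # the margin sediments sit in contact with the OMZ, with bottom water
        # between the two sediment-source thresholds (2-50 uM).
        o2 = 15.0 + 215.0 * np.exp(-((z / 150.0) ** 2))
        boundary = BoundaryForcing(
            dust_dep=0.02 * jitter(),
            river_c_flux=1e-5 * jitter(),
            o2_bw=float(o2[-1]),
            sed_fe_flux=5e-8 * jitter(),
        )
        env = EnvForcing(
            t=5.0 + 20.0 * np.exp(-z / 150.0),
            o2=o2,
            par=60.0 * np.exp(-z / 25.0),
            bact=(0.3 + 2.2 * np.exp(-z / 100.0)) * jitter(),
            si=(5.0 + 55.0 * (1.0 - np.exp(-z / 300.0))) * jitter(),
            nano_biomass=0.05 * np.exp(-z / 40.0) * jitter(),
            diat_biomass=0.04 * np.exp(-z / 40.0) * jitter(),
            mu_nano=0.8 * np.exp(-z / 30.0) * jitter(),
            mu_diat=1.0 * np.exp(-z / 30.0) * jitter(),
            graze_rate=np.full(n, 0.15),
            mort_rate=np.full(n, 0.05),
            agg_rate=np.full(n, 0.02),
            remin_rate_c=0.01 + 0.09 * np.exp(-z / 300.0),
            boundary=boundary,
        )
    elif name == "oligotrophic_gyre":
        kz = spec.kz if spec.kz is not None else None
        grid = ColumnGrid(zi, np.full(n - 1, kz) if kz is not None
                          else _mixing_profile(zi_int, 40.0, 2.0))
        o2 = 210.0 - 40.0 * np.exp(-(((z - 800.0) / 600.0) ** 2))  # oxic floor 170 uM
        boundary = BoundaryForcing(
            dust_dep=0.01 * jitter(),
            river_c_flux=0.0,
            o2_bw=float(o2[-1]),
            sed_fe_flux=1e-8 * jitter(),
        )
        env = EnvForcing(
            t=2.0 + 22.0 * np.exp(-z / 300.0),
            o2=o2,
            par=55.0 * np.exp(-z / 30.0),
            bact=(0.1 + 0.9 * np.exp(-z / 150.0)) * jitter(),
            si=(0.5 + 25.0 * (1.0 - np.exp(-z / 1500.0))) * jitter(),
            nano_biomass=0.01 * np.exp(-z / 60.0) * jitter(),
            diat_biomass=0.002 * np.exp(-z / 60.0) * jitter(),
            mu_nano=0.5 * np.exp(-z / 40.0) * jitter(),
            mu_diat=0.3 * np.exp(-z / 40.0) * jitter(),
            graze_rate=np.full(n, 0.1),
            mort_rate=np.full(n, 0.05),
            agg_rate=np.full(n, 0.01),
            remin_rate_c=0.005 + 0.045 * np.exp(-z / 500.0),
            boundary=boundary,
        )
    else:  # arctic_shelf
        kz = spec.kz if spec.kz is not None else None
        grid = ColumnGrid(zi, np.full(n - 1, kz) if kz is not None
                          else _mixing_profile(zi_int, 30.0, 5.0, scale=40.0))
        o2 = 320.0 - 0.2 * z  # oxic throughout
        boundary = BoundaryForcing(
            dust_dep=0.002 * jitter(),
            river_c_flux=5e-5 * jitter(),
            o2_bw=float(o2[-1]),
            sed_fe_flux=1e-6 * jitter(),
        )
        env = EnvForcing(
            t=0.2 + 0.8 * np.exp(-z / 50.0),  # < 2 degC everywhere
            o2=o2,
            par=25.0 * np.exp(-z / 15.0),
            bact=(0.2 + 0.8 * np.exp(-z / 50.0)) * jitter(),
            si=(8.0 + 0.05 * z) * jitter(),
            nano_biomass=0.03 * np.exp(-z / 30.0) * jitter(),
            diat_biomass=0.05 * np.exp(-z / 30.0) * jitter(),
            mu_nano=0.4 * np.exp(-z / 25.0) * jitter(),
            mu_diat=0.6 * np.exp(-z / 25.0) * jitter(),
            graze_rate=np.full(n, 0.1),
            mort_rate=np.full(n, 0.05),
            agg_rate=np.full(n, 0.03),
            remin_rate_c=np.full(n, 0.04),
            boundary=boundary,
        )
    env.validate(grid)
    return grid, env, env.boundary


# ---------------------------------------------------------------------------
# File I/O

_BOUNDARY_FIELDS = ("dust_dep", "river_c_flux", "o2_bw", "sed_fe_flux")


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    if ext in (".nc", ".cdf", ".netcdf"):
        return "netcdf"
    if ext in (".csv", ".txt"):
        return "csv"
    raise ValueError(f"cannot infer forcing format from {path!r}; pass format=")


def write_forcing(grid: ColumnGrid, env: EnvForcing, path: str,
                  fmt: str | None = None) -> None:
    """Write a forcing column to netCDF (CF-style names/units) or headered CSV."""
    fmt = _infer_format(path, fmt)
    if fmt == "netcdf":
        ds = xr.Dataset(
            {name: ("layer", getattr(env, name)) for name in _ENV_FIELDS}
            | {"z_interface": ("interface", grid.z_interface),
               "kz": ("interface_interior", grid.kz)}
            | {name: ((), getattr(env.boundary, name)) for name in _BOUNDARY_FIELDS},
            coords={"depth": ("layer", grid.z_center)},
        )
        for name, da in ds.variables.items():
            if name in _UNITS:
                da.attrs["units"] = _UNITS[name]
        ds.to_netcdf(path, engine="scipy")
    elif fmt == "csv":
        n = grid.n_layers
        df = pd.DataFrame({"z_top": grid.z_interface[:-1], "z_bot": grid.z_interface[1:]})
        df["kz_below"] = np.append(grid.kz, np.nan)
        for name in _ENV_FIELDS:
            df[name] = getattr(env, name)
        for name in _BOUNDARY_FIELDS:
            df[name] = np.full(n, getattr(env.boundary, name))
        df.to_csv(path, index=False, float_format="%.17g")  # exact float64 round trip
    else:
        raise ValueError(f"unknown forcing format {fmt!r}")


def read_forcing(path: str, fmt: str | None = None):
    """Read a forcing column; returns (ColumnGrid, EnvForcing, BoundaryForcing).

    Missing fields are reported all at once; a non-monotone depth axis raises
    a grid error.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "netcdf":
        with xr.open_dataset(path, engine="scipy") as ds:
            required = list(_ENV_FIELDS) + list(_BOUNDARY_FIELDS) + ["z_interface", "kz"]
            missing = [name for name in required if name not in ds.variables]
            if missing:
                raise ValueError(f"forcing file {path!r} is missing fields: {', '.join(missing)}")
            grid = ColumnGrid(ds["z_interface"].values, ds["kz"].values)
            env_kwargs = {name: ds[name].values.astype(float) for name in _ENV_FIELDS}
            boundary = BoundaryForcing(**{name: float(ds[name].values)
                                          for name in _BOUNDARY_FIELDS})
    elif fmt == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = ["z_top", "z_bot", "kz_below"] + list(_ENV_FIELDS) + list(_BOUNDARY_FIELDS)
        missing = [name for name in required if name not in df.columns]
        if missing:
            raise ValueError(f"forcing file {path!r} is missing fields: {', '.join(missing)}")
        zi = np.append(df["z_top"].to_numpy(float), float(df["z_bot"].iloc[-1]))
        grid = ColumnGrid(zi, df["kz_below"].to_numpy(float)[:-1])
        env_kwargs = {name: df[name].to_numpy(float) for name in _ENV_FIELDS}
        boundary = BoundaryForcing(**{name: float(df[name].iloc[0])
                                      for name in _BOUNDARY_FIELDS})
    else:
        raise ValueError(f"unknown forcing format {fmt!r}")
    env = EnvForcing(**env_kwargs, boundary=boundary)
    env.validate(grid)
    return grid, env, boundary
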
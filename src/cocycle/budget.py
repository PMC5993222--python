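"""Flux budgets, residence times, and the sensitivity-experiment suite.

Budgets time-average the stored process-flux snapshots over the final window
of a run, integrate them over depth strata split at configurable horizons
(default 100 m and 250 m), and combine them with the dissolved-Co inventory
into residence times (inventory / total external input).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PM_M_TO_MOL_M2, CoParams, ScenarioConfig, EXPERIMENTS
from .simulator import RunResult, run

__all__ = [
    "FluxBudget",
    "ExperimentTable",
    "integrate_budget",
    "residence_time",
    "run_experiment_suite",
    "write_budget",
    "read_budget",
]

DAYS_PER_YEAR = 365.0

_PROCESSES = ("dust", "sediment", "river", "uptake", "recycling",
              "regeneration", "scavenging", "dissolution")


def residence_time(inventory: float, total_input: float) -> float:
    """Residence time (years) = standing inventory / total input flux."""
    if total_input <= 0:
        raise ValueError("residence time undefined for nonpositive total input")
    return inventory / total_input


def _strata(grid, horizons):
    """(labels, layer masks) for 0-h1, h1-h2, ..., >hN strata by layer center."""
    edges = [0.0, *sorted(horizons), np.inf]
    zc = grid.z_center
    labels, masks = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (zc > lo) & (zc <= hi) if lo > 0 else (zc <= hi)
        label = f"{lo:g}-{hi:g} m" if np.isfinite(hi) else f">{lo:g} m"
        labels.append(label)
        masks.append(mask)
    return labels, masks


@dataclass
class FluxBudget:
    """Depth/time-integrated process fluxes, inventories, and residence times.

    ``table`` has one row per process (mol/m^2/yr) with one column per depth
    stratum plus a total; ``inventory`` is dissolved Co (mol/m^2) per stratum.
    """

    table: pd.DataFrame
    inventory: dict
    residence_time_years: float
    residence_by_stratum: dict
    horizons: list
    sinking_at_horizon: dict = field(default_factory=dict)  # mol/m^2/yr
    burial: float = 0.0                                     # mol/m^2/yr
    window_days: tuple = (0.0, 0.0)

    @property
    def total_input(self) -> float:
        return float(self.table.loc[["dust", "sediment", "river"], "total"].sum())


def integrate_budget(result: RunResult, horizons=(100.0, 250.0),
                     window_frac: float = 0.1) -> FluxBudget:
    """Budget from the final ``window_frac`` of a run's stored snapshots.

    Process fluxes (pM/day per layer) are averaged over the window, converted
    to mol/m^2/yr, and integrated per depth stratum; boundary inputs come from
    the run's exact cumulative accounting.  Residence times are reported for
    the whole column and per stratum (stratum inventory over external input
    into that stratum, ignoring vertical exchange).
    """
    if len(result.states) == 0:
        raise ValueError("run result holds no snapshots")
    times = result.times
    t_end = times[-1]
    t_start = t_end - window_frac * (t_end - times[0])
    sel = np.flatnonzero(times >= t_start - 1e-9)
    if sel.size == 0:
        sel = np.array([len(times) - 1])

    grid = result.grid
    dz = grid.dz
    labels, masks = _strata(grid, horizons)

    def window_mean(attr, source) -> np.ndarray:
        return np.mean([np.asarray(getattr(source[i], attr), dtype=float)
                        for i in sel], axis=0)

    mean_rates = {
        "uptake": window_mean("up_co_d", result.rates) + window_mean("up_co_n", result.rates),
        "recycling": window_mean("excret_co", result.rates),
        "regeneration": (window_mean("remin_co_s", result.rates)
                         + window_mean("remin_co_b", result.rates)),
        "scavenging": window_mean("scav_co", result.rates),
        "dissolution": window_mean("dissol_co", result.rates),
    }

    duration = max(result.duration_days, 1e-30)
    mean_inputs = {k: v / duration * DAYS_PER_YEAR
                   for k, v in result.cumulative_inputs.items()}  # mol/m^2/yr

    rows = {}
    for name in _PROCESSES:
        per_stratum = []
        for mask in masks:
            if name in mean_rates:
                flux = float(np.sum(mean_rates[name][mask] * dz[mask])
                             * PM_M_TO_MOL_M2 * DAYS_PER_YEAR)
            elif name in ("dust", "river"):
                flux = mean_inputs[name] if mask[0] else 0.0
            else:  # sediment enters the bottom layer
                flux = mean_inputs["sediment"] if mask[-1] else 0.0
            per_stratum.append(flux)
        rows[name] = per_stratum + [sum(per_stratum)]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=labels + ["total"])

    mean_dco = window_mean("dco", result.states)
    inventory = {label: float(np.sum(mean_dco[mask] * dz[mask]) * PM_M_TO_MOL_M2)
                 for label, mask in zip(labels, masks)}
    inventory["total"] = float(sum(inventory.values()))

    total_input = float(table.loc[["dust", "sediment", "river"], "total"].sum())
    tau = residence_time(inventory["total"], total_input) if total_input > 0 else np.nan
    tau_stratum = {}
    for label in labels:
        inp = float(table.loc[["dust", "sediment", "river"], label].sum())
        tau_stratum[label] = inventory[label] / inp if inp > 0 else np.nan

    # sinking flux across each horizon from the window-mean particulate fields
    sinking = {}
    mean_fields = {name: window_mean(name, result.states)
                   for name in ("scco", "pco_s", "pco_b")}
    speeds = {"scco": result.params.w_scco, "pco_s": result.params.w_pcos,
              "pco_b": result.params.w_pcob}
    for h in horizons:
        idx = int(np.searchsorted(grid.z_interface, h, side="right")) - 1
        idx = min(max(idx, 0), grid.n_layers - 1)
        sinking[float(h)] = float(sum(speeds[nm] * mean_fields[nm][idx]
                                      for nm in speeds) * PM_M_TO_MOL_M2 * DAYS_PER_YEAR)

    burial = float(sum(result.cumulative_burial.values()) / duration * DAYS_PER_YEAR)
    return FluxBudget(table=table, inventory=inventory,
                      residence_time_years=float(tau),
                      residence_by_stratum=tau_stratum,
                      horizons=list(horizons), sinking_at_horizon=sinking,
                      burial=burial,
                      window_days=(float(t_start), float(t_end)))


@dataclass
class ExperimentTable:
    """Per-experiment end states, budgets, and deltas against the control."""

    experiments: list
    profiles: pd.DataFrame      # depth x experiment, final dCo (pM)
    summary: pd.DataFrame       # one row per experiment
    budgets: dict               # name -> FluxBudget
    results: dict               # name -> RunResult
    attribution_pct: np.ndarray | None = None  # (dNOSEDOX / dNOSED) x 100 per layer


def run_experiment_suite(base: ScenarioConfig, params: CoParams | None = None,
                         experiments=("CTL", "NODUST", "NOSED", "NOSEDOX",
                                      "NOSEDOXA", "SCAV1", "SCAV2"),
                         horizons=(100.0, 250.0)) -> ExperimentTable:
    """Run the canonical toggle experiments from identical forcing and state.

    All experiments share the forcing generated from ``base`` (same seed) and
    the same initial condition; deltas are reported against the control.  When
    both NOSED and NOSEDOX are present, the per-layer percentage of the
    sediment influence attributable to low-bottom-water-oxygen supply is
    computed as (delta_NOSEDOX / delta_NOSED) x 100.
    """
    params = params or CoParams()
    names = [n.upper() for n in experiments]
    for n in names:
        if n not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {n!r}; choose from {', '.join(EXPERIMENTS)}")

    from .forcing import make_scenario
    grid, env, _ = make_scenario(base.scenario_name, seed=base.seed)

    results, budgets = {}, {}
    for name in names:
        cfg = ScenarioConfig.experiment(name, base)
        results[name] = run(cfg, params, grid=grid, env=env.copy())
        budgets[name] = integrate_budget(results[name], horizons=horizons)

    ctl = results.get("CTL")
    profiles = pd.DataFrame({name: res.dco_profile() for name, res in results.items()},
                            index=pd.Index(grid.z_center, name="depth_m"))
    rows = []
    for name in names:
        res = results[name]
        row = {
            "experiment": name,
            "surface_mean_dco_pM": res.surface_mean_dco(),
            "depth_of_max_dco_m": res.depth_of_max_dco(),
            "inventory_mol_m2": budgets[name].inventory["total"],
            "residence_time_yr": budgets[name].residence_time_years,
        }
        if ctl is not None:
            row["delta_surface_dco_pM"] = (res.surface_mean_dco()
                                           - ctl.surface_mean_dco())
            row["mean_abs_delta_dco_pM"] = float(np.mean(
                np.abs(res.dco_profile() - ctl.dco_profile())))
        rows.append(row)
    summary = pd.DataFrame(rows).set_index("experiment")

    attribution = None
    if ctl is not None and "NOSED" in results and "NOSEDOX" in results:
        d_nosed = results["NOSED"].dco_profile() - ctl.dco_profile()
        d_nosedox = results["NOSEDOX"].dco_profile() - ctl.dco_profile()
        with np.errstate(invalid="ignore", divide="ignore"):
            attribution = np.where(np.abs(d_nosed) > 1e-12,
                                   d_nosedox / np.where(np.abs(d_nosed) > 1e-12,
                                                        d_nosed, 1.0) * 100.0,
                                   np.nan)
    return ExperimentTable(experiments=names, profiles=profiles, summary=summary,
                           budgets=budgets, results=results,
                           attribution_pct=attribution)


def write_budget(obj, path: str) -> None:
    """Write a FluxBudget or ExperimentTable to CSV (units in the header)."""
    if isinstance(obj, FluxBudget):
        df = obj.table.copy()
        df.index.name = "process [mol/m2/yr]"
        inv = pd.DataFrame({col: [obj.inventory.get(col, np.nan)]
                            for col in df.columns},
                           index=pd.Index(["dco_inventory [mol/m2]"],
                                          name=df.index.name))
        tau_row = {col: obj.residence_by_stratum.get(col, np.nan) for col in df.columns}
        tau_row["total"] = obj.residence_time_years
        tau = pd.DataFrame(tau_row, index=pd.Index(["residence_time [yr]"],
                                                   name=df.index.name))
        pd.concat([df, inv, tau]).to_csv(path)
    elif isinstance(obj, ExperimentTable):
        df = obj.summary.copy()
        df.to_csv(path)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")


def read_budget(path: str) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_budget` as a DataFrame."""
    return pd.read_csv(path, index_col=0)
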
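"""Model constants, tracer state, vertical grid, run configuration and mass accounting.

The cobalt model carries six prognostic tracers per layer — dissolved Co (dCo),
scavenged Co (scCo, putatively Mn-oxide associated), Co within diatoms and
nanophytoplankton (phyCo_D, phyCo_N), and small/large particulate organic Co
(pCo_S, pCo_B) — plus an implicit zooplankton Co pool and two diagnostic
speciation fields (ligand-bound Co and inorganic Co').

Units convention: all Co tracers are carried in pM; process fluxes are pM/day
per layer; boundary fluxes are mol/m^2/day and are converted through the
thickness of the receiving layer.  1 pM over 1 m of water is 1e-9 mol/m^2.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

__all__ = [
    "CoParams",
    "TracerState",
    "ColumnGrid",
    "ScenarioConfig",
    "EXPERIMENTS",
    "load_params",
    "dump_params",
    "mass_total",
    "PM_M_TO_MOL_M2",
]

# 1 pM integrated over 1 m of seawater = 1e-12 mol/L * 1000 L/m^3 * 1 m
PM_M_TO_MOL_M2 = 1.0e-9

CO_MOLAR_MASS = 58.933  # g/mol
FE_MOLAR_MASS = 55.845  # g/mol
# Upper continental crust Fe mass fraction (3.52 wt%), same crustal-composition
# compilation that provides the Co mineral fraction of dust.
UPPER_CRUST_FE_MASS_FRACTION = 0.0352


def _default_m_co_fe() -> float:
    """Molar Co/Fe ratio of upper-crustal material.

    Derived from the crustal Co mass fraction used for dust (17.3 ug/g) and the
    upper-crust Fe content; used to benchmark the sedimentary Co flux against
    the sedimentary Fe flux.
    """
    co_mol = 17.3e-6 / CO_MOLAR_MASS
    fe_mol = UPPER_CRUST_FE_MASS_FRACTION / FE_MOLAR_MASS
    return co_mol / fe_mol


@dataclass
class CoParams:
    """Tunable constants of the cobalt model.

    Defaults are the standard control-model values of the global cobalt cycle;
    where two values exist the suffix names the phytoplankton functional type
    (nano / diat).
    """

    # Sediment-source oxygen thresholds (uM O2)
    o2_thres_1: float = 50.0
    o2_thres_2: float = 2.0
    # Maximum Co/P quotas (umol Co / mol P)
    theta_max_nano: float = 150.0
    theta_max_diat: float = 150.0
    # Half saturation for Co uptake (pM Co)
    kdco_nano: float = 50.0
    kdco_diat: float = 80.0
    # Half saturation for the Zn-Co interaction (nM Zn, diatoms only)
    k_zn_co: float = 0.5
    # Scavenging rates (1/day)
    lambda_co_min: float = 0.1e-3
    lambda_co: float = 0.01
    # Scavenging environmental controls
    o2_st: float = 100.0        # uM O2 threshold for scavenging
    k_o2_lambda: float = 25.0   # uM O2 half saturation (scavenging + dissolution)
    k_b_lambda: float = 2.5     # uM C half saturation for bacterial effect
    k_par_lambda: float = 15.0  # W/m^2 half saturation for PAR effect
    # Dissolution of scCo
    o2_dt: float = 50.0             # uM O2 threshold for dissolution
    lambda_max_dissol: float = 0.1  # 1/day maximum scCo dissolution rate
    # Speciation
    col_min: float = 25.0  # pM minimum Co-ligand concentration
    # Zooplankton quota (umol Co / mol P) and remineralization scaling
    theta_zoo: float = 20.0
    phi: float = 1.5
    # Temperature control of Mn-oxidizing bacterial Co oxidation
    q10: float = 2.75
    t_ref: float = 20.0  # degC; Q is a relative modulation, only 10-degC ratios matter
    # Elevated scavenging of high inorganic Co
    co_prime_elevated_thresh: float = 100.0  # pM
    elevated_factor: float = 10.0
    elevated_smooth_pm: float = 0.0  # optional linear blend half-width (pM), off by default
    # External sources
    dust_co_fraction: float = 17.3   # ug Co per g dust
    dust_solubility: float = 0.08
    river_co_c: float = 12.0         # umol Co per mol C
    m_co_fe: float | None = None     # mol Co / mol Fe, crustal benchmark ratio
    sed_lowo2_factor: float = 1000.0
    sed_oxic_factor: float = 25.0
    # Sinking speeds (m/day)
    w_scco: float = 1.0
    w_pcos: float = 2.0
    w_pcob: float = 50.0
    # Zn proxy from silicic acid (nM Zn = slope * uM Si + intercept)
    zn_si_slope: float = 0.065
    zn_si_intercept: float = 0.183
    # Zn-Co uptake scalar bounds
    xi_floor: float = 0.1
    xi_scale: float = 1.3
    # Quota-regulation denominator constant
    quota_denom_const: float = 1.05
    co_molar_mass: float = CO_MOLAR_MASS
    # Implicit zooplankton Co pool turnover to large particles (1/day)
    zoo_turnover: float = 0.05
    # Routing fraction of phytoplankton mortality/aggregation to small particles
    frac_to_small: float = 0.5

    def __post_init__(self) -> None:
        if self.m_co_fe is None:
            self.m_co_fe = _default_m_co_fe()
        self.validate()

    def validate(self) -> None:
        nonneg = [
            "o2_thres_1", "o2_thres_2", "theta_max_nano", "theta_max_diat",
            "lambda_co_min", "lambda_co", "o2_st", "o2_dt", "lambda_max_dissol",
            "col_min", "theta_zoo", "phi", "t_ref", "co_prime_elevated_thresh",
            "dust_co_fraction", "river_co_c", "m_co_fe", "sed_lowo2_factor",
            "sed_oxic_factor", "w_scco", "w_pcos", "w_pcob", "zn_si_slope",
            "zn_si_intercept", "xi_floor", "zoo_turnover", "elevated_smooth_pm",
        ]
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be nonnegative, got {getattr(self, name)}")
        positive = [
            "kdco_nano", "kdco_diat", "k_zn_co", "k_o2_lambda", "k_b_lambda",
            "k_par_lambda", "q10", "co_molar_mass", "xi_scale",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {getattr(self, name)}")
        if not self.o2_thres_2 < self.o2_thres_1:
            raise ValueError(
                f"o2_thres_2 ({self.o2_thres_2}) must be below o2_thres_1 ({self.o2_thres_1})"
            )
        if not 0.0 < self.dust_solubility <= 1.0:
            raise ValueError(f"dust_solubility must lie in (0, 1], got {self.dust_solubility}")
        if not self.xi_floor < self.xi_scale:
            raise ValueError(
                f"xi_floor ({self.xi_floor}) must be below xi_scale ({self.xi_scale})"
            )
        if self.quota_denom_const <= 1.0:
            raise ValueError(f"quota_denom_const must exceed 1, got {self.quota_denom_const}")
        if self.elevated_factor < 1.0:
            raise ValueError(f"elevated_factor must be >= 1, got {self.elevated_factor}")
        if not 0.0 <= self.frac_to_small <= 1.0:
            raise ValueError(f"frac_to_small must lie in [0, 1], got {self.frac_to_small}")


_PARAM_NAMES = {f.name for f in fields(CoParams)}


def load_params(config_text: str) -> CoParams:
    """Build a :class:`CoParams` from a YAML document; omitted keys keep defaults.

    Unknown keys are rejected, malformed documents raise a parse error naming
    the offending line, and invariant violations raise ``ValueError`` naming
    the field.
    """
    try:
        doc = yaml.safe_load(io.StringIO(config_text))
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValueError(f"malformed parameter document{loc}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValueError("parameter document must be a mapping of name: value")
    unknown = sorted(set(doc) - _PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter keys: {', '.join(unknown)}")
    return CoParams(**{k: float(v) for k, v in doc.items()})


def dump_params(params: CoParams) -> str:
    """Serialize the full active parameter set as YAML (round-trips exactly)."""
    data = {f.name: getattr(params, f.name) for f in fields(CoParams)}
    return yaml.safe_dump(data, sort_keys=False)


@dataclass
class ColumnGrid:
    """Vertical discretization: interfaces increase downward from 0 m.

    ``kz`` holds the diffusivity (m^2/day) on the n-1 interior interfaces.
    """

    z_interface: np.ndarray
    kz: np.ndarray

    def __post_init__(self) -> None:
        self.z_interface = np.asarray(self.z_interface, dtype=float)
        self.kz = np.asarray(self.kz, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.z_interface.ndim != 1 or self.z_interface.size < 2:
            raise ValueError("z_interface must be a 1-D array of at least two depths")
        if self.z_interface[0] != 0.0:
            raise ValueError("first interface must sit at 0 m")
        if np.any(np.diff(self.z_interface) <= 0):
            raise ValueError("z_interface must be strictly increasing downward")
        if self.kz.shape != (self.n_layers - 1,):
            raise ValueError(
                f"kz must have n_layers-1={self.n_layers - 1} entries, got {self.kz.shape}"
            )
        if np.any(self.kz < 0):
            raise ValueError("kz must be nonnegative")

    @property
    def n_layers(self) -> int:
        return self.z_interface.size - 1

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_interface)

    @property
    def z_center(self) -> np.ndarray:
        return 0.5 * (self.z_interface[:-1] + self.z_interface[1:])

    @property
    def depth(self) -> float:
        return float(self.z_interface[-1])

    @classmethod
    def uniform(cls, depth: float, n_layers: int, kz: float | np.ndarray = 0.0) -> "ColumnGrid":
        zi = np.linspace(0.0, depth, n_layers + 1)
        kz_arr = np.broadcast_to(np.asarray(kz, dtype=float), (n_layers - 1,)).copy()
        return cls(zi, kz_arr)


_TRACERS = ("dco", "scco", "phyco_d", "phyco_n", "pco_s", "pco_b")


@dataclass
class TracerState:
    """Per-layer concentrations of the six Co tracers plus diagnostics (all pM).

    ``zoo_co`` is the implicit zooplankton Co pool; ``col`` (ligand-bound Co)
    and ``co_prime`` (inorganic Co) are diagnostics refreshed from the forcing.
    """

    dco: np.ndarray
    scco: np.ndarray
    phyco_d: np.ndarray
    phyco_n: np.ndarray
    pco_s: np.ndarray
    pco_b: np.ndarray
    zoo_co: np.ndarray
    col: np.ndarray
    co_prime: np.ndarray

    TRACERS = _TRACERS

    def __post_init__(self) -> None:
        for f in fields(self):
            setattr(self, f.name, np.asarray(getattr(self, f.name), dtype=float))

    @classmethod
    def zeros(cls, n_layers: int) -> "TracerState":
        return cls(*(np.zeros(n_layers) for _ in range(9)))

    @classmethod
    def uniform(cls, n_layers: int, dco: float = 20.0) -> "TracerState":
        st = cls.zeros(n_layers)
        st.dco[:] = dco
        return st

    @property
    def n_layers(self) -> int:
        return self.dco.size

    def copy(self) -> "TracerState":
        return TracerState(*(getattr(self, f.name).copy() for f in fields(self)))

    def validate(self) -> None:
        n = self.n_layers
        for f in fields(self):
            arr = getattr(self, f.name)
            if arr.shape != (n,):
                raise ValueError(f"tracer {f.name!r} has shape {arr.shape}, expected ({n},)")
            if np.any(arr < 0):
                raise ValueError(f"tracer {f.name!r} contains negative values")
        if np.any(self.co_prime > self.dco + 1e-9):
            raise ValueError("co_prime exceeds dco")


EXPERIMENTS = {
    "CTL": {},
    "NODUST": {"dust_on": False},
    "NOSED": {"sed_on": False},
    "NOSEDOX": {"sed_lowo2_enhance_on": False},
    "NOSEDOXA": {"sed_lowo2_shutoff_on": False},
    "SCAV1": {"scav_o2_effect_on": False},
    "SCAV2": {"scav_bact_effect_on": False},
}


@dataclass
class ScenarioConfig:
    """Run control: scenario choice, duration, step, process toggles, output."""

    scenario_name: str = "closed_box"
    years: float = 5.0
    dt: float = 0.25  # days
    dust_on: bool = True
    sed_on: bool = True
    sed_lowo2_enhance_on: bool = True
    sed_lowo2_shutoff_on: bool = True
    scav_o2_effect_on: bool = True
    scav_bact_effect_on: bool = True
    # artifact plumbing: allow pure-transport and pure-kinetics runs
    kinetics_on: bool = True
    diffusion_on: bool = True
    sinking_on: bool = True
    seed: int = 0
    output_path: str | None = None
    output_interval: float = 36.5  # days between stored snapshots
    seasonal_amplitude: float = 0.0  # optional sinusoidal PAR/biomass modulation
    initial_dco: float = 20.0  # pM, uniform initial condition

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.years <= 0:
            raise ValueError("years must be positive")
        if self.output_interval <= 0:
            raise ValueError("output_interval must be positive")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must lie in [0, 1)")

    @classmethod
    def experiment(cls, name: str, base: "ScenarioConfig | None" = None) -> "ScenarioConfig":
        """Configuration for one of the canonical sensitivity experiments."""
        key = name.upper()
        if key not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {name!r}; choose from {', '.join(EXPERIMENTS)}"
            )
        base = base if base is not None else cls()
        return dataclasses.replace(base, **EXPERIMENTS[key])


def mass_total(state: TracerState, grid: ColumnGrid, zoo_co: np.ndarray | None = None) -> float:
    """Total Co in the column (mol/m^2), including the implicit zooplankton pool.

    Sums the six prognostic tracers plus zooplankton Co over all layers and
    converts pM*m to mol/m^2.  Linear in every tracer and in dz.
    """
    zoo = state.zoo_co if zoo_co is None else np.asarray(zoo_co, dtype=float)
    if state.n_layers != grid.n_layers or zoo.shape != (grid.n_layers,):
        raise ValueError(
            f"layer mismatch: state has {state.n_layers}, grid has {grid.n_layers} layers"
        )
    per_layer = zoo.copy()
    for name in _TRACERS:
        per_layer = per_layer + getattr(state, name)
    return float(np.sum(per_layer * grid.dz) * PM_M_TO_MOL_M2)
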
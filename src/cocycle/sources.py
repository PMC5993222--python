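"""External dCo inputs: atmospheric dust, rivers, and sediments.

The sediment source follows a three-regime bottom-water-oxygen rule benchmarked
to the sedimentary Fe flux: suboxic bottom waters release Co from dissolving
Fe/Mn oxides (enhanced flux), near-anoxic bottom waters trap Co in pyrite
(no flux), and oxic bottom waters leak a small desorptive flux.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import CoParams

__all__ = [
    "BoundaryForcing",
    "dust_co_flux",
    "river_co_flux",
    "sediment_co_flux",
]


@dataclass
class BoundaryForcing:
    """Boundary fields the host ocean model would supply.

    dust_dep: dust deposition at the surface (g/m^2/day)
    river_c_flux: riverine organic-carbon delivery (mol C/m^2/day; coastal only)
    o2_bw: bottom-water O2 (uM)
    sed_fe_flux: benchmark sedimentary Fe flux (mol Fe/m^2/day)
    """

    dust_dep: float = 0.0
    river_c_flux: float = 0.0
    o2_bw: float = 0.0
    sed_fe_flux: float = 0.0

    def __post_init__(self) -> None:
        for name in ("dust_dep", "river_c_flux", "o2_bw", "sed_fe_flux"):
            if getattr(self, name) < 0:
                raise ValueError(f"boundary field {name!r} must be nonnegative")

    @classmethod
    def zeros(cls) -> "BoundaryForcing":
        return cls()


def dust_co_flux(dust_dep: float, params: CoParams | None = None) -> float:
    """Soluble Co deposition from dust (mol Co/m^2/day).

    dust [g/m^2/day] x mineral Co fraction [g/g] x solubility / molar mass.
    """
    params = params or CoParams()
    if dust_dep < 0:
        raise ValueError("dust deposition must be nonnegative")
    return dust_dep * params.dust_co_fraction * 1e-6 * params.dust_solubility / params.co_molar_mass


def river_co_flux(river_c_flux: float, params: CoParams | None = None) -> float:
    """Riverine Co delivery (mol Co/m^2/day) at a fixed Co/C molar ratio."""
    params = params or CoParams()
    if river_c_flux < 0:
        raise ValueError("river carbon flux must be nonnegative")
    return river_c_flux * params.river_co_c * 1e-6


def sediment_co_flux(sed_fe_flux: float, o2_bw: float,
                     params: CoParams | None = None, *,
                     sed_on: bool = True,
                     lowo2_enhance_on: bool = True,
                     lowo2_shutoff_on: bool = True) -> float:
    """Sedimentary Co flux (mol Co/m^2/day) from the three-regime O2 rule.

    o2_bw <= o2_thres_2          -> 0 (pyrite trapping; takes precedence)
    o2_bw <= o2_thres_1          -> sed_fe x M x sed_lowo2_factor (suboxic release)
    o2_bw >  o2_thres_1          -> sed_fe x M x sed_oxic_factor (desorptive leak)

    Toggles implement the sensitivity experiments: ``lowo2_enhance_on=False``
    sets the enhancement threshold to 0 (oxic branch everywhere),
    ``lowo2_shutoff_on=False`` sets the shutoff threshold to 0, and
    ``sed_on=False`` zeroes the flux entirely.
    """
    params = params or CoParams()
    if sed_fe_flux < 0 or o2_bw < 0:
        raise ValueError("sediment forcing fields must be nonnegative")
    if not sed_on:
        return 0.0
    thres_1 = params.o2_thres_1 if lowo2_enhance_on else 0.0
    thres_2 = params.o2_thres_2 if lowo2_shutoff_on else 0.0
    base = sed_fe_flux * params.m_co_fe
    if o2_bw <= thres_2:
        return 0.0
    if o2_bw <= thres_1:
        return base * params.sed_lowo2_factor
    return base * params.sed_oxic_factor
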
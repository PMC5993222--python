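"""Stateless rate laws for the internal cobalt cycle.

Speciation, quota-regulated phytoplankton uptake, Mn-oxide-mediated scavenging
and its environmental controls, scCo dissolution, remineralization, and
zooplankton excretion.  Every function accepts scalars or per-layer arrays and
has no side effects; the column simulator composes them into tendencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from .params import CoParams

logger = logging.getLogger(__name__)

__all__ = [
    "ProcessRates",
    "zn_from_si",
    "xi_zn",
    "ligand_conc",
    "co_prime",
    "uptake_rate",
    "temp_factor",
    "k_o2_scav",
    "k_bact",
    "k_par",
    "scav_specific_rate",
    "scav_loss",
    "dissol_specific_rate",
    "remin_flux",
    "zoo_excretion",
]


@dataclass
class ProcessRates:
    """Per-layer process fluxes (pM/day) and specific rates (1/day)."""

    up_co_d: np.ndarray
    up_co_n: np.ndarray
    scav_co: np.ndarray
    dissol_co: np.ndarray
    remin_co_s: np.ndarray
    remin_co_b: np.ndarray
    excret_co: np.ndarray
    lambda_spec: np.ndarray
    lambda_dissol_spec: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "ProcessRates":
        return cls(*(np.zeros(n) for _ in range(9)))

    def copy(self) -> "ProcessRates":
        return ProcessRates(*(np.asarray(getattr(self, f.name), dtype=float).copy()
                              for f in fields(self)))


def zn_from_si(si, params: CoParams | None = None):
    """Total Zn (nM) from silicic acid (uM) via the linear Si proxy."""
    params = params or CoParams()
    si = np.asarray(si, dtype=float)
    if np.any(si < 0):
        raise ValueError("silicic acid concentration must be nonnegative")
    return params.zn_si_slope * si + params.zn_si_intercept


def xi_zn(zn, params: CoParams | None = None):
    """Zn-Co interreplacement scalar for diatom Co uptake.

    Co and Zn substitute for one another in carbonic anhydrase, so abundant Zn
    suppresses diatom Co uptake (down to the floor, a 90% reduction at the
    default 0.1) while scarce Zn raises it (up to the 1.3 ceiling).
    """
    params = params or CoParams()
    zn = np.asarray(zn, dtype=float)
    if np.any(zn < 0):
        raise ValueError("Zn concentration must be nonnegative")
    return np.maximum(params.xi_floor,
                      params.xi_scale * (1.0 - zn / (zn + params.k_zn_co)))


def ligand_conc(nano_biomass, total_phyto_biomass, dco, params: CoParams | None = None):
    """Diagnostic Co-ligand concentration (pM).

    Ligand production is tied to the nanophytoplankton share of total
    phytoplankton biomass (cobalamin-like ligands trace the picocyanobacteria /
    nanophytoplankton community), with an imposed deep-ocean floor ``col_min``
    and a hard cap at dCo: the model permits no excess free ligand.
    """
    params = params or CoParams()
    nano = np.asarray(nano_biomass, dtype=float)
    total = np.asarray(total_phyto_biomass, dtype=float)
    dco = np.asarray(dco, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_nano = np.where(total > 0, nano / np.where(total > 0, total, 1.0), 0.0)
    return np.minimum(dco, np.maximum(params.col_min, f_nano * dco))


def co_prime(dco, col):
    """Inorganic Co (pM): the dCo fraction not bound by strong ligands."""
    return np.maximum(0.0, np.asarray(dco, dtype=float) - np.asarray(col, dtype=float))


def uptake_rate(group: str, bco, theta, mu_max, phyto_p, zn,
                params: CoParams | None = None):
    """Phytoplankton Co uptake (pM/day) for one functional group.

    Monod dependence on the bioavailable pool ``bco`` (dCo for
    nanophytoplankton, Co' for diatoms), hyperbolic down-regulation as the
    cellular Co/P quota ``theta`` approaches its maximum, and the Zn
    interaction scalar for diatoms only.
    """
    params = params or CoParams()
    if group not in ("diatom", "nano"):
        raise ValueError(f"group must be 'diatom' or 'nano', got {group!r}")
    bco = np.asarray(bco, dtype=float)
    theta = np.asarray(theta, dtype=float)
    mu_max = np.asarray(mu_max, dtype=float)
    phyto_p = np.asarray(phyto_p, dtype=float)
    if group == "diatom":
        kd, theta_max = params.kdco_diat, params.theta_max_diat
        xi = xi_zn(zn, params)
    else:
        kd, theta_max = params.kdco_nano, params.theta_max_nano
        xi = 1.0
    if np.any(theta > theta_max):
        logger.warning("Co/P quota exceeds theta_max for %s; uptake clamped to zero", group)
    rel = theta / theta_max
    quota_reg = np.where(rel >= 1.0, 0.0,
                         np.maximum(0.0, 1.0 - rel) / (params.quota_denom_const - np.minimum(rel, 1.0)))
    monod = bco / (bco + kd)
    return mu_max * theta_max * monod * quota_reg * xi * phyto_p


def temp_factor(t, params: CoParams | None = None):
    """Q10 temperature modulation of Mn-oxidizing bacterial Co oxidation."""
    params = params or CoParams()
    t = np.asarray(t, dtype=float)
    return params.q10 ** ((t - params.t_ref) / 10.0)


def k_o2_scav(o2, params: CoParams | None = None):
    """Oxygen control on scavenging, in [0, 1): zero at or below the threshold."""
    params = params or CoParams()
    o2 = np.asarray(o2, dtype=float)
    if np.any(o2 < 0):
        raise ValueError("O2 must be nonnegative")
    excess = np.maximum(0.0, o2 - params.o2_st)
    return excess**2 / (excess**2 + params.k_o2_lambda**2)


def k_bact(bact, params: CoParams | None = None):
    """Bacterial-biomass control on scavenging, in [0, 1)."""
    params = params or CoParams()
    bact = np.asarray(bact, dtype=float)
    if np.any(bact < 0):
        raise ValueError("bacterial biomass must be nonnegative")
    return bact**2 / (bact**2 + params.k_b_lambda**2)


def k_par(par, params: CoParams | None = None):
    """Irradiance control, in [0, 1): photoreduction destroys Mn oxides at high PAR."""
    params = params or CoParams()
    par = np.asarray(par, dtype=float)
    if np.any(par < 0):
        raise ValueError("PAR must be nonnegative")
    return par**2 / (par**2 + params.k_par_lambda**2)


def scav_specific_rate(t, o2, bact, par, params: CoParams | None = None, *,
                       o2_effect: bool = True, bact_effect: bool = True):
    """Specific scavenging rate Lambda (1/day).

    Lambda = lambda_min + lambda_co * Q(T) * kO2 * kBACT * (1 - kPAR);
    the O2 and bacterial factors can be switched to 1 for the SCAV1/SCAV2
    sensitivity experiments.
    """
    params = params or CoParams()
    q = temp_factor(t, params)
    f_o2 = k_o2_scav(o2, params) if o2_effect else 1.0
    f_bact = k_bact(bact, params) if bact_effect else 1.0
    f_par = k_par(par, params)
    return params.lambda_co_min + params.lambda_co * q * f_o2 * f_bact * (1.0 - f_par)


def scav_loss(co_prime_conc, lambda_spec, params: CoParams | None = None):
    """Scavenging flux dCo -> scCo (pM/day): Lambda x Co'.

    Above the elevated threshold (default 100 pM Co') the variable part of the
    rate is multiplied by ``elevated_factor`` (the whole Co' pool is affected
    while above threshold).  An optional linear blend of half-width
    ``elevated_smooth_pm`` smooths the discontinuity; it is off by default.
    """
    params = params or CoParams()
    cop = np.asarray(co_prime_conc, dtype=float)
    lam = np.asarray(lambda_spec, dtype=float)
    variable = np.maximum(0.0, lam - params.lambda_co_min)
    lam_elev = params.lambda_co_min + params.elevated_factor * variable
    w = params.elevated_smooth_pm
    thresh = params.co_prime_elevated_thresh
    if w > 0:
        s = np.clip((cop - (thresh - w)) / (2.0 * w), 0.0, 1.0)
        lam_eff = lam + s * (lam_elev - lam)
    else:
        lam_eff = np.where(cop > thresh, lam_elev, lam)
    return lam_eff * cop


def dissol_specific_rate(par, o2, params: CoParams | None = None):
    """Specific scCo dissolution rate (1/day): active at high light or low O2.

    lambda = lambda_max * max(kPAR, kO2d) with the O2 factor one-sided: it is
    zero at or above the dissolution threshold and grows as O2 falls below it.
    """
    params = params or CoParams()
    o2 = np.asarray(o2, dtype=float)
    if np.any(o2 < 0):
        raise ValueError("O2 must be nonnegative")
    deficit = np.maximum(0.0, params.o2_dt - o2)
    k_o2d = deficit**2 / (deficit**2 + params.k_o2_lambda**2)
    return params.lambda_max_dissol * np.maximum(k_par(par, params), k_o2d)


def remin_flux(pco, remin_rate_c, params: CoParams | None = None):
    """Remineralization of particulate organic Co (pM/day).

    Particulate Co regenerates phi times faster than organic carbon
    (phi = 1.5 by default: 50% faster).
    """
    params = params or CoParams()
    return params.phi * np.asarray(remin_rate_c, dtype=float) * np.asarray(pco, dtype=float)


def zoo_excretion(grazed_co, grazed_p, params: CoParams | None = None):
    """Zooplankton Co excretion (pM/day).

    Grazers hold a fixed Co/P quota; Co grazed in excess of
    theta_zoo x (grazed P) is excreted back to dCo, the remainder is retained
    by the implicit zooplankton pool.
    """
    params = params or CoParams()
    grazed_co = np.asarray(grazed_co, dtype=float)
    grazed_p = np.asarray(grazed_p, dtype=float)
    return np.maximum(0.0, grazed_co - params.theta_zoo * grazed_p)
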
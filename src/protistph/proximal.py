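"""Near-cell (proximal) [H+] from diffusion-limited solute fluxes.

A cell exchanging solutes with still water develops a spherical
diffusion gradient; at the cell surface the steady-state concentration
offset for a solute taken up at Q mol s⁻¹ is −Q/(4π·D·r·Sh), where D is
the solute diffusivity, r the cell radius and Sh ≥ 1 a Sherwood-number
transport enhancement (motility/turbulence; Sh → ∞ collapses the
gradient).  Proximal [H+] is obtained by offsetting bulk DIC and TA
with the surface offsets of DIC and of the TA-affecting nutrients and
re-solving the speciation at the cell surface.

This is the pure-diffusion Sherwood formulation: boundary-layer CO2
hydration kinetics are not modelled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import carbonate
from .carbonate import CarbonateState, ConstantSet, TA_STOICH

__all__ = [
    "ProximalParams",
    "surface_offset",
    "proximal_H",
    "cell_carbon_mol",
    "cells_per_litre",
    "proximal_series",
    "DIFFUSIVITY",
]

#: solute diffusivities at 15 °C (m² s⁻¹); DIC uses a single effective
#: value between those of CO2 and HCO3⁻
DIFFUSIVITY = {"DIC": 1.2e-9, "NH4": 1.5e-9, "NO3": 1.5e-9, "PO4": 0.7e-9}

#: cellular carbon per biovolume (pg C µm⁻³), similar across protists
CARBON_DENSITY_PG_UM3 = 0.2
_MOLAR_MASS_C = 12.011


@dataclass(frozen=True)
class ProximalParams:
    """Geometry, transport and per-cell fluxes for one evaluation.

    ``fluxes`` maps solute name (DIC, NH4, NO3, PO4) to the per-cell
    net uptake in mol s⁻¹ (release = negative uptake).
    """

    radius_m: float
    Sh: float = 1.0
    diffusivity: dict = field(default_factory=lambda: dict(DIFFUSIVITY))
    fluxes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.radius_m > 0.0:
            raise ValueError("cell radius must be positive")
        if not self.Sh >= 1.0:
            raise ValueError("Sherwood factor must be >= 1")
        for name, d in self.diffusivity.items():
            if not d > 0.0:
                raise ValueError(f"diffusivity {name} must be positive")


def surface_offset(flux_per_cell: float, D: float, r: float, Sh: float = 1.0):
    """Surface concentration offset (mol m⁻³) for one solute.

    ``flux_per_cell`` is net uptake in mol s⁻¹ (uptake depletes the
    surface, release enriches it); D in m² s⁻¹, r in m.
    """
    if not r > 0.0:
        raise ValueError("radius must be positive")
    if not D > 0.0:
        raise ValueError("diffusivity must be positive")
    return -flux_per_cell / (4.0 * math.pi * D * r * Sh)


def cell_carbon_mol(ESD_um: float) -> float:
    """Carbon content (mol) of a cell of given ESD, from a fixed
    C-per-biovolume density."""
    vol = math.pi / 6.0 * ESD_um**3
    return vol * CARBON_DENSITY_PG_UM3 * 1e-12 / _MOLAR_MASS_C


def cells_per_litre(biomass_C_uM: float, ESD_um: float) -> float:
    """Population abundance implied by biomass C (µg atom L⁻¹)."""
    return biomass_C_uM * 1e-6 / cell_carbon_mol(ESD_um)


def proximal_H(
    bulk: CarbonateState, params: ProximalParams, constants: ConstantSet
):
    """Proximal (cell-surface) [H+] and pH given the bulk state.

    Surface DIC is bulk DIC plus the DIC offset; surface TA is bulk TA
    plus the charge-balance-weighted nutrient offsets.  The speciation
    is re-solved at the surface values.
    """
    # mol/m3 -> umol/L (== umol/kg under the 1:1 density convention)
    off_dic = 0.0
    f = params.fluxes.get("DIC", 0.0)
    if f != 0.0:
        off_dic = 1000.0 * surface_offset(
            f, params.diffusivity["DIC"], params.radius_m, params.Sh
        )
    dta = 0.0
    for nut, gamma in TA_STOICH.items():
        fn = params.fluxes.get(nut, 0.0)
        if fn != 0.0:
            off = 1000.0 * surface_offset(
                fn, params.diffusivity[nut], params.radius_m, params.Sh
            )
            dta -= gamma * off  # uptake of NO3/PO4 raises surface TA
    dic_s = bulk.DIC + off_dic
    ta_s = bulk.TA + dta
    if dic_s <= 0.0 or ta_s <= 0.0:
        raise ValueError(
            "unphysical flux/size combination: surface DIC or TA "
            f"non-positive (DIC={dic_s:.1f}, TA={ta_s:.1f})"
        )
    surf = carbonate.solve_speciation(dic_s, ta_s, constants)
    return surf.H, surf.pH


def proximal_series(
    biology: dict,
    fluxes: dict,
    bulk_states: list,
    config,
    constants: ConstantSet,
    Sh: float = 1.0,
):
    """Proximal H and pH along a simulation, one value per output step.

    Per-cell fluxes are the population fluxes divided by the cell
    abundance implied by the biomass and the configured ESD.  With no
    cells (or zero flux) the proximal state equals the bulk state.
    """
    r_m = config.ESD * 1e-6 / 2.0
    c_cell = cell_carbon_mol(config.ESD)
    n = len(bulk_states)
    h = np.empty(n)
    ph = np.empty(n)
    # population umol/L/d -> per-cell mol/s
    conv = 1e-6 / 86400.0
    net_dic = (
        fluxes["CO2_external_uptake"]
        - fluxes["basal_respiration_C"]
        - fluxes["SDA_net_external_C"]
    )
    net_nh4 = (
        fluxes["NH4_uptake"]
        - fluxes["SDA_net_external_N"]
        - fluxes["regeneration_NH4"]
    )
    net_no3 = fluxes["NO3_uptake"]
    net_po4 = (
        fluxes["PO4_uptake"]
        - fluxes["SDA_net_external_P"]
        - fluxes["regeneration_PO4"]
    )
    for i, bulk in enumerate(bulk_states):
        biomass = biology["C"][i]
        if biomass <= 0.0:
            h[i], ph[i] = bulk.H, bulk.pH
            continue
        cells = biomass * 1e-6 / c_cell
        per_cell = {
            "DIC": net_dic[i] * conv / cells,
            "NH4": net_nh4[i] * conv / cells,
            "NO3": net_no3[i] * conv / cells,
            "PO4": net_po4[i] * conv / cells,
        }
        params = ProximalParams(radius_m=r_m, Sh=Sh, fluxes=per_cell)
        h[i], ph[i] = proximal_H(bulk, params, constants)
    return h, ph
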
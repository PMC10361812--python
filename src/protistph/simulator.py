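"""Closed-system batch-culture simulation.

A single protist population grows in a water parcel that was initially
in air–sea equilibrium with a stated atmospheric pCO2 but is closed to
gas exchange thereafter.  Light follows a square-wave 0.7:0.3
light:dark cycle.  The biology (one ODE system) is integrated once;
the carbonate chemistry is evaluated strictly downstream for each
initial-pCO2 variant (default 300 and 600 µatm), so the nutrient and
biomass dynamics are identical across variants by construction and the
chemistry differs only through the initial equilibrium.

Biological DIC forcing is the integrated respiration + external SDA
release − external CO2 uptake; total-alkalinity forcing follows from
the net change of the NH4, NO3 and PO4 pools via the charge-balance
stoichiometry (+1, −1, +1 per µmol of NO3, NH4, PO4 uptake).
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import carbonate, proximal
from .functional_types import make_config
from .physiology import (
    DissolvedPools,
    PreyField,
    ProtistConfig,
    ProtistState,
    protist_derivatives,
)

__all__ = [
    "Scenario",
    "SimulationResult",
    "irradiance",
    "build_default_prey",
    "run_scenario",
    "mass_balance",
]

#: state-vector layout for the biological ODE system
_STATE_NAMES = (
    "C", "N", "P", "Chl", "acquired_capacity",
    "prey_C", "prey_N", "prey_P", "prey_Chl",
    "NH4", "NO3", "PO4",
    "DOC", "DON", "DOP",
    "VOC", "VON", "VOP",
    "DIC_biological_delta",
)

REDFIELD_NC = 16.0 / 106.0
REDFIELD_PC = 1.0 / 106.0

#: prey chloroplast content as a fraction of prey C (C-equivalent index)
PREY_CHL_FRACTION = 0.10


def build_default_prey(
    N_target: float = 20.0,
    NC_quality: float = 1.0,
    prey_ESD: float = 5.0,
) -> PreyField:
    """Redfield prey field from a target N content (µg atom N L⁻¹).

    C:N:P = 106:16:1, so ``N_target = 20`` gives the standard prey C
    abundance of 132.5 µg atom L⁻¹ with P = 1.25.  ``NC_quality < 1``
    models poor-quality prey: N:C and P:C are both multiplied by it at
    unchanged prey C (e.g. doubled quantity at half quality keeps the
    absolute prey N and P of the default field).
    """
    if not N_target > 0.0:
        raise ValueError("N_target must be positive")
    prey_c = N_target * 106.0 / 16.0
    return PreyField(
        prey_C=prey_c,
        prey_N=N_target * NC_quality,
        prey_P=N_target / 16.0 * NC_quality,
        prey_Chl=PREY_CHL_FRACTION * prey_c,
        prey_ESD=prey_ESD,
    )


@dataclass
class Scenario:
    """Full initial conditions and forcing for one batch-culture run."""

    config: ProtistConfig
    name: str = ""
    biomass_C_init: float = 0.25  # µg atom C L⁻¹ inoculum
    prey: PreyField = field(default_factory=build_default_prey)
    pools: DissolvedPools = field(default_factory=DissolvedPools)
    PFD_light: float = 500.0  # µmol photons m⁻² s⁻¹
    light_fraction: float = 0.7
    pCO2_init: tuple = (300.0, 600.0)  # µatm
    TA_init: float = 2300.0  # µmol kg⁻¹
    T: float = 15.0  # °C
    S: float = 35.0
    duration: float = 20.0  # d
    dt_out: float = 0.02  # d
    rtol: float = 1e-8
    atol: float = 1e-10
    proximal: bool = False
    sherwood: float = 1.0  # transport enhancement for proximal output

    def __post_init__(self) -> None:
        if not 0.0 < self.light_fraction < 1.0:
            raise ValueError("light_fraction must be in (0, 1)")
        if not self.duration > 0.0:
            raise ValueError("duration must be positive")
        if self.biomass_C_init < 0.0:
            raise ValueError("initial biomass must be non-negative")
        for nm in ("NH4", "NO3", "PO4", "DOC", "DON", "DOP",
                   "VOC", "VON", "VOP"):
            if getattr(self.pools, nm) < 0.0:
                raise ValueError(f"initial pool {nm} must be non-negative")
        if not self.name:
            self.name = self.config.name

    def initial_protist(self) -> ProtistState:
        """Inoculum at Redfield stoichiometry.

        Constitutive phototrophs start half-acclimated (Chl:C at half
        of maximum); non-constitutive types start with no photosystems
        and zero acquired capacity.
        """
        c = self.biomass_C_init
        constitutive = self.config.can_photosynthesize_constitutively
        return ProtistState(
            C=c,
            N=REDFIELD_NC * c,
            P=REDFIELD_PC * c,
            Chl=0.5 * self.config.ChlC_max * c if constitutive else 0.0,
            acquired_capacity=1.0 if constitutive else 0.0,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["config"] = self.config.as_dict()
        d["pCO2_init"] = list(self.pCO2_init)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        ft = d.pop("functional_type", None)
        variant = d.pop("variant", "equal")
        overrides = d.pop("config_overrides", None) or {}
        if ft is not None:
            cfg = make_config(ft, variant=variant, overrides=overrides)
        else:
            cfg = ProtistConfig(**d.pop("config"))
        if "prey" in d and isinstance(d["prey"], dict):
            d["prey"] = PreyField(**d["prey"])
        if "pools" in d and isinstance(d["pools"], dict):
            d["pools"] = DissolvedPools(**d["pools"])
        if "pCO2_init" in d:
            d["pCO2_init"] = tuple(d["pCO2_init"])
        return cls(config=cfg, **d)


def irradiance(t: float, scenario: Scenario) -> float:
    """Square-wave photon flux density at time t (days).

    Light for the first ``light_fraction`` of each day, darkness for
    the remainder.
    """
    if t < 0.0:
        raise ValueError("time must be non-negative")
    frac = t - math.floor(t)
    return scenario.PFD_light if frac < scenario.light_fraction else 0.0


@dataclass
class SimulationResult:
    """Output of one run: biology time series plus per-pCO2 chemistry."""

    time: np.ndarray
    biology: dict  # name -> array over time (identical across variants)
    fluxes: dict  # FluxVector field -> array over time
    chemistry: dict  # pCO2 (float) -> dict of arrays (DIC, TA, H, pH, ...)
    scenario: Scenario
    metadata: dict

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per time x variable x pCO2 variant.

        Biology and flux variables, being variant-independent, carry
        variant = 'shared'.
        """
        frames = []
        for name, arr in {**self.biology, **self.fluxes}.items():
            frames.append(pd.DataFrame(
                {"time": self.time, "variable": name, "value": arr,
                 "pCO2_variant": "shared"}
            ))
        for pco2, chem in self.chemistry.items():
            for name, arr in chem.items():
                frames.append(pd.DataFrame(
                    {"time": self.time, "variable": name, "value": arr,
                     "pCO2_variant": f"p{pco2:g}"}
                ))
        return pd.concat(frames, ignore_index=True)

    def metadata_json(self) -> str:
        return json.dumps(self.metadata, indent=1, default=str)


def _pack(state, prey, pools) -> np.ndarray:
    return np.array([
        state.C, state.N, state.P, state.Chl, state.acquired_capacity,
        prey.prey_C, prey.prey_N, prey.prey_P, prey.prey_Chl,
        pools.NH4, pools.NO3, pools.PO4,
        pools.DOC, pools.DON, pools.DOP,
        pools.VOC, pools.VON, pools.VOP,
        pools.DIC_biological_delta,
    ])


def _unpack(y: np.ndarray, prey_esd: float):
    state = ProtistState(
        C=y[0], N=y[1], P=y[2], Chl=max(0.0, y[3]),
        acquired_capacity=min(1.0, max(0.0, y[4])),
    )
    prey = PreyField(
        prey_C=max(0.0, y[5]), prey_N=max(0.0, y[6]),
        prey_P=max(0.0, y[7]), prey_Chl=max(0.0, y[8]),
        prey_ESD=prey_esd,
    )
    pools = DissolvedPools(
        NH4=max(0.0, y[9]), NO3=max(0.0, y[10]), PO4=max(0.0, y[11]),
        DOC=max(0.0, y[12]), DON=max(0.0, y[13]), DOP=max(0.0, y[14]),
        VOC=max(0.0, y[15]), VON=max(0.0, y[16]), VOP=max(0.0, y[17]),
        DIC_biological_delta=y[18],
    )
    return state, prey, pools


def _evaluate_fluxes(y: np.ndarray, scenario: Scenario, pfd: float):
    state, prey, pools = _unpack(y, scenario.prey.prey_ESD)
    return protist_derivatives(state, pools, prey, scenario.config, pfd)


def _segment_boundaries(scenario: Scenario):
    """Day-fraction breakpoints of the square-wave light forcing."""
    pts = [0.0]
    day = 0
    while True:
        for b in (day + scenario.light_fraction, day + 1.0):
            if b >= scenario.duration:
                pts.append(scenario.duration)
                return pts
            pts.append(b)
        day += 1


def run_scenario(scenario: Scenario) -> SimulationResult:
    """Integrate the biology once and speciate each pCO2 variant.

    The stiff-capable integrator is stopped and restarted at every
    light/dark boundary so the square-wave forcing is never smeared
    across a step.  Carbonate speciation runs downstream at output
    resolution only; there is no feedback to the physiology.
    """
    cfg = scenario.config
    state0 = scenario.initial_protist()
    y0 = _pack(state0, scenario.prey, scenario.pools)
    t_out = np.round(
        np.arange(0.0, scenario.duration + 0.5 * scenario.dt_out,
                  scenario.dt_out),
        10,
    )
    t_out[-1] = min(t_out[-1], scenario.duration)

    def rhs(t, y, pfd):
        _, d_state, d_pools, d_prey = _evaluate_fluxes(y, scenario, pfd)
        return _pack(d_state, d_prey, d_pools)

    ys = np.empty((len(t_out), len(y0)))
    ys[0] = y0
    filled = 1
    y = y0
    bounds = _segment_boundaries(scenario)
    for a, b in zip(bounds[:-1], bounds[1:]):
        pfd = irradiance(0.5 * (a + b), scenario)
        mask = (t_out > a + 1e-12) & (t_out <= b + 1e-12)
        sol = solve_ivp(
            rhs, (a, b), y, method="LSODA", args=(pfd,),
            rtol=scenario.rtol, atol=scenario.atol,
            dense_output=True, max_step=0.25,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed in segment [{a}, {b}] of scenario "
                f"{scenario.name!r}: {sol.message}; last state {sol.y[:, -1]}"
            )
        pts = t_out[mask]
        if len(pts):
            ys[filled:filled + len(pts)] = sol.sol(pts).T
            filled += len(pts)
        y = sol.y[:, -1]
    if filled != len(t_out):
        raise RuntimeError("output grid not fully covered by segments")

    worst = ys[:, :18].min()
    if worst < -1e-6:
        raise RuntimeError(
            f"negative pool excursion beyond tolerance: min={worst:.3e}"
        )
    ys[:, :18] = np.clip(ys[:, :18], 0.0, None)

    biology = {nm: ys[:, i].copy() for i, nm in enumerate(_STATE_NAMES)}

    # flux diagnostics at output resolution
    flux_rows = []
    for t, yrow in zip(t_out, ys):
        pfd = irradiance(min(t, scenario.duration - 1e-9), scenario)
        fl, _, _, _ = _evaluate_fluxes(yrow, scenario, pfd)
        flux_rows.append(fl.as_dict())
    fluxes = {k: np.array([r[k] for r in flux_rows]) for k in flux_rows[0]}

    # downstream carbonate chemistry per pCO2 variant
    k = carbonate.equilibrium_constants(scenario.T, scenario.S)
    p0 = scenario.pools
    ta_delta = carbonate.alkalinity_increment(
        p0.NH4 - biology["NH4"], p0.NO3 - biology["NO3"],
        p0.PO4 - biology["PO4"],
    )
    chemistry = {}
    for pco2 in scenario.pCO2_init:
        base = carbonate.equilibrate_with_atmosphere(pco2, scenario.TA_init, k)
        dic_t = base.DIC + biology["DIC_biological_delta"]
        ta_t = scenario.TA_init + ta_delta
        states = [
            carbonate.solve_speciation(d, a, k) for d, a in zip(dic_t, ta_t)
        ]
        chem = {
            "DIC": dic_t,
            "TA": ta_t,
            "H": np.array([s.H for s in states]),
            "pH": np.array([s.pH for s in states]),
            "pCO2": np.array([s.pCO2 for s in states]),
        }
        if scenario.proximal:
            hp, php = proximal.proximal_series(
                biology, fluxes, states, cfg, k, Sh=scenario.sherwood
            )
            chem["H_proximal"] = hp
            chem["pH_proximal"] = php
        chemistry[float(pco2)] = chem

    metadata = {
        "scenario": scenario.to_dict(),
        "constants": k.as_dict(),
        "constant_formulations": {
            "K0": "Weiss 1974", "K1K2": "Lueker et al. 2000 (total scale)",
            "KB": "Dickson 1990", "KW": "Millero 1995",
            "BT": "Uppstrom 1974",
        },
        "density_convention": "1 umol/kg == 1 umol/L (rho ignored)",
        "integrator": "LSODA, restarted at light/dark boundaries",
    }
    return SimulationResult(
        time=t_out, biology=biology, fluxes=fluxes, chemistry=chemistry,
        scenario=scenario, metadata=metadata,
    )


def mass_balance(result: SimulationResult) -> dict:
    """Max relative deviation of total C, N and P from the initial total.

    Total C counts biomass, prey, DOC, VOC and the biological DIC
    change; N and P analogously include the inorganic pools.  A closed
    run conserves each element to well below 1e-6 relative.
    """
    b = result.biology
    if not len(result.time):
        raise ValueError("empty result")
    tot = {
        "C": b["C"] + b["prey_C"] + b["DOC"] + b["VOC"]
        + b["DIC_biological_delta"],
        "N": b["N"] + b["prey_N"] + b["NH4"] + b["NO3"] + b["DON"] + b["VON"],
        "P": b["P"] + b["prey_P"] + b["PO4"] + b["DOP"] + b["VOP"],
    }
    return {
        el: float(np.max(np.abs(series - series[0])) / abs(series[0]))
        for el, series in tot.items()
    }
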
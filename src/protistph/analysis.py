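"""Desk calculations and run summaries.

The balance-point arithmetic asks how much a mixoplankton must eat for
its phagoheterotrophy to exactly null the DIC drawdown of its
photoautotrophy, and compares that with the ration a pure phagotroph
needs to grow at the same rate.  With assimilation efficiency AE and an
SDA fraction lost on anabolism, growth C per ingested C is
AE·(1 − SDA), so a pure phagotroph growing at µ ingests
µ/(AE·(1 − SDA)) ≈ 1.9 µ at the default AE = 0.75, SDA = 0.30.  A
mixoplankton at the zero-net-DIC point has gross fixation exactly
offsetting its respiratory releases, so *all* of its growth C comes
from assimilated food: ingestion = µ/AE ≈ 1.3 µ — much less, because
the SDA carbon is refixed internally instead of being lost.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .functional_types import make_config
from .simulator import Scenario, SimulationResult, build_default_prey

__all__ = [
    "RunSummary",
    "balance_point",
    "phago_to_fixation_ratio",
    "prey_capture_interval",
    "summarize_run",
    "scenario_presets",
]

_BALANCE_MODES = ("pure_phagotroph", "mixoplankton_zero_net_DIC")


def balance_point(AE: float, SDA: float, mode: str) -> float:
    """C-specific ingestion rate, as a multiple of the growth rate.

    ``pure_phagotroph``: all growth C is assimilated post-SDA food, so
    the multiple is 1/(AE·(1 − SDA)).  ``mixoplankton_zero_net_DIC``:
    gross fixation exactly offsets the SDA + basal respiratory CO2, so
    growth C equals assimilated food C and the multiple is 1/AE.
    """
    if not 0.0 < AE <= 1.0:
        raise ValueError(f"AE must be in (0, 1], got {AE}")
    if not 0.0 <= SDA < 1.0:
        raise ValueError(f"SDA must be in [0, 1), got {SDA}")
    if mode == "pure_phagotroph":
        return 1.0 / (AE * (1.0 - SDA))
    if mode == "mixoplankton_zero_net_DIC":
        return 1.0 / AE
    raise ValueError(f"mode must be one of {_BALANCE_MODES}, got {mode!r}")


def phago_to_fixation_ratio(
    AE: float, SDA: float, basal_respiration_multiple: float
) -> float:
    """Ingested C : gross fixed C at the mixoplankton zero-net-DIC point.

    At that point ingestion I = µ/AE and the gross fixation F must
    offset the SDA release on the retained ration plus basal
    respiration: F = SDA·(AE·I) + basal·µ.  With the defaults
    (AE 0.75, SDA 0.30, basal 0.15 µ) the ratio is ≈ 3 : 1.
    """
    ingestion = balance_point(AE, SDA, "mixoplankton_zero_net_DIC")
    if basal_respiration_multiple < 0.0:
        raise ValueError("basal respiration multiple must be >= 0")
    fixation = SDA * AE * ingestion + basal_respiration_multiple
    if fixation == 0.0:
        raise ZeroDivisionError(
            "no fixation at the balance point (SDA and basal both zero)"
        )
    return ingestion / fixation


def prey_capture_interval(
    pred_ESD: float,
    prey_ESD: float,
    ingestion_multiple: float,
    mu: float,
    interpretation: str = "specific",
) -> float:
    """Minutes per prey item at a given C-specific ingestion rate.

    With equal C-biovolume densities a predator:prey ESD ratio of x
    means each prey carries 1/x³ of the predator's C, so prey items per
    day = multiple·µ·(pred/prey)³ and the capture interval is 1440
    divided by that.  ``interpretation='absolute'`` reads the multiple
    as an absolute d⁻¹ ration instead of a multiple of µ (the two
    readings differ by the factor µ).
    """
    if min(pred_ESD, prey_ESD, ingestion_multiple, mu) <= 0.0:
        raise ValueError("all arguments must be positive")
    if pred_ESD < prey_ESD:
        raise ValueError("predator must be at least prey-sized")
    vol_ratio = (pred_ESD / prey_ESD) ** 3
    if interpretation == "specific":
        prey_per_day = ingestion_multiple * mu * vol_ratio
    elif interpretation == "absolute":
        prey_per_day = ingestion_multiple * vol_ratio
    else:
        raise ValueError("interpretation must be 'specific' or 'absolute'")
    return 1440.0 / prey_per_day


@dataclass
class RunSummary:
    """End-of-simulation aggregates for one scenario x pCO2 variant."""

    scenario: str
    pCO2_init: float
    DIC_initial: float
    DIC_final: float
    delta_DIC: float
    TA_initial: float
    TA_final: float
    pH_initial: float
    pH_final: float
    H_initial: float
    H_final: float
    delta_H: float
    pH_min: float
    pH_max: float
    final_biomass_C: float
    final_biomass_N: float
    final_biomass_P: float
    cumulative_DOC: float
    cumulative_VOC: float
    cumulative_VON: float
    cumulative_VOP: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_run(result: SimulationResult) -> list:
    """One :class:`RunSummary` per pCO2 variant of a completed run."""
    if result.time is None or not len(result.time):
        raise ValueError("empty simulation result")
    if not result.chemistry:
        raise ValueError("result carries no carbonate chemistry")
    b = result.biology
    out = []
    for pco2, chem in sorted(result.chemistry.items()):
        out.append(RunSummary(
            scenario=result.scenario.name,
            pCO2_init=pco2,
            DIC_initial=float(chem["DIC"][0]),
            DIC_final=float(chem["DIC"][-1]),
            delta_DIC=float(chem["DIC"][-1] - chem["DIC"][0]),
            TA_initial=float(chem["TA"][0]),
            TA_final=float(chem["TA"][-1]),
            pH_initial=float(chem["pH"][0]),
            pH_final=float(chem["pH"][-1]),
            H_initial=float(chem["H"][0]),
            H_final=float(chem["H"][-1]),
            delta_H=float(chem["H"][-1] - chem["H"][0]),
            pH_min=float(np.min(chem["pH"])),
            pH_max=float(np.max(chem["pH"])),
            final_biomass_C=float(b["C"][-1]),
            final_biomass_N=float(b["N"][-1]),
            final_biomass_P=float(b["P"][-1]),
            cumulative_DOC=float(b["DOC"][-1]),
            cumulative_VOC=float(b["VOC"][-1]),
            cumulative_VON=float(b["VON"][-1]),
            cumulative_VOP=float(b["VOP"][-1]),
        ))
    return out


def scenario_presets(catalogue_id: str) -> list:
    """Scenario catalogues of the three comparison experiments.

    ``fig3``: the five functional types at defaults.  ``fig4``: CM and
    phytoplankton at 20 and 250 µm ESD with proximal output enabled.
    ``fig5``: the five CM variants — priority to phototrophy, priority
    to phagotrophy, low light (PFD 50), doubled prey, and doubled prey
    of halved N:C and P:C quality.  Every preset carries both pCO2
    variants (300 and 600 µatm).
    """
    if catalogue_id == "fig3":
        return [
            Scenario(config=make_config(ft), name=ft)
            for ft in ("phytoplankton", "zooplankton", "GNCM", "pSNCM", "CM")
        ]
    if catalogue_id == "fig4":
        out = []
        for ft in ("CM", "phytoplankton"):
            for esd in (20.0, 250.0):
                out.append(Scenario(
                    config=make_config(ft, overrides={"ESD": esd}),
                    name=f"{ft}_ESD{esd:g}",
                    proximal=True,
                ))
        return out
    if catalogue_id == "fig5":
        return [
            Scenario(config=make_config("CM", variant="photo_first"),
                     name="CM_photo_first"),
            Scenario(config=make_config("CM", variant="phago_first"),
                     name="CM_phago_first"),
            Scenario(config=make_config("CM"), name="CM_low_PFD",
                     PFD_light=50.0),
            Scenario(config=make_config("CM"), name="CM_prey_quantity",
                     prey=build_default_prey(N_target=40.0)),
            Scenario(config=make_config("CM"),
                     name="CM_prey_quantity_quality",
                     prey=build_default_prey(N_target=40.0, NC_quality=0.5)),
        ]
    raise ValueError(
        f"unknown catalogue {catalogue_id!r}; available: fig3, fig4, fig5"
    )
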
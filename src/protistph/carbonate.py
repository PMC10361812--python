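"""Seawater CO2-system speciation.

Equilibrium constants, the DIC/TA -> [H+] solver, atmospheric
equilibration of a closed water parcel, and the alkalinity increments
that biological nutrient fluxes impose.  This module is operated
strictly *downstream* of the biology: nothing here feeds back into the
physiological rates.

Units
-----
DIC, TA and the carbonate species are in µmol kg⁻¹; [H+] is in
mol kg⁻¹ on the total hydrogen-ion scale; pCO2 is in µatm.  The
density conversion between the biology's µmol L⁻¹ and the chemistry's
µmol kg⁻¹ is taken as 1:1 (ρ ≈ 1.025 ignored), which keeps the closed
mass balance exact in a single unit system.

Constant formulations: Weiss (1974) CO2 solubility; Lueker et al.
(2000) carbonic-acid dissociations (total scale); Dickson (1990) boric
acid; Millero (1995) water; Uppström (1974) total borate from salinity.
The formulation set is recorded in run metadata; fidelity is asserted
against an independent reference calculation, not formulation identity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "ConstantSet",
    "CarbonateState",
    "equilibrium_constants",
    "solve_speciation",
    "equilibrate_with_atmosphere",
    "alkalinity_increment",
]

#: Alkalinity change per µmol of nutrient taken up (release = negative
#: uptake).  Standard charge-balance convention: NO3⁻ removal raises TA,
#: NH4⁺ removal lowers it, phosphate removal raises it by one unit.
TA_STOICH = {"NO3": +1.0, "NH4": -1.0, "PO4": +1.0}

_PH_BRACKET = (2.0, 12.0)  # fixed solver bracket, pH units


@dataclass(frozen=True)
class ConstantSet:
    """Thermodynamic constants of the CO2 system at fixed (T, S).

    K0 in mol kg⁻¹ atm⁻¹; K1, K2, KB, KW in mol kg⁻¹ (total scale);
    BT is total borate in mol kg⁻¹.
    """

    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    BT: float
    T: float
    S: float

    def __post_init__(self) -> None:
        for name in ("K0", "K1", "K2", "KB", "KW", "BT"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0.0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not self.K1 > self.K2:
            raise ValueError("K1 must exceed K2")

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CarbonateState:
    """Speciated state of a water parcel.

    DIC, TA, CO2aq, HCO3, CO3 in µmol kg⁻¹; H in mol kg⁻¹ (total
    scale); pH = −log10 H; pCO2 in µatm.
    """

    DIC: float
    TA: float
    H: float
    pH: float
    CO2aq: float
    HCO3: float
    CO3: float
    pCO2: float

    def as_dict(self) -> dict:
        return asdict(self)


def equilibrium_constants(T: float, S: float) -> ConstantSet:
    """Compute the constant set at temperature T (°C) and salinity S.

    Valid for 0 ≤ T ≤ 40 °C and 20 ≤ S ≤ 40 (the fitting ranges of the
    chosen formulations); out-of-range input is rejected.
    """
    if not 0.0 <= T <= 40.0:
        raise ValueError(f"temperature {T} °C outside supported range [0, 40]")
    if not 20.0 <= S <= 40.0:
        raise ValueError(f"salinity {S} outside supported range [20, 40]")
    TK = T + 273.15
    lnTK = math.log(TK)
    sqS = math.sqrt(S)

    ln_K0 = (
        -60.2409
        + 93.4517 * (100.0 / TK)
        + 23.3585 * math.log(TK / 100.0)
        + S * (0.023517 - 0.023656 * (TK / 100.0) + 0.0047036 * (TK / 100.0) ** 2)
    )
    pK1 = 3633.86 / TK - 61.2172 + 9.67770 * lnTK - 0.011555 * S + 0.0001152 * S * S
    pK2 = 471.78 / TK + 25.9290 - 3.16967 * lnTK - 0.01781 * S + 0.0001122 * S * S
    ln_KB = (
        (-8966.90 - 2890.53 * sqS - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S * S) / TK
        + 148.0248
        + 137.1942 * sqS
        + 1.62142 * S
        + (-24.4344 - 25.085 * sqS - 0.2474 * S) * lnTK
        + 0.053105 * sqS * TK
    )
    ln_KW = (
        148.9802
        - 13847.26 / TK
        - 23.6521 * lnTK
        + (118.67 / TK - 5.977 + 1.0495 * lnTK) * sqS
        - 0.01615 * S
    )
    return ConstantSet(
        K0=math.exp(ln_K0),
        K1=10.0**-pK1,
        K2=10.0**-pK2,
        KB=math.exp(ln_KB),
        KW=math.exp(ln_KW),
        BT=0.0004157 * S / 35.0,
        T=T,
        S=S,
    )


def _speciate_at_H(DIC_mol: float, H: float, k: ConstantSet):
    """Carbonate species (mol/kg) of DIC at hydrogen-ion activity H."""
    den = H * H + k.K1 * H + k.K1 * k.K2
    co2 = DIC_mol * H * H / den
    hco3 = DIC_mol * k.K1 * H / den
    co3 = DIC_mol * k.K1 * k.K2 / den
    return co2, hco3, co3


def _ta_of_H(DIC_mol: float, H: float, k: ConstantSet) -> float:
    """Total alkalinity (mol/kg) implied by (DIC, H)."""
    _, hco3, co3 = _speciate_at_H(DIC_mol, H, k)
    return hco3 + 2.0 * co3 + k.BT * k.KB / (k.KB + H) + k.KW / H - H


def _state_from_H(DIC_mol: float, H: float, k: ConstantSet) -> CarbonateState:
    co2, hco3, co3 = _speciate_at_H(DIC_mol, H, k)
    ta = _ta_of_H(DIC_mol, H, k)
    return CarbonateState(
        DIC=DIC_mol * 1e6,
        TA=ta * 1e6,
        H=H,
        pH=-math.log10(H),
        CO2aq=co2 * 1e6,
        HCO3=hco3 * 1e6,
        CO3=co3 * 1e6,
        pCO2=co2 / k.K0 * 1e6,
    )


def solve_speciation(DIC: float, TA: float, constants: ConstantSet) -> CarbonateState:
    """Solve the TA balance for [H+] at given DIC and TA (µmol kg⁻¹).

    TA(H) = [HCO3] + 2[CO3] + [B(OH)4] + [OH] − [H].  The root is found
    by a bisection-safeguarded Newton iteration on log10 H within the
    fixed bracket pH ∈ [2, 12]; the accepted root satisfies
    |TA(H) − TA|/TA < 1e-9.
    """
    if not DIC > 0.0:
        raise ValueError(f"DIC must be positive, got {DIC}")
    if not TA > 0.0:
        raise ValueError(f"TA must be positive, got {TA}")
    dic_m, ta_m = DIC * 1e-6, TA * 1e-6

    def f(pH: float) -> float:
        return _ta_of_H(dic_m, 10.0**-pH, constants) - ta_m

    lo, hi = _PH_BRACKET
    flo, fhi = f(lo), f(hi)
    # TA(H) decreases with H, so f increases with pH
    if not (flo < 0.0 < fhi):
        raise RuntimeError(
            "speciation solver: no root bracketed in pH [2, 12]; "
            f"f(2)={flo:.3e}, f(12)={fhi:.3e} for DIC={DIC}, TA={TA}"
        )
    pH = 8.0
    for _ in range(100):
        H = 10.0**-pH
        val = f(pH)
        if val > 0.0:
            hi = pH
        else:
            lo = pH
        # analytic derivative of TA wrt pH: dTA/dpH = dTA/dH * dH/dpH
        den = H * H + constants.K1 * H + constants.K1 * constants.K2
        dden = 2.0 * H + constants.K1
        dhco3 = dic_m * constants.K1 * (den - H * dden) / (den * den)
        dco3 = -dic_m * constants.K1 * constants.K2 * dden / (den * den)
        dboh4 = -constants.BT * constants.KB / (constants.KB + H) ** 2
        doh = -constants.KW / (H * H)
        dTA_dH = dhco3 + 2.0 * dco3 + dboh4 + doh - 1.0
        dH_dpH = -math.log(10.0) * H
        step = val / (dTA_dH * dH_dpH)
        cand = pH - step
        if not lo < cand < hi:  # Newton left the bracket: bisect
            cand = 0.5 * (lo + hi)
        if abs(val) / ta_m < 1e-12 and abs(cand - pH) < 1e-12:
            pH = cand
            break
        pH = cand
    state = _state_from_H(dic_m, 10.0**-pH, constants)
    if abs(state.TA - TA) / TA > 1e-9:
        raise RuntimeError(
            f"speciation solver did not converge: residual "
            f"{abs(state.TA - TA) / TA:.2e} for DIC={DIC}, TA={TA}"
        )
    return state


def equilibrate_with_atmosphere(
    pCO2: float, TA: float, constants: ConstantSet
) -> CarbonateState:
    """State of water equilibrated with an atmosphere at pCO2 (µatm).

    Fixes CO2aq = K0·pCO2 (Henry's law) and solves the TA balance for
    [H+]; DIC follows from the speciation.  Recomputing pCO2 from the
    returned state reproduces the input to 1e-6 relative.
    """
    if not pCO2 > 0.0:
        raise ValueError(f"pCO2 must be positive, got {pCO2}")
    if not TA > 0.0:
        raise ValueError(f"TA must be positive, got {TA}")
    co2 = constants.K0 * pCO2 * 1e-6  # mol/kg
    ta_m = TA * 1e-6
    k = constants

    def f(pH: float) -> float:
        H = 10.0**-pH
        hco3 = co2 * k.K1 / H
        co3 = co2 * k.K1 * k.K2 / (H * H)
        ta = hco3 + 2.0 * co3 + k.BT * k.KB / (k.KB + H) + k.KW / H - H
        return ta - ta_m

    lo, hi = _PH_BRACKET
    if not (f(lo) < 0.0 < f(hi)):
        raise RuntimeError(
            f"atmospheric equilibration failed to bracket a root for "
            f"pCO2={pCO2}, TA={TA}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-14:
            break
    H = 10.0 ** (-0.5 * (lo + hi))
    dic_m = co2 * (1.0 + k.K1 / H + k.K1 * k.K2 / (H * H))
    return _state_from_H(dic_m, H, k)


def alkalinity_increment(
    net_flux_NH4: float, net_flux_NO3: float, net_flux_PO4: float
) -> float:
    """Total-alkalinity change (µmol kg⁻¹) from net nutrient uptake.

    Arguments are net uptake (µmol kg⁻¹; release = negative uptake).
    NO3⁻ and phosphate uptake raise TA; NH4⁺ uptake lowers it — so
    ammonium *release* by heterotrophs raises TA and damps the rise in
    [H+] that their respired CO2 causes.
    """
    return (
        TA_STOICH["NH4"] * net_flux_NH4
        + TA_STOICH["NO3"] * net_flux_NO3
        + TA_STOICH["PO4"] * net_flux_PO4
    )
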
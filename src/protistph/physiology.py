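"""Quota-based protist physiology: the mass-conserving flux model.

One population of a single protist functional type grows in a closed
water parcel.  Carbon enters the cell by gross photosynthesis and by
phagotrophy; nitrogen and phosphorus enter by inorganic uptake and by
phagotrophy.  Ingested material is partitioned into voided micro-faeces
(fraction ``1 − AE``), a specific-dynamic-action (SDA) catabolic loss
(fraction ``SDA`` of the retained ingestate, released as CO2, NH4+ and
phosphate) and the anabolate that joins biomass.  Inside a mixoplankton
the SDA releases first meet the concurrent photosynthetic CO2 demand and
inorganic-nutrient demand; only the surplus is released to the water.

All rates are per day; dissolved pools are µM (µmol L⁻¹ = µg atom L⁻¹
for single atoms); biomass pools are µg atom L⁻¹.  Chlorophyll is
carried as a carbon-equivalent *index* pool attached to biomass and is
deliberately excluded from the element mass balance.

Internal stoichiometry follows a Droop quota scheme: N/C and P/C are
free between configured minima and maxima; trophic controls are smooth
sigmoids of the normalized quota, and regeneration/overflow fluxes
engage at the quota boundaries so the bounds are never crossed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

__all__ = [
    "ProtistConfig",
    "ProtistState",
    "DissolvedPools",
    "PreyField",
    "FluxVector",
    "control_factors",
    "gross_photosynthesis",
    "inorganic_uptake",
    "ingestion",
    "digestion_partition",
    "sda_recycle",
    "acquired_phototrophy_update",
    "maintenance_losses",
    "quota_balancing",
    "protist_derivatives",
]

_ACQ_MODES = ("none", "generalist", "plastidic_specialist")
_PRIORITIES = ("equal", "photo_first", "phago_first")

#: Redfield reference stoichiometry (g atom ratios to C)
_REDFIELD_NC = 16.0 / 106.0
_REDFIELD_PC = 1.0 / 106.0

#: half-width (in normalized-quota units) of the boundary band over
#: which regeneration / carbon-overflow corrections ramp in
_QUOTA_BAND = 0.05
#: first-order relaxation rate (d⁻¹) pulling a quota back inside its
#: bounds after an integrator overshoot
_QUOTA_RELAX = 10.0


@dataclass(frozen=True)
class ProtistConfig:
    """Parameterization of one protist functional type.

    Rates are biomass-C-specific unless noted.  ``basal_respiration``
    and the various ``*_multiplier`` values are expressed as multiples
    of ``mu_max`` so that functional types differing only in trophic
    capability share identical physiological constants.
    """

    name: str = "protist"
    mu_max: float = 0.693  # d-1, a doubling per day
    ESD: float = 20.0  # µm equivalent spherical diameter
    can_photosynthesize_constitutively: bool = True
    acquired_phototrophy_mode: str = "none"
    can_use_NO3: bool = True
    can_use_NH4: bool = True
    can_use_PO4: bool = True
    can_ingest: bool = False
    AE: float = 0.75  # assimilation efficiency (fraction retained)
    SDA: float = 0.30  # fraction of retained ingestate lost on anabolism
    priority: str = "equal"
    basal_respiration: float = 0.15  # fraction of mu_max, C-specific
    DOC_leak_fraction: float = 0.10  # of gross anabolic C input
    NC_min: float = 0.05
    NC_max: float = 0.20
    PC_min: float = 0.003
    PC_max: float = 0.02
    ChlC_max: float = 0.06  # C-equivalent Chl index per biomass C
    half_sat_NH4: float = 0.3  # µM
    half_sat_NO3: float = 0.3  # µM
    half_sat_PO4: float = 0.1  # µM
    grazing_half_sat: float = 50.0  # µM prey C
    acquired_decay_rate: float = 0.0  # d-1; generalist >> specialist
    # ---- functional-form shape constants -------------------------------
    photo_max_multiplier: float = 3.0  # Pmax = multiplier * mu_max
    uptake_max_multiplier: float = 3.0  # Vmax_X = mult * mu_max * XC_max
    ingest_max_multiplier: float = 3.0  # Imax = multiplier * mu_max
    PFD_half_sat: float = 75.0  # µmol photons m-2 s-1 (exp saturation)
    control_exponent: float = 2.0
    control_k_photo: float = 0.5
    control_k_phago: float = 0.5
    control_k_uptake: float = 0.5
    control_cap_photo: float = 1.0  # <1 represses the de-prioritized mode
    control_cap_phago: float = 1.0
    nh4_inhibition_K: float = 0.5  # µM; NH4 represses NO3 uptake
    chl_synthesis_rate: float = 1.0  # d-1 relaxation toward Chl target
    acq_gain_rate: float = 2.0  # capacity gain per unit chl ingestion
    doc_reabsorb_rate: float = 0.0  # d-1 first-order DOC recovery
    esd_ref: float = 20.0  # µm; encounter factor = ESD / esd_ref

    def __post_init__(self) -> None:
        if not 0.0 < self.AE <= 1.0:
            raise ValueError(f"AE must be in (0, 1], got {self.AE}")
        if not 0.0 <= self.SDA < 1.0:
            raise ValueError(f"SDA must be in [0, 1), got {self.SDA}")
        if not self.NC_min < self.NC_max:
            raise ValueError("NC_min must be < NC_max")
        if not self.PC_min < self.PC_max:
            raise ValueError("PC_min must be < PC_max")
        if not self.mu_max > 0.0:
            raise ValueError("mu_max must be positive")
        if self.acquired_phototrophy_mode not in _ACQ_MODES:
            raise ValueError(
                f"acquired_phototrophy_mode must be one of {_ACQ_MODES}"
            )
        if self.priority not in _PRIORITIES:
            raise ValueError(f"priority must be one of {_PRIORITIES}")

    # -- capability helpers ------------------------------------------------
    @property
    def is_phototroph(self) -> bool:
        """True if the type can photosynthesize at all (innate or acquired)."""
        return (
            self.can_photosynthesize_constitutively
            or self.acquired_phototrophy_mode != "none"
        )

    @property
    def phagotrophy_needs_carbon(self) -> bool:
        """Pure heterotrophs must eat for C, not only for N and P."""
        return not self.is_phototroph

    def with_overrides(self, **overrides) -> "ProtistConfig":
        unknown = set(overrides) - set(self.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown ProtistConfig fields: {sorted(unknown)}")
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ProtistState:
    """Population biomass pools (µg atom L⁻¹) and acquisition capacity."""

    C: float
    N: float
    P: float
    Chl: float = 0.0
    acquired_capacity: float = 1.0

    def quotas(self) -> tuple:
        if self.C <= 0.0:
            return (float("nan"), float("nan"))
        return (self.N / self.C, self.P / self.C)

    def validate(self, config: ProtistConfig, tol: float = 1e-6) -> None:
        for v, nm in ((self.C, "C"), (self.N, "N"), (self.P, "P"),
                      (self.Chl, "Chl")):
            if v < -tol:
                raise ValueError(f"negative biomass pool {nm}={v}")
        if not -tol <= self.acquired_capacity <= 1.0 + tol:
            raise ValueError(
                f"acquired_capacity {self.acquired_capacity} outside [0, 1]"
            )
        if self.C > 0.0:
            qn, qp = self.quotas()
            if not config.NC_min - tol <= qn <= config.NC_max + tol:
                raise ValueError(
                    f"N/C quota {qn:.4f} outside "
                    f"[{config.NC_min}, {config.NC_max}]"
                )
            if not config.PC_min - tol <= qp <= config.PC_max + tol:
                raise ValueError(
                    f"P/C quota {qp:.5f} outside "
                    f"[{config.PC_min}, {config.PC_max}]"
                )


@dataclass
class DissolvedPools:
    """Dissolved inorganic/organic pools (µM) in the water parcel.

    ``DIC_biological_delta`` is the cumulative biological change in DIC
    (µmol kg⁻¹, any sign) applied downstream to the carbonate system.
    VOC/VON/VOP are voided micro-faeces, operationally dissolved.
    """

    NH4: float = 10.0
    NO3: float = 10.0
    PO4: float = 1.25
    DOC: float = 0.0
    DON: float = 0.0
    DOP: float = 0.0
    VOC: float = 0.0
    VON: float = 0.0
    VOP: float = 0.0
    DIC_biological_delta: float = 0.0


@dataclass
class PreyField:
    """Non-growing prey (µg atom L⁻¹) of fixed stoichiometry."""

    prey_C: float = 132.5
    prey_N: float = 20.0
    prey_P: float = 1.25
    prey_Chl: float = 13.25
    prey_ESD: float = 5.0


@dataclass
class FluxVector:
    """All per-day population fluxes (one evaluation of the flux model)."""

    gross_photosynthesis_C: float = 0.0
    CO2_external_uptake: float = 0.0
    NH4_uptake: float = 0.0
    NO3_uptake: float = 0.0
    PO4_uptake: float = 0.0
    ingestion_C: float = 0.0
    ingestion_N: float = 0.0
    ingestion_P: float = 0.0
    ingestion_Chl: float = 0.0
    void_C: float = 0.0
    void_N: float = 0.0
    void_P: float = 0.0
    SDA_release_C: float = 0.0
    SDA_release_N: float = 0.0
    SDA_release_P: float = 0.0
    SDA_recycled_C: float = 0.0
    SDA_recycled_N: float = 0.0
    SDA_recycled_P: float = 0.0
    SDA_net_external_C: float = 0.0
    SDA_net_external_N: float = 0.0
    SDA_net_external_P: float = 0.0
    basal_respiration_C: float = 0.0
    DOC_leak: float = 0.0
    DON_leak: float = 0.0
    DOP_leak: float = 0.0
    DOC_reabsorption: float = 0.0
    regeneration_NH4: float = 0.0
    regeneration_PO4: float = 0.0
    net_growth_C: float = 0.0

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# controls
# ---------------------------------------------------------------------------

def _normalized_quota(q: float, qmin: float, qmax: float) -> float:
    return min(1.0, max(0.0, (q - qmin) / (qmax - qmin)))


def _sigmoid(stress: float, k: float, h: float) -> float:
    """Normalized Hill response: 0 at zero stress, exactly 1 at stress 1."""
    s = min(1.0, max(0.0, stress))
    if s == 0.0:
        return 0.0
    sh = s**h
    kh = k**h
    return sh * (1.0 + kh) / (sh + kh)


def control_factors(state: ProtistState, config: ProtistConfig):
    """De-repression controls for phototrophy, phagotrophy and uptake.

    Controls rise smoothly from ~0 (satiated, quota at maximum) to 1
    (quota at minimum).  ``priority`` caps the control of the
    de-prioritized trophic mode (via ``control_cap_*``), so the
    prioritized mode always runs at least as de-repressed as the other
    at every quota.  To the extent that a cell cannot currently
    photosynthesize — a zooplankton always, a non-constitutive
    mixoplankton while its acquired capacity or photosystems are run
    down — its phagotrophy control additionally responds to carbon
    deficit (high quotas mean a C-poor cell), since food is then its
    only carbon source.

    Returns ``(photo_control, phago_control, uptake_controls)`` with
    ``uptake_controls = {"N": ..., "P": ...}``.
    """
    state.validate(config)
    if state.C <= 0.0:
        return 0.0, 0.0, {"N": 0.0, "P": 0.0}
    qn_raw, qp_raw = state.quotas()
    qn = _normalized_quota(qn_raw, config.NC_min, config.NC_max)
    qp = _normalized_quota(qp_raw, config.PC_min, config.PC_max)
    q = min(qn, qp)
    stress = 1.0 - q
    h = config.control_exponent
    photo = min(
        config.control_cap_photo, _sigmoid(stress, config.control_k_photo, h)
    )
    if config.can_photosynthesize_constitutively:
        photo_competence = 1.0
    elif config.acquired_phototrophy_mode != "none":
        chl_factor = min(1.0, max(0.0, state.Chl / state.C) / config.ChlC_max)
        photo_competence = (
            max(0.0, min(1.0, state.acquired_capacity)) * chl_factor
        )
    else:
        photo_competence = 0.0
    # carbon stress felt only by the currently non-photosynthetic part
    s_phago = max(stress, q * (1.0 - photo_competence))
    phago = min(
        config.control_cap_phago, _sigmoid(s_phago, config.control_k_phago, h)
    )
    up = {
        "N": _sigmoid(1.0 - qn, config.control_k_uptake, h),
        "P": _sigmoid(1.0 - qp, config.control_k_uptake, h),
    }
    return photo, phago, up


# ---------------------------------------------------------------------------
# resource acquisition
# ---------------------------------------------------------------------------

def gross_photosynthesis(
    state: ProtistState, PFD: float, config: ProtistConfig
) -> float:
    """Gross C fixation (µg atom C L⁻¹ d⁻¹).

    Exponential-saturation P–I response scaled by the Chl:C index, a
    carbon-demand factor, and (for non-constitutive types) the acquired
    phototrophic capacity.  PFD 500 is saturating; PFD 0 gives zero
    fixation.

    The demand factor is the larger of the quota-stress de-repression
    control (C acquisition under nutrient stress, shifted by the
    trophic priority) and the Droop growth drive (a nutrient-replete
    cell fixes at capacity to supply growth): fixation is high both in
    balanced replete growth and during stress-driven overflow
    production, with a shallow minimum at intermediate quota.
    """
    if PFD < 0.0:
        raise ValueError("PFD must be non-negative")
    if not config.is_phototroph or state.C <= 0.0 or PFD == 0.0:
        return 0.0
    capacity = (
        1.0
        if config.can_photosynthesize_constitutively
        else max(0.0, min(1.0, state.acquired_capacity))
    )
    chl_factor = min(1.0, max(0.0, state.Chl / state.C) / config.ChlC_max)
    if capacity == 0.0 or chl_factor == 0.0:
        return 0.0
    f_light = 1.0 - math.exp(-PFD / config.PFD_half_sat)
    photo_control, _, _ = control_factors(state, config)
    qn_raw, qp_raw = state.quotas()
    growth_drive = min(
        _normalized_quota(qn_raw, config.NC_min, config.NC_max),
        _normalized_quota(qp_raw, config.PC_min, config.PC_max),
    )
    demand = max(photo_control, growth_drive)
    pmax = config.photo_max_multiplier * config.mu_max
    return pmax * chl_factor * f_light * demand * capacity * state.C


def inorganic_uptake(
    state: ProtistState, pools: DissolvedPools, config: ProtistConfig
):
    """Michaelis–Menten nutrient uptake rates (µM d⁻¹): (NH4, NO3, PO4).

    NO3 uptake is additionally repressed by ambient NH4 (ammonium
    preference) and is zero for types that cannot use nitrate.  Types
    with no inorganic-nutrient capability (zooplankton) take up nothing.
    """
    if state.C <= 0.0:
        return 0.0, 0.0, 0.0
    _, _, up = control_factors(state, config)
    vmax_n = config.uptake_max_multiplier * config.mu_max * config.NC_max
    vmax_p = config.uptake_max_multiplier * config.mu_max * config.PC_max
    v_nh4 = v_no3 = v_po4 = 0.0
    if config.can_use_NH4 and pools.NH4 > 0.0:
        v_nh4 = (
            vmax_n
            * pools.NH4 / (pools.NH4 + config.half_sat_NH4)
            * up["N"] * state.C
        )
    if config.can_use_NO3 and pools.NO3 > 0.0:
        inhib = config.nh4_inhibition_K / (
            config.nh4_inhibition_K + max(0.0, pools.NH4)
        )
        v_no3 = (
            vmax_n
            * pools.NO3 / (pools.NO3 + config.half_sat_NO3)
            * up["N"] * inhib * state.C
        )
    if config.can_use_PO4 and pools.PO4 > 0.0:
        v_po4 = (
            vmax_p
            * pools.PO4 / (pools.PO4 + config.half_sat_PO4)
            * up["P"] * state.C
        )
    return v_nh4, v_no3, v_po4


def ingestion(state: ProtistState, prey: PreyField, config: ProtistConfig):
    """Type-II grazing on the prey field: rates for prey C, N, P, Chl.

    Rectangular-hyperbolic in prey C, scaled by the phagotrophy control
    and an encounter factor proportional to predator ESD (larger cells
    sweep more water per unit biomass).  N, P and Chl are ingested in
    the prey's stoichiometric proportion.
    """
    if not config.can_ingest or state.C <= 0.0 or prey.prey_C <= 0.0:
        return 0.0, 0.0, 0.0, 0.0
    _, phago, _ = control_factors(state, config)
    encounter = config.ESD / config.esd_ref
    imax = config.ingest_max_multiplier * config.mu_max
    i_c = (
        imax
        * encounter
        * prey.prey_C / (prey.prey_C + config.grazing_half_sat)
        * phago
        * state.C
    )
    ratio_n = prey.prey_N / prey.prey_C
    ratio_p = prey.prey_P / prey.prey_C
    ratio_chl = prey.prey_Chl / prey.prey_C
    return i_c, i_c * ratio_n, i_c * ratio_p, i_c * ratio_chl


def digestion_partition(ingested, config: ProtistConfig, AE: float | None = None):
    """Partition ingested (C, N, P) into voided, SDA gross, anabolate.

    voided = (1 − AE)·ingested; SDA = SDA·AE·ingested (released as CO2
    / NH4 / phosphate equivalents); anabolate is the exact remainder so
    the three sum to the input by construction.  ``AE`` defaults to the
    configured assimilation efficiency; callers may pass an effective
    value (see :func:`effective_assimilation`) when prey quality departs
    from the consumer's needs.
    """
    ae = config.AE if AE is None else AE
    voided, sda, anab = [], [], []
    for x in ingested:
        if x < 0.0:
            raise ValueError("ingested rates must be non-negative")
        v = (1.0 - ae) * x
        s = config.SDA * ae * x
        voided.append(v)
        sda.append(s)
        anab.append(x - v - s)
    return tuple(voided), tuple(sda), tuple(anab)


def effective_assimilation(prey: PreyField, config: ProtistConfig) -> float:
    """Assimilation efficiency adjusted for prey nutritional quality.

    Stoichiometric ecology: prey poorer in N:C or P:C than the Redfield
    reference is assimilated less efficiently, with the shortfall
    voided (AE scales with the square root of the worst relative
    quality).  Redfield or richer prey is assimilated at the configured
    AE.
    """
    if prey.prey_C <= 0.0:
        return config.AE
    quality = min(
        1.0,
        (prey.prey_N / prey.prey_C) / _REDFIELD_NC,
        (prey.prey_P / prey.prey_C) / _REDFIELD_PC,
    )
    return config.AE * math.sqrt(max(0.0, quality))


def sda_recycle(
    sda_gross,
    photosynthetic_demand_C: float,
    nutrient_demand_N: float,
    nutrient_demand_P: float,
    config: ProtistConfig,
):
    """Internal reuse of SDA releases against concurrent demands.

    Element-wise, recycled = min(SDA release, concurrent demand); the
    remainder is released to the water.  Recycled CO2 reduces the
    external CO2 demand of photosynthesis; recycled N and P reduce the
    external inorganic uptake.  A zooplankton has zero demand in every
    element, so all of its SDA release is external.
    """
    demands = (photosynthetic_demand_C, nutrient_demand_N, nutrient_demand_P)
    recycled = tuple(min(s, max(0.0, d)) for s, d in zip(sda_gross, demands))
    net_external = tuple(s - r for s, r in zip(sda_gross, recycled))
    return recycled, net_external


def acquired_phototrophy_update(
    state: ProtistState, ingested_Chl: float, config: ProtistConfig
):
    """Rates of change of acquired capacity and of the Chl index pool.

    Generalists gain capacity from ingested chloroplast material and
    lose it quickly (no maintenance); plastidic specialists decay much
    more slowly and can additionally photoacclimate, synthesizing Chl
    on their retained plastids up to ``ChlC_max``.  Constitutive and
    non-phototrophic types are a no-op.
    """
    mode = config.acquired_phototrophy_mode
    if mode == "none":
        return 0.0, 0.0
    if state.C <= 0.0:
        return 0.0, 0.0
    acq = max(0.0, min(1.0, state.acquired_capacity))
    # capacity gain saturates toward 1 with specific chl ingestion
    specific_chl_in = ingested_Chl / (config.ChlC_max * state.C)
    gain = config.acq_gain_rate * specific_chl_in * (1.0 - acq)
    d_acq = gain - config.acquired_decay_rate * acq
    retained_chl = config.AE * ingested_Chl
    if mode == "generalist":
        d_chl = retained_chl - config.acquired_decay_rate * state.Chl
    else:
        # plastidic specialist: photoacclimation toward a target scaled
        # by capacity and nutrient status (starved cells shed pigment)
        qn = _normalized_quota(state.N / state.C, config.NC_min, config.NC_max)
        qp = _normalized_quota(state.P / state.C, config.PC_min, config.PC_max)
        target = acq * min(qn, qp) * config.ChlC_max * state.C
        d_chl = retained_chl + config.chl_synthesis_rate * (target - state.Chl)
    return d_acq, d_chl


def maintenance_losses(
    state: ProtistState,
    gross_photo: float,
    config: ProtistConfig,
    anabolate_C: float = 0.0,
):
    """Basal respiration and baseline DOM leakage (all ≥ 0).

    Basal respiration is biomass-C specific and light-independent, so a
    dark cell is a net CO2 source.  The DOM leak is a fixed fraction of
    the gross anabolic C input (photosynthesis plus assimilated food —
    heterotrophs leak from digestion), with N and P leaking in biomass
    proportion, gated away from the minimum quota.  Stoichiometric
    carbon overflow and NH4/PO4 regeneration are handled by
    :func:`quota_balancing`.
    """
    if state.C <= 0.0:
        return 0.0, 0.0, 0.0, 0.0
    basal = config.basal_respiration * config.mu_max * state.C
    doc = config.DOC_leak_fraction * (gross_photo + anabolate_C)
    qn_raw, qp_raw = state.quotas()
    qn = _normalized_quota(qn_raw, config.NC_min, config.NC_max)
    qp = _normalized_quota(qp_raw, config.PC_min, config.PC_max)
    don = 0.25 * doc * qn_raw * qn
    dop = 0.25 * doc * qp_raw * qp
    return basal, doc, don, dop


def _ramp(x: float) -> float:
    return min(1.0, max(0.0, x))


def quota_balancing(
    state: ProtistState,
    dC: float,
    dN: float,
    dP: float,
    config: ProtistConfig,
):
    """Boundary fluxes keeping N/C and P/C inside their Droop bounds.

    Returns ``(overflow_C, regen_NH4, regen_PO4)``.  Carbon overflow
    (leaked as DOC) engages in a narrow band above the minimum quota so
    that net C gain cannot dilute N or P below ``*C_min``; NH4 and PO4
    regeneration engage below the maximum quota so respiration cannot
    concentrate N or P above ``*C_max``.  A stiff relaxation term pulls
    back any numerical overshoot past a bound.  Away from the bands all
    three fluxes are exactly zero.
    """
    if state.C <= 0.0:
        return 0.0, 0.0, 0.0
    qn_raw, qp_raw = state.quotas()
    qn = _normalized_quota(qn_raw, config.NC_min, config.NC_max)
    qp = _normalized_quota(qp_raw, config.PC_min, config.PC_max)
    b = _QUOTA_BAND

    # ---- carbon overflow at the lower quota bounds ----------------------
    overflow = 0.0
    lo_n = _ramp((b - qn) / b)
    if lo_n > 0.0:
        overflow = max(overflow, lo_n * max(0.0, dC - dN / config.NC_min))
    lo_p = _ramp((b - qp) / b)
    if lo_p > 0.0:
        overflow = max(overflow, lo_p * max(0.0, dC - dP / config.PC_min))
    # overshoot relaxation below the minimum
    if qn_raw < config.NC_min:
        overflow += _QUOTA_RELAX * (config.NC_min * state.C - state.N) / config.NC_min
    if qp_raw < config.PC_min:
        overflow += _QUOTA_RELAX * (config.PC_min * state.C - state.P) / config.PC_min
    dC_corr = dC - overflow

    # ---- nutrient regeneration at the upper quota bounds ----------------
    regen_n = 0.0
    hi_n = _ramp((qn - (1.0 - b)) / b)
    if hi_n > 0.0:
        regen_n = hi_n * max(0.0, dN - config.NC_max * dC_corr)
    if qn_raw > config.NC_max:
        regen_n += _QUOTA_RELAX * (state.N - config.NC_max * state.C)
    regen_p = 0.0
    hi_p = _ramp((qp - (1.0 - b)) / b)
    if hi_p > 0.0:
        regen_p = hi_p * max(0.0, dP - config.PC_max * dC_corr)
    if qp_raw > config.PC_max:
        regen_p += _QUOTA_RELAX * (state.P - config.PC_max * state.C)
    return overflow, regen_n, regen_p


# ---------------------------------------------------------------------------
# full flux assembly
# ---------------------------------------------------------------------------

def protist_derivatives(
    state: ProtistState,
    pools: DissolvedPools,
    prey: PreyField,
    config: ProtistConfig,
    PFD: float,
):
    """Assemble every flux into one mass-conserving derivative set.

    Returns ``(fluxes, d_state, d_pools, d_prey)`` where the ``d_*``
    objects hold per-day time derivatives of the corresponding pools.
    The biological DIC derivative is respiration plus net external SDA
    carbon minus gross *external* CO2 uptake; net nutrient fluxes carry
    the total-alkalinity forcing (applied downstream by the simulator).
    For every element, the summed derivative of (biomass + prey +
    dissolved organic + voided + inorganic) pools is zero.
    """
    # acquisition
    g_pot = gross_photosynthesis(state, PFD, config)
    v_nh4, v_no3, v_po4 = inorganic_uptake(state, pools, config)
    i_c, i_n, i_p, i_chl = ingestion(state, prey, config)
    ae_eff = effective_assimilation(prey, config)
    (void_c, void_n, void_p), (sda_c, sda_n, sda_p), (anab_c, anab_n, anab_p) = (
        digestion_partition((i_c, i_n, i_p), config, AE=ae_eff)
    )

    # internal SDA recycling against concurrent demands
    (rec_c, rec_n, rec_p), (ext_c, ext_n, ext_p) = sda_recycle(
        (sda_c, sda_n, sda_p), g_pot, v_nh4 + v_no3, v_po4, config
    )
    co2_external = g_pot - rec_c
    demand_n = v_nh4 + v_no3
    scale_n = (demand_n - rec_n) / demand_n if demand_n > 0.0 else 0.0
    v_nh4_act, v_no3_act = v_nh4 * scale_n, v_no3 * scale_n
    scale_p = (v_po4 - rec_p) / v_po4 if v_po4 > 0.0 else 0.0
    v_po4_act = v_po4 * scale_p

    # maintenance
    basal, doc_base, don_leak, dop_leak = maintenance_losses(
        state, g_pot, config, anabolate_C=anab_c
    )
    reab = config.doc_reabsorb_rate * max(0.0, pools.DOC)

    # provisional biomass derivatives, then quota-boundary corrections
    dC_prov = g_pot + anab_c + reab - basal - doc_base
    dN_prov = v_nh4_act + v_no3_act + anab_n + rec_n - don_leak
    dP_prov = v_po4_act + anab_p + rec_p - dop_leak
    overflow, regen_n, regen_p = quota_balancing(
        state, dC_prov, dN_prov, dP_prov, config
    )

    dC = dC_prov - overflow
    dN = dN_prov - regen_n
    dP = dP_prov - regen_p

    # chlorophyll index and acquired capacity
    if config.can_photosynthesize_constitutively:
        qn = _normalized_quota(
            state.N / state.C if state.C > 0 else 0.0,
            config.NC_min, config.NC_max,
        )
        qp = _normalized_quota(
            state.P / state.C if state.C > 0 else 0.0,
            config.PC_min, config.PC_max,
        )
        target = min(qn, qp) * config.ChlC_max * state.C
        d_chl = config.chl_synthesis_rate * (target - state.Chl)
        d_acq = 0.0
    else:
        d_acq, d_chl = acquired_phototrophy_update(state, i_chl, config)

    fluxes = FluxVector(
        gross_photosynthesis_C=g_pot,
        CO2_external_uptake=co2_external,
        NH4_uptake=v_nh4_act,
        NO3_uptake=v_no3_act,
        PO4_uptake=v_po4_act,
        ingestion_C=i_c,
        ingestion_N=i_n,
        ingestion_P=i_p,
        ingestion_Chl=i_chl,
        void_C=void_c,
        void_N=void_n,
        void_P=void_p,
        SDA_release_C=sda_c,
        SDA_release_N=sda_n,
        SDA_release_P=sda_p,
        SDA_recycled_C=rec_c,
        SDA_recycled_N=rec_n,
        SDA_recycled_P=rec_p,
        SDA_net_external_C=ext_c,
        SDA_net_external_N=ext_n,
        SDA_net_external_P=ext_p,
        basal_respiration_C=basal,
        DOC_leak=doc_base + overflow,
        DON_leak=don_leak,
        DOP_leak=dop_leak,
        DOC_reabsorption=reab,
        regeneration_NH4=regen_n,
        regeneration_PO4=regen_p,
        net_growth_C=dC,
    )

    d_state = ProtistState(C=dC, N=dN, P=dP, Chl=d_chl, acquired_capacity=d_acq)
    d_pools = DissolvedPools(
        NH4=-v_nh4_act + ext_n + regen_n,
        NO3=-v_no3_act,
        PO4=-v_po4_act + ext_p + regen_p,
        DOC=doc_base + overflow - reab,
        DON=don_leak,
        DOP=dop_leak,
        VOC=void_c,
        VON=void_n,
        VOP=void_p,
        DIC_biological_delta=basal + ext_c - co2_external,
    )
    d_prey = PreyField(
        prey_C=-i_c, prey_N=-i_n, prey_P=-i_p, prey_Chl=-i_chl,
        prey_ESD=0.0,
    )
    return fluxes, d_state, d_pools, d_prey
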
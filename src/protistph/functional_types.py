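"""Factory for the five protist functional-type configurations.

The types span the trophic spectrum: phytoplankton (pure phototroph),
zooplankton (pure phagotroph), GNCM (generalist non-constitutive
mixoplankton: feeds, acquires short-lived phototrophy from any prey,
uses ammonium but not nitrate), pSNCM (plastidic-specialist NCM:
feeds, maintains and photoacclimates its acquired photosystems, uses
nitrate) and CM (constitutive mixoplankton: innate plastids plus full
inorganic-nutrient use plus feeding).  CM additionally comes in
priority variants (equal / photo_first / phago_first).

All five share the same maximum growth rate (0.693 d⁻¹), cell size
(20 µm ESD) and physiological constants; they differ only in
capability flags, trophic priorities and acquisition parameters, so
cross-type comparisons isolate trophic strategy.
"""
from __future__ import annotations

from .physiology import ProtistConfig

__all__ = [
    "FUNCTIONAL_TYPES",
    "CM_VARIANTS",
    "make_config",
]

#: decay of acquired phototrophic capacity (d⁻¹): generalists lose it
#: within a few days of prey exhaustion, specialists persist for weeks
GENERALIST_DECAY = 0.7
SPECIALIST_DECAY = 0.05

#: slow first-order recovery of leaked DOC by the pure heterotroph
ZOOPLANKTON_DOC_REABSORB = 0.3

FUNCTIONAL_TYPES = ("phytoplankton", "zooplankton", "GNCM", "pSNCM", "CM")
CM_VARIANTS = ("equal", "photo_first", "phago_first")

#: priority -> (control_cap_photo, control_cap_phago): the
#: de-prioritized trophic mode is capped at 0.4 de-repression, so the
#: favoured mode is always at least as enabled at every nutrient status
_PRIORITY_CAPS = {
    "equal": (1.0, 1.0),
    "photo_first": (1.0, 0.4),
    "phago_first": (0.4, 1.0),
}


def _base(name: str, **kw) -> ProtistConfig:
    return ProtistConfig(name=name, mu_max=0.693, ESD=20.0, **kw)


def make_config(
    name: str, variant: str = "equal", overrides: dict | None = None
) -> ProtistConfig:
    """Build the configuration for one functional type.

    ``variant`` selects the trophic priority (meaningful for CM, per the
    priority-shift experiments); ``overrides`` may adjust any declared
    ``ProtistConfig`` field and is validated against the field list.
    """
    if name not in FUNCTIONAL_TYPES:
        raise ValueError(
            f"unknown functional type {name!r}; valid names: "
            f"{', '.join(FUNCTIONAL_TYPES)}"
        )
    if variant not in CM_VARIANTS:
        raise ValueError(
            f"unknown priority variant {variant!r}; valid: "
            f"{', '.join(CM_VARIANTS)}"
        )
    cap_photo, cap_phago = _PRIORITY_CAPS[variant]
    priority = {"equal": "equal", "photo_first": "photo_first",
                "phago_first": "phago_first"}[variant]

    if name == "phytoplankton":
        cfg = _base(
            name,
            can_photosynthesize_constitutively=True,
            acquired_phototrophy_mode="none",
            can_use_NH4=True, can_use_NO3=True, can_use_PO4=True,
            can_ingest=False,
            priority=priority,
            control_cap_photo=cap_photo, control_cap_phago=cap_phago,
        )
    elif name == "zooplankton":
        cfg = _base(
            name,
            can_photosynthesize_constitutively=False,
            acquired_phototrophy_mode="none",
            can_use_NH4=False, can_use_NO3=False, can_use_PO4=False,
            can_ingest=True,
            priority=priority,
            control_cap_photo=cap_photo, control_cap_phago=cap_phago,
            doc_reabsorb_rate=ZOOPLANKTON_DOC_REABSORB,
        )
    elif name == "GNCM":
        cfg = _base(
            name,
            can_photosynthesize_constitutively=False,
            acquired_phototrophy_mode="generalist",
            can_use_NH4=True, can_use_NO3=False, can_use_PO4=True,
            can_ingest=True,
            priority=priority,
            control_cap_photo=cap_photo, control_cap_phago=cap_phago,
            acquired_decay_rate=GENERALIST_DECAY,
        )
    elif name == "pSNCM":
        cfg = _base(
            name,
            can_photosynthesize_constitutively=False,
            acquired_phototrophy_mode="plastidic_specialist",
            can_use_NH4=True, can_use_NO3=True, can_use_PO4=True,
            can_ingest=True,
            priority=priority,
            control_cap_photo=cap_photo, control_cap_phago=cap_phago,
            acquired_decay_rate=SPECIALIST_DECAY,
        )
    else:  # CM
        cfg = _base(
            name,
            can_photosynthesize_constitutively=True,
            acquired_phototrophy_mode="none",
            can_use_NH4=True, can_use_NO3=True, can_use_PO4=True,
            can_ingest=True,
            priority=priority,
            control_cap_photo=cap_photo, control_cap_phago=cap_phago,
        )
    if overrides:
        cfg = cfg.with_overrides(**overrides)
    return cfg
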
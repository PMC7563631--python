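"""Stable identifiers for the deviation-checklist items and their aliases.

The 16-item deviation checklist (one point per deviated critical action,
total 0-16) is a reconstruction assembled from the deviation categories a
pilot simulation study reports (compressions-to-ventilations ratio,
epinephrine dose/dilution, reversible-causes search including hypovolemia,
timeliness of epinephrine) padded with standard PALS critical actions.
Item ids are shared between the simulator's fault-injection machinery and
the scoring instruments.
"""

from __future__ import annotations

CDEV_ITEM_IDS: tuple[str, ...] = (
    "cd01_timely_recognition",
    "cd02_call_for_help",
    "cd03_early_compressions",
    "cd04_compression_ventilation_ratio",
    "cd05_compression_rate",
    "cd06_monitor_attached",
    "cd07_rhythm_check_cadence",
    "cd08_epinephrine_dose",
    "cd09_epinephrine_dilution",
    "cd10_first_epinephrine_timely",
    "cd11_epinephrine_interval",
    "cd12_vascular_access",
    "cd13_reversible_causes_search",
    "cd14_hypovolemia_treatment",
    "cd15_airway_management",
    "cd16_prompt_cpr_resumption",
)

# Compound fault names: one behavioral fault can deviate several checklist
# items (e.g. omitting the reversible-causes work fails both the search and
# the hypovolemia-treatment items).
FAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "incorrect_ratio": ("cd04_compression_ventilation_ratio",),
    "incorrect_dose_or_dilution": (
        "cd08_epinephrine_dose",
        "cd09_epinephrine_dilution",
    ),
    "reversible_causes_omission": (
        "cd13_reversible_causes_search",
        "cd14_hypovolemia_treatment",
    ),
}

KNOWN_FAULTS: frozenset[str] = frozenset(CDEV_ITEM_IDS) | frozenset(FAULT_ALIASES)


def expand_faults(names) -> frozenset[str]:
    """Resolve fault names (item ids or aliases) to checklist item ids."""
    out: set[str] = set()
    for name in names:
        if name in FAULT_ALIASES:
            out.update(FAULT_ALIASES[name])
        elif name in CDEV_ITEM_IDS:
            out.add(name)
        else:
            raise ValueError(f"unknown fault name {name!r}")
    return frozenset(out)
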
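"""Canonical 12-lead definitions and the anatomical lead-region map.

Every signal matrix in this package uses the fixed row order
``LEAD_NAMES``.  The region map ties each myocardial-infarction subtype to
the subset of leads that classically reflect the injured wall; it drives
both the synthetic-data generator and lead-weight sanity checks.
"""

from __future__ import annotations

LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

N_LEADS = len(LEAD_NAMES)

_LOWER_TO_CANON = {name.lower(): name for name in LEAD_NAMES}

# Frank orthogonal leads occasionally present in PhysioNet-style records;
# they are recognised and dropped on read.
FRANK_LEADS: tuple[str, ...] = ("vx", "vy", "vz")

# anatomical wall -> leads facing it
REGION_LEADS: dict[str, tuple[str, ...]] = {
    "anterior": ("V3", "V4"),
    "septal": ("V1", "V2"),
    "inferior": ("II", "III", "aVF"),
    "lateral": ("I", "aVL", "V5", "V6"),
}

# MI subtype -> affected leads (union over the involved walls)
CLASS_AFFECTED_LEADS: dict[str, tuple[str, ...]] = {
    "HC": (),
    "AMI": REGION_LEADS["anterior"],
    "ALMI": REGION_LEADS["anterior"] + REGION_LEADS["lateral"],
    "ASMI": REGION_LEADS["septal"] + REGION_LEADS["anterior"],
    "IMI": REGION_LEADS["inferior"],
    "ILMI": REGION_LEADS["inferior"] + ("V5", "V6"),
}

MI_CLASSES: tuple[str, ...] = ("AMI", "ALMI", "ASMI", "IMI", "ILMI")
ALL_CLASSES: tuple[str, ...] = ("HC",) + MI_CLASSES


def canonical_lead(name: str) -> str:
    """Map a lead name to its canonical spelling (case-insensitive)."""
    try:
        return _LOWER_TO_CANON[name.strip().lower()]
    except KeyError:
        raise KeyError(f"unknown ECG lead name: {name!r}") from None


def lead_index(name: str) -> int:
    return LEAD_NAMES.index(canonical_lead(name))
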
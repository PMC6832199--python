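"""Patient-level cohort records and the fixed 7-marker serum panel."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import SchemaError

#: Canonical panel order; cohort CSV columns and all per-marker reports use it.
MARKERS: tuple[str, ...] = (
    "miR-122",
    "miR-133a",
    "miR-143",
    "miR-150",
    "miR-155",
    "miR-192",
    "miR-223",
)

#: Literal token naming the age item inside a score definition.
AGE: str = "AGE"


@dataclass(frozen=True)
class CohortRecord:
    """One patient: demographics, outcomes, follow-up and marker levels.

    Attributes
    ----------
    patient_id : str
        Opaque identifier.
    age : float
        Age in years.
    sepsis : bool
        Sepsis-3 criteria fulfilled at admission.
    icu_death : bool
        Died during the ICU stay.
    icu_los : float
        ICU length of stay in days (the time axis of ICU-survival analyses).
    overall_event : bool
        Died at any point of the total observation period.
    followup_time : float
        Days to death or right censoring.
    markers : Mapping[str, float]
        Serum level per panel marker, arbitrary units, strictly positive.
    """

    patient_id: str
    age: float
    sepsis: bool
    icu_death: bool
    icu_los: float
    overall_event: bool
    followup_time: float
    markers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.icu_death and not self.overall_event:
            raise SchemaError(
                f"{self.patient_id}: icu_death implies overall_event"
            )
        if not self.followup_time > 0:
            raise SchemaError(f"{self.patient_id}: followup_time must be > 0")
        if not self.icu_los > 0:
            raise SchemaError(f"{self.patient_id}: icu_los must be > 0")
        missing = [m for m in MARKERS if m not in self.markers]
        extra = [m for m in self.markers if m not in MARKERS]
        if missing or extra:
            raise SchemaError(
                f"{self.patient_id}: marker panel mismatch "
                f"(missing={missing}, unexpected={extra})"
            )
        for name, level in self.markers.items():
            if not level > 0:
                raise SchemaError(
                    f"{self.patient_id}: marker {name} must be > 0, got {level}"
                )
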
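"""Patient-level data model for large hemispheric infarction (LHI) cohorts.

A :class:`PatientRecord` carries everything the risk scores need: vascular
risk-factor history, NIHSS severity at admission and day 5, the three early
CT signs (>1/3 hypodensity, hyperdense MCA sign, brain edema), the MCA
territory involvement that defines complete vs incomplete infarction, and
the in-hospital outcome flags.  Records validate on construction; the
cohort readers collect per-row validation failures instead of aborting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields

__all__ = [
    "TERRITORIES",
    "InfarctClass",
    "PatientRecord",
    "RecordValidationError",
    "BOOL_FIELDS",
]

#: The three vascular subdivisions of the MCA territory.
TERRITORIES = frozenset({"deep", "superior", "posterior"})

#: Binary indicator fields, in canonical column order.
BOOL_FIELDS = (
    "chf",
    "hypertension",
    "diabetes",
    "prior_stroke_or_tia",
    "atrial_fibrillation",
    "smoking",
    "hypercholesterolemia",
    "coronary_artery_disease",
    "hypodensity_gt_one_third",
    "hmcas",
    "brain_edema",
    "died_in_hospital",
    "stroke_related_death",
    "thrombolysis",
    "craniectomy",
)


class RecordValidationError(ValueError):
    """A patient record violated a domain invariant.

    ``errors`` lists ``(field, message)`` pairs so cohort readers can report
    every problem in a row at once.
    """

    def __init__(self, errors: list[tuple[str, str]]):
        self.errors = errors
        super().__init__(
            "; ".join(f"{f}: {m}" for f, m in errors) or "invalid record"
        )


class InfarctClass(enum.Enum):
    """MCA-territory classification of an ischemic infarct.

    CMCA — complete MCA infarction: all three (deep, superior, posterior)
    territories involved.  IMCA — incomplete MCA infarction: more than 50%
    of the MCA territory but not all three subdivisions.  NOT_LHI — below
    the large-hemispheric-infarction threshold; the mortality scores are
    not defined for these patients.
    """

    CMCA = "CMCA"
    IMCA = "IMCA"
    NOT_LHI = "NOT_LHI"

    def is_lhi(self) -> bool:
        return self is not InfarctClass.NOT_LHI


@dataclass(frozen=True)
class PatientRecord:
    """One patient's clinical, radiographic and outcome fields.

    ``nihss_day5`` is ``None`` when the day-5 assessment is missing.
    ``territories`` is a subset of :data:`TERRITORIES`; ``mca_fraction`` is
    the fraction of the MCA territory involved on follow-up imaging.
    """

    patient_id: str
    age: int
    sex: str  # "male" | "female"
    chf: bool
    hypertension: bool
    diabetes: bool
    prior_stroke_or_tia: bool
    atrial_fibrillation: bool
    smoking: bool
    hypercholesterolemia: bool
    coronary_artery_disease: bool
    nihss_admission: int
    nihss_day5: int | None
    hypodensity_gt_one_third: bool
    hmcas: bool
    brain_edema: bool
    territories: frozenset = field(default_factory=frozenset)
    mca_fraction: float = 0.0
    died_in_hospital: bool = False
    stroke_related_death: bool = False
    thrombolysis: bool = False
    craniectomy: bool = False

    def __post_init__(self):
        errors: list[tuple[str, str]] = []
        if not 18 <= self.age <= 120:
            errors.append(("age", f"age {self.age} outside [18, 120]"))
        if self.sex not in ("male", "female"):
            errors.append(("sex", f"sex must be 'male' or 'female', got {self.sex!r}"))
        if not 0 <= self.nihss_admission <= 42:
            errors.append(
                ("nihss_admission", f"NIHSS {self.nihss_admission} outside [0, 42]")
            )
        if self.nihss_day5 is not None and not 0 <= self.nihss_day5 <= 42:
            errors.append(("nihss_day5", f"NIHSS {self.nihss_day5} outside [0, 42]"))
        object.__setattr__(self, "territories", frozenset(self.territories))
        bad = self.territories - TERRITORIES
        if bad:
            errors.append(
                ("territories", f"unknown territories {sorted(bad)}; "
                                f"allowed: {sorted(TERRITORIES)}")
            )
        if not 0.0 <= self.mca_fraction <= 1.0:
            errors.append(
                ("mca_fraction", f"mca_fraction {self.mca_fraction} outside [0, 1]")
            )
        if self.stroke_related_death and not self.died_in_hospital:
            errors.append(
                ("stroke_related_death",
                 "stroke_related_death requires died_in_hospital")
            )
        for f in BOOL_FIELDS:
            v = getattr(self, f)
            if not isinstance(v, (bool,)):
                if v in (0, 1):
                    object.__setattr__(self, f, bool(v))
                else:
                    errors.append((f, f"indicator must be 0/1 or bool, got {v!r}"))
        if errors:
            raise RecordValidationError(errors)

    @property
    def peak_nihss_5d(self) -> int:
        """Highest NIHSS observed in the first 5 days (admission or day 5)."""
        if self.nihss_day5 is None:
            return self.nihss_admission
        return max(self.nihss_admission, self.nihss_day5)


def record_field_names() -> list[str]:
    """Field names of :class:`PatientRecord` in declaration order."""
    return [f.name for f in fields(PatientRecord)]
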
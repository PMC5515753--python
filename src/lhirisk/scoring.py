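"""Rule-based risk scores for large hemispheric infarction.

Four additive scores, each a sum of binary indicators compared against an
inclusive cutoff:

* **CHADS₂** — congestive heart failure, hypertension, age ≥ 75, diabetes
  (1 point each) and prior stroke/TIA (2 points); range 0–6.  Used here as
  a component (≥ 4) of the mortality scores.
* **CMCA score** — predicts complete MCA infarction from admission-window
  data: >1/3 early hypodensity, hyperdense MCA sign, brain edema, admission
  NIHSS ≥ 17, and stroke in progression (NIHSS rise ≥ 2 or stroke-related
  death by day 5); 1 point each, range 0–5, cutoff 2.
* **Mortality score 1** — CMCA infarction + CHADS₂ ≥ 4; range 0–2, cutoff 1.
* **Mortality score 2** — CMCA infarction + CHADS₂ ≥ 4 + NIHSS ≥ 26 within
  the first 5 days; range 0–3, cutoff 2.

All cutoffs are configuration values with the published defaults so that
sensitivity analyses can move them without touching the definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

from .records import TERRITORIES, InfarctClass, PatientRecord

__all__ = [
    "ScoreConfig",
    "ScoreBreakdown",
    "ScoreDomainError",
    "classify_infarct",
    "compute_chads2",
    "is_stroke_in_progression",
    "compute_cmca_score",
    "compute_mortality_score1",
    "compute_mortality_score2",
]


class ScoreDomainError(ValueError):
    """A score was requested outside its domain (e.g. mortality score on NOT_LHI)."""


@dataclass(frozen=True)
class ScoreConfig:
    """Thresholds for every score, defaulting to the published values.

    All comparisons are inclusive (``>=``).
    """

    nihss_admission_cutoff: int = 17   # CMCA-score severity component
    nihss_peak_cutoff: int = 26        # mortality-score-2 severity component
    chads2_cutoff: int = 4             # CHADS2-as-component threshold
    sip_delta: int = 2                 # NIHSS rise defining stroke in progression
    lhi_fraction: float = 0.5          # minimum MCA fraction for LHI/IMCA
    cmca_score_cutoff: int = 2
    mortality1_cutoff: int = 1
    mortality2_cutoff: int = 2
    # "peak": max(admission, day 5) NIHSS for mortality score 2 (severity at
    # any point in the 5-day window); "day5": day-5 value only, falling back
    # to admission when day 5 is missing.
    nihss_window: str = "peak"

    def __post_init__(self):
        if self.nihss_window not in ("peak", "day5"):
            raise ValueError("nihss_window must be 'peak' or 'day5'")

    def with_cutoffs(self, **kwargs) -> "ScoreConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = ScoreConfig()


@dataclass(frozen=True)
class ScoreBreakdown:
    """A named score with its per-component contributions.

    ``components`` is an ordered list of ``(name, met, points)``; ``total``
    is the sum of points over met components; ``positive`` is
    ``total >= cutoff``.
    """

    score_name: str
    components: tuple  # of (name, met: bool, points: int)
    cutoff: int
    total: int = field(init=False)
    positive: bool = field(init=False)

    def __post_init__(self):
        total = sum(p for _, met, p in self.components if met)
        object.__setattr__(self, "total", total)
        object.__setattr__(self, "positive", total >= self.cutoff)

    def component_dict(self) -> dict[str, bool]:
        return {name: met for name, met, _ in self.components}


def classify_infarct(
    territories: Iterable[str],
    mca_fraction: float,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> InfarctClass:
    """Classify MCA-territory involvement.

    CMCA requires all three territories (deep, superior, posterior),
    regardless of the reported fraction; otherwise an involvement fraction
    ≥ 0.5 is IMCA; anything smaller is below the LHI threshold.
    """
    territories = frozenset(territories)
    bad = territories - TERRITORIES
    if bad:
        raise ValueError(
            f"unknown territories {sorted(bad)}; allowed: {sorted(TERRITORIES)}"
        )
    if not 0.0 <= mca_fraction <= 1.0:
        raise ValueError(f"mca_fraction {mca_fraction} outside [0, 1]")
    if territories == TERRITORIES:
        return InfarctClass.CMCA
    if mca_fraction >= config.lhi_fraction:
        return InfarctClass.IMCA
    return InfarctClass.NOT_LHI


def compute_chads2(record: PatientRecord, config: ScoreConfig = DEFAULT_CONFIG) -> ScoreBreakdown:
    """CHADS₂ cardioembolic-risk score (range 0–6, prior stroke weighted 2)."""
    components = (
        ("chf", record.chf, 1),
        ("hypertension", record.hypertension, 1),
        ("age_ge_75", record.age >= 75, 1),
        ("diabetes", record.diabetes, 1),
        ("prior_stroke_or_tia", record.prior_stroke_or_tia, 2),
    )
    return ScoreBreakdown("CHADS2", components, cutoff=config.chads2_cutoff)


def is_stroke_in_progression(
    record: PatientRecord, config: ScoreConfig = DEFAULT_CONFIG
) -> bool:
    """NIHSS rise ≥ 2 between admission and day 5, or stroke-related death.

    A surviving patient with no day-5 NIHSS cannot be assessed; the
    indicator evaluates False and a data-completeness warning is emitted
    (no imputation is attempted).
    """
    if record.stroke_related_death:
        return True
    if record.nihss_day5 is None:
        if not record.died_in_hospital:
            warnings.warn(
                f"patient {record.patient_id}: day-5 NIHSS missing in a "
                "survivor; stroke-in-progression assumed absent",
                UserWarning,
                stacklevel=2,
            )
        return False
    return record.nihss_day5 - record.nihss_admission >= config.sip_delta


def compute_cmca_score(
    record: PatientRecord, config: ScoreConfig = DEFAULT_CONFIG
) -> ScoreBreakdown:
    """Predictive score for complete MCA infarction (range 0–5, cutoff 2)."""
    components = (
        ("hypodensity_gt_one_third", record.hypodensity_gt_one_third, 1),
        ("hmcas", record.hmcas, 1),
        ("brain_edema", record.brain_edema, 1),
        ("nihss_admission_ge_17",
         record.nihss_admission >= config.nihss_admission_cutoff, 1),
        ("stroke_in_progression", is_stroke_in_progression(record, config), 1),
    )
    return ScoreBreakdown("CMCA_SCORE", components, cutoff=config.cmca_score_cutoff)


def _require_lhi(infarct: InfarctClass, score_name: str) -> None:
    if infarct is InfarctClass.NOT_LHI:
        raise ScoreDomainError(
            f"{score_name} is defined only for LHI patients (CMCA or IMCA)"
        )


def _window_nihss(record: PatientRecord, config: ScoreConfig) -> int:
    if config.nihss_window == "day5" and record.nihss_day5 is not None:
        return record.nihss_day5
    return record.peak_nihss_5d


def compute_mortality_score1(
    record: PatientRecord,
    infarct: InfarctClass,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> ScoreBreakdown:
    """First in-hospital mortality score: CMCA + CHADS₂ ≥ 4 (cutoff 1)."""
    _require_lhi(infarct, "mortality score 1")
    chads2 = compute_chads2(record, config)
    components = (
        ("cmca", infarct is InfarctClass.CMCA, 1),
        ("chads2_ge_cutoff", chads2.total >= config.chads2_cutoff, 1),
    )
    return ScoreBreakdown("MORTALITY_1", components, cutoff=config.mortality1_cutoff)


def compute_mortality_score2(
    record: PatientRecord,
    infarct: InfarctClass,
    config: ScoreConfig = DEFAULT_CONFIG,
) -> ScoreBreakdown:
    """Second mortality score: CMCA + CHADS₂ ≥ 4 + NIHSS ≥ 26 in 5 days (cutoff 2).

    The severity component uses the peak of admission and day-5 NIHSS by
    default (``config.nihss_window``), so a patient who deteriorates after
    admission is captured.
    """
    _require_lhi(infarct, "mortality score 2")
    chads2 = compute_chads2(record, config)
    components = (
        ("cmca", infarct is InfarctClass.CMCA, 1),
        ("chads2_ge_cutoff", chads2.total >= config.chads2_cutoff, 1),
        ("nihss_5d_ge_cutoff",
         _window_nihss(record, config) >= config.nihss_peak_cutoff, 1),
    )
    return ScoreBreakdown("MORTALITY_2", components, cutoff=config.mortality2_cutoff)
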
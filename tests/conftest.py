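import pytest

from lhirisk import PatientRecord


@pytest.fixture
def make_record():
    """Factory for a valid record; defaults: 60-year-old IMCA survivor, no risk factors."""

    def _make(**overrides):
        base = dict(
            patient_id="p1",
            age=60,
            sex="male",
            chf=False,
            hypertension=False,
            diabetes=False,
            prior_stroke_or_tia=False,
            atrial_fibrillation=False,
            smoking=False,
            hypercholesterolemia=False,
            coronary_artery_disease=False,
            nihss_admission=10,
            nihss_day5=10,
            hypodensity_gt_one_third=False,
            hmcas=False,
            brain_edema=False,
            territories=frozenset({"deep", "superior"}),
            mca_fraction=0.6,
            died_in_hospital=False,
            stroke_related_death=False,
            thrombolysis=False,
            craniectomy=False,
        )
        base.update(overrides)
        return PatientRecord(**base)

    return _make
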
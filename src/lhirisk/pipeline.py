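"""End-to-end cohort analysis.

``score_patients`` computes every score with its component breakdown for
each patient; ``analyze_cohort`` adds the group-comparison table (t tests
for numeric fields, chi-square for binary ones) and the three ROC analyses
— the complete-infarction score against CMCA group membership, and the two
mortality scores against in-hospital death — and packages everything in an
:class:`AnalysisReport` that serializes losslessly to JSON.

One temporal caveat is inherited from the score definitions and computed
as written: the CMCA score contains a day-5 component (stroke in
progression) yet predicts a classification itself made on second imaging,
so its ROC is an in-sample association, not a prospective validation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .records import BOOL_FIELDS, InfarctClass, PatientRecord
from .scoring import (
    DEFAULT_CONFIG,
    ScoreConfig,
    classify_infarct,
    compute_chads2,
    compute_cmca_score,
    compute_mortality_score1,
    compute_mortality_score2,
)
from .stats import (
    DegenerateInputError,
    pct,
    pearson_chi2,
    roc_curve,
    sens_spec,
    two_sample_t,
)

__all__ = ["AnalysisReport", "score_patients", "analyze_cohort"]

_NUMERIC_FIELDS = ("age", "nihss_admission", "nihss_day5")
_COMPARED_BOOL_FIELDS = tuple(
    f for f in BOOL_FIELDS if f != "stroke_related_death"
) + ("stroke_in_progression",)


def score_patients(
    cohort: list[PatientRecord], config: ScoreConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Per-patient score table.

    One row per patient with the infarct class, each score total, each
    positivity flag and every component indicator.  Mortality scores of
    patients below the LHI threshold are NA with ``mortality_applicable``
    False.
    """
    rows = []
    for rec in cohort:
        infarct = classify_infarct(rec.territories, rec.mca_fraction, config)
        chads2 = compute_chads2(rec, config)
        cmca_score = compute_cmca_score(rec, config)
        row: dict[str, Any] = {
            "patient_id": rec.patient_id,
            "infarct_class": infarct.value,
            "chads2_total": chads2.total,
            "cmca_score_total": cmca_score.total,
            "cmca_score_positive": cmca_score.positive,
            "mortality_applicable": infarct.is_lhi(),
            "died_in_hospital": rec.died_in_hospital,
        }
        for name, met in cmca_score.component_dict().items():
            row["cmca_component_" + name] = met
        if infarct.is_lhi():
            m1 = compute_mortality_score1(rec, infarct, config)
            m2 = compute_mortality_score2(rec, infarct, config)
            row.update(
                mortality1_total=m1.total, mortality1_positive=m1.positive,
                mortality2_total=m2.total, mortality2_positive=m2.positive,
            )
        else:
            row.update(
                mortality1_total=pd.NA, mortality1_positive=pd.NA,
                mortality2_total=pd.NA, mortality2_positive=pd.NA,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """Structured analysis output.

    ``group_comparison`` maps variable -> {cmca, imca, test, statistic, p};
    for binary variables the group entries carry counts and percentages,
    for numeric ones means and sds.  ``roc`` maps score name -> {auc,
    best_cutoff, sens/spec at the best and at the default cutoff, points,
    target}.  ``provenance.timestamp`` is None unless explicitly supplied,
    so reports are bit-identical across runs by default.
    """

    summary: dict = field(default_factory=dict)
    group_comparison: dict = field(default_factory=dict)
    roc: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)
    patient_scores: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True,
                          default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        return cls(**json.loads(text))

    def to_text(self) -> str:
        """Human-readable summary tables."""
        out = []
        s = self.summary
        out.append(f"Cohort: n={s['n']}  CMCA {s['n_cmca']} ({s['pct_cmca']}%)  "
                   f"IMCA {s['n_imca']} ({s['pct_imca']}%)  "
                   f"NOT_LHI {s['n_not_lhi']}")
        out.append(f"In-hospital mortality: {s['n_died']}/{s['n']} "
                   f"({s['pct_died']}%)")
        out.append("")
        out.append(f"{'variable':<28}{'CMCA':>16}{'IMCA':>16}{'test':>8}{'p':>10}")
        for name, row in self.group_comparison.items():
            cm, im = row["cmca"], row["imca"]
            if row["test"] == "chi2":
                c1 = f"{cm['k']}/{cm['n']} ({cm['pct']}%)"
                c2 = f"{im['k']}/{im['n']} ({im['pct']}%)"
            else:
                c1 = f"{cm['mean']:.1f}±{cm['sd']:.1f}"
                c2 = f"{im['mean']:.1f}±{im['sd']:.1f}"
            p = "NA" if row["p"] is None else f"{row['p']:.3f}"
            out.append(f"{name:<28}{c1:>16}{c2:>16}{row['test']:>8}{p:>10}")
        out.append("")
        for name, r in self.roc.items():
            out.append(
                f"ROC {name} (target: {r['target']}): AUC={r['auc']:.3f}  "
                f"best cutoff={r['best_cutoff']:g} "
                f"(sens {r['sens_at_best_pct']}%, spec {r['spec_at_best_pct']}%); "
                f"default cutoff={r['default_cutoff']:g} "
                f"(sens {r['sens_at_default_pct']}%, "
                f"spec {r['spec_at_default_pct']}%)"
            )
        for n_ in self.notices:
            out.append(f"NOTE: {n_}")
        return "\n".join(out)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if obj is pd.NA or (isinstance(obj, float) and np.isnan(obj)):
        return None
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _binary_row(mask_cmca, mask_imca, values) -> dict:
    values = np.asarray(values, dtype=bool)
    k1, n1 = int(values[mask_cmca].sum()), int(mask_cmca.sum())
    k2, n2 = int(values[mask_imca].sum()), int(mask_imca.sum())
    row = {
        "cmca": {"k": k1, "n": n1, "pct": pct(k1, n1) if n1 else None},
        "imca": {"k": k2, "n": n2, "pct": pct(k2, n2) if n2 else None},
        "test": "chi2",
    }
    try:
        stat, p = pearson_chi2([[k1, n1 - k1], [k2, n2 - k2]])
        row["statistic"], row["p"] = stat, p
    except DegenerateInputError:
        row["statistic"], row["p"] = None, None
    return row


def _numeric_row(mask_cmca, mask_imca, values, welch: bool) -> dict:
    values = np.asarray(values, dtype=float)
    out = {"test": "welch_t" if welch else "t"}
    for key, mask in (("cmca", mask_cmca), ("imca", mask_imca)):
        v = values[mask]
        v = v[~np.isnan(v)]
        out[key] = {"n": int(len(v)),
                    "mean": float(v.mean()) if len(v) else None,
                    "sd": float(v.std(ddof=1)) if len(v) > 1 else None}
    v1 = values[mask_cmca]
    v2 = values[mask_imca]
    v1, v2 = v1[~np.isnan(v1)], v2[~np.isnan(v2)]
    if len(v1) >= 2 and len(v2) >= 2:
        stat, p = two_sample_t(v1, v2, welch=welch)
        out["statistic"], out["p"] = stat, p
    else:
        out["statistic"], out["p"] = None, None
    return out


def _roc_section(scores, labels, default_cutoff, target: str) -> dict:
    roc = roc_curve(scores, labels)
    se_d, sp_d = sens_spec(scores, labels, default_cutoff)
    return {
        "target": target,
        "auc": roc.auc,
        "best_cutoff": roc.best_cutoff,
        "sens_at_best_pct": pct(round(roc.sens_at_best * 10000), 10000),
        "spec_at_best_pct": pct(round(roc.spec_at_best * 10000), 10000),
        "default_cutoff": default_cutoff,
        "sens_at_default_pct": pct(round(se_d * 10000), 10000),
        "spec_at_default_pct": pct(round(sp_d * 10000), 10000),
        "points": [list(p) if p[0] != np.inf else ["inf", p[1], p[2]]
                   for p in roc.points],
    }


def analyze_cohort(
    cohort: list[PatientRecord],
    config: ScoreConfig = DEFAULT_CONFIG,
    welch: bool = False,
    seed: int | None = None,
) -> AnalysisReport:
    """Full cohort analysis: scores, group comparisons and ROC curves.

    ROC targets: the CMCA score against CMCA group membership; both
    mortality scores against in-hospital death (LHI patients only).  A
    single-outcome cohort omits the corresponding ROC with a notice.
    """
    if len(cohort) < 2:
        raise ValueError("need at least 2 patients")
    table = score_patients(cohort, config)
    infarct = table["infarct_class"].to_numpy()
    mask_cmca = infarct == "CMCA"
    mask_imca = infarct == "IMCA"
    died = np.array([r.died_in_hospital for r in cohort])

    report = AnalysisReport()
    n = len(cohort)
    report.summary = {
        "n": n,
        "n_cmca": int(mask_cmca.sum()),
        "n_imca": int(mask_imca.sum()),
        "n_not_lhi": int((infarct == "NOT_LHI").sum()),
        "pct_cmca": pct(int(mask_cmca.sum()), n),
        "pct_imca": pct(int(mask_imca.sum()), n),
        "n_died": int(died.sum()),
        "pct_died": pct(int(died.sum()), n),
        "n_stroke_in_progression":
            int(table["cmca_component_stroke_in_progression"].sum()),
        "pct_stroke_in_progression":
            pct(int(table["cmca_component_stroke_in_progression"].sum()), n),
    }

    if mask_cmca.sum() >= 2 and mask_imca.sum() >= 2:
        comp = {}
        for name in _NUMERIC_FIELDS:
            vals = [getattr(r, name) if getattr(r, name) is not None else np.nan
                    for r in cohort]
            comp[name] = _numeric_row(mask_cmca, mask_imca, vals, welch)
        for name in _COMPARED_BOOL_FIELDS:
            if name == "stroke_in_progression":
                vals = table["cmca_component_stroke_in_progression"].to_numpy()
            else:
                vals = [getattr(r, name) for r in cohort]
            comp[name] = _binary_row(mask_cmca, mask_imca, vals)
        report.group_comparison = comp
    else:
        report.notices.append(
            "group comparison omitted: fewer than 2 patients in a group"
        )

    # ROC analyses
    if mask_cmca.any() and mask_imca.any():
        lhi = mask_cmca | mask_imca
        report.roc["cmca_score"] = _roc_section(
            table.loc[lhi, "cmca_score_total"].to_numpy(float),
            mask_cmca[lhi].astype(int),
            config.cmca_score_cutoff, target="cmca_membership",
        )
    else:
        report.notices.append("CMCA-score ROC omitted: single infarct group")
    lhi = table["mortality_applicable"].to_numpy(bool)
    if died[lhi].any() and not died[lhi].all():
        for score, cut in (("mortality1", config.mortality1_cutoff),
                           ("mortality2", config.mortality2_cutoff)):
            report.roc[score] = _roc_section(
                table.loc[lhi, score + "_total"].to_numpy(float),
                died[lhi].astype(int),
                cut, target="in_hospital_death",
            )
    else:
        report.notices.append(
            "mortality ROC omitted: only one outcome present among LHI patients"
        )

    report.patient_scores = [
        {k: (None if v is pd.NA else v) for k, v in row.items()}
        for row in table.to_dict(orient="records")
    ]
    cfg = asdict(config)
    report.provenance = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": seed,
        "timestamp": None,
    }
    return report
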
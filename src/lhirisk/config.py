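"""Configuration loading: one YAML file mirroring the generator and analysis knobs."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .scoring import ScoreConfig
from .simulate import CohortParams

__all__ = ["default_config", "load_config", "parse_config"]

_SCORE_KEYS = {
    "nihss_admission_cutoff", "nihss_peak_cutoff", "chads2_cutoff",
    "sip_delta", "lhi_fraction", "cmca_score_cutoff",
    "mortality1_cutoff", "mortality2_cutoff", "nihss_window",
}
_TUPLE_KEYS = {
    k for k in CohortParams.__dataclass_fields__
    if k.startswith("p_") and k not in ("p_cmca", "p_male")
} | {"age_range", "nihss_admission_mean", "nihss_day5_mean",
     "imca_fraction_range"}


def default_config() -> dict:
    """The shipped default configuration as a plain dict."""
    text = resources.files("lhirisk").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return default_config()
    return yaml.safe_load(Path(path).read_text())


def parse_config(cfg: dict) -> tuple[CohortParams, ScoreConfig, dict]:
    """Split a config dict into (CohortParams, ScoreConfig, analysis options)."""
    cohort = dict(cfg.get("cohort", {}))
    for k in list(cohort):
        if k in _TUPLE_KEYS:
            cohort[k] = tuple(cohort[k])
    params = CohortParams(**cohort)
    analysis = dict(cfg.get("analysis", {}))
    score_cfg = ScoreConfig(**{k: v for k, v in analysis.items() if k in _SCORE_KEYS})
    options = {k: v for k, v in analysis.items() if k not in _SCORE_KEYS}
    return params, score_cfg, options
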
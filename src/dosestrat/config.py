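"""Configuration: shipped defaults plus YAML overrides.

The package ships a ``defaults.yaml`` with the ROI vocabulary, the paired
left/right organ families, the per-symptom cluster feature windows and NTCP
organ lists, and algorithm hyperparameters.  ``load_config`` returns that
mapping, optionally deep-merged with a user YAML file.
"""

from __future__ import annotations

import copy
import importlib.resources
import logging
from typing import Any, Mapping

import yaml

log = logging.getLogger("dosestrat")

SYMPTOMS = ("drymouth", "swallow", "mucus", "voice")

#: fixed questionnaire timepoint labels: baseline, 7 weekly on-treatment
#: ratings, 6-week and 6-month follow-up (the analysed late timepoint).
TIMEPOINTS = (
    "baseline",
    "week1", "week2", "week3", "week4", "week5", "week6", "week7",
    "followup_6wk",
    "followup_6mo",
)
LATE_TIMEPOINT = "followup_6mo"


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def default_config() -> dict[str, Any]:
    """Return the shipped default configuration as a fresh dict."""
    text = (
        importlib.resources.files("dosestrat") / "data" / "defaults.yaml"
    ).read_text()
    return yaml.safe_load(text)


def load_config(path: str | None = None) -> dict[str, Any]:
    """Load defaults, deep-merged with the YAML file at *path* if given."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ValueError(f"config file {path!r} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    return cfg
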
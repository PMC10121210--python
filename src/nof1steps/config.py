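"""YAML/JSON configuration for the simulate -> impute -> analyze -> report chain."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from .design import TrialDesign
from .simulate import (
    SimulationParams,
    default_minute_intensity,
    default_wear_probability,
)


@dataclass
class AnalysisOptions:
    include_baseline: bool = False
    carryover_lag_days: int = 0
    impute: bool = True
    min_obs: int = 5
    smooth: bool = True


@dataclass
class RunConfig:
    design: TrialDesign = field(default_factory=TrialDesign)
    params: SimulationParams = field(default_factory=SimulationParams)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    n_participants: int = 26


def _build_params(section: Dict[str, Any]) -> SimulationParams:
    section = dict(section)
    if "total_daily_steps" in section:
        section["minute_intensity"] = default_minute_intensity(
            float(section.pop("total_daily_steps"))
        )
    if "wear_prob" in section:  # scalar shorthand for a flat profile
        section["wear_prob_profile"] = np.full(1440, float(section.pop("wear_prob")))
    return SimulationParams(**section)


def load_config(path) -> RunConfig:
    """Load a run configuration from a YAML (or JSON) file.

    Recognized top-level keys: ``design``, ``simulation``, ``analysis``,
    ``n_participants``; all optional, with package defaults.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    design_kw = raw.get("design", {})
    if "sequences" in design_kw:
        design_kw["sequences"] = tuple(tuple(s) for s in design_kw["sequences"])
    if "randomization_ratio" in design_kw:
        design_kw["randomization_ratio"] = tuple(design_kw["randomization_ratio"])
    design = TrialDesign(**design_kw)
    params = _build_params(raw.get("simulation", {}))
    analysis = AnalysisOptions(**raw.get("analysis", {}))
    return RunConfig(
        design=design,
        params=params,
        analysis=analysis,
        n_participants=int(raw.get("n_participants", 26)),
    )
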
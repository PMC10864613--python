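"""Run configuration: drug dictionaries, analysis windows, statistical options."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field

from .cohort import DrugDictionary


class DrugConfig(BaseModel):
    """Per-drug settings: names, quarter window, label and indication terms."""

    dictionary: DrugDictionary
    window_start: str
    window_end: str
    #: PT terms listed in the product label, for expectedness flagging;
    #: None means expectedness cannot be evaluated
    label_terms: list[str] | None = None
    #: explicit indication-term exclusion list; None means use the INDI_PT
    #: values observed for the drug
    indication_terms: list[str] | None = None


class StatsConfig(BaseModel):
    """Statistical switches for the disproportionality stage."""

    continuity_correction: bool = False
    yates: bool = False
    bcpnn_method: Literal["closed_form", "monte_carlo"] = "closed_form"
    tto_min_n: int = Field(10, ge=2)


class RunConfig(BaseModel):
    drugs: dict[str, DrugConfig]
    stats: StatsConfig = Field(default_factory=StatsConfig)
    pt_soc_map: str | None = None
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)
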
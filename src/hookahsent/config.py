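"""Single-file pipeline configuration with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .corpus import DEFAULT_ROOT_TERMS
from .debias import (
    DEFAULT_BOT_THRESHOLD,
    DEFAULT_FOLLOWER_BAND_HALFWIDTH,
    DEFAULT_HUMAN_COMPOUND_STD,
    DEFAULT_HUMAN_MOBILE_FRACTION,
    DEFAULT_HUMAN_POS_PROFILE,
    FEATURE_NAMES,
)
from .synth import GeneratorConfig
from .valence import DEFAULT_ALPHA, DEFAULT_NEUTRAL_BAND


@dataclass
class PipelineConfig:
    """Every tunable default of the pipeline, stated in one place."""

    seed: int = 0
    input_path: Optional[str] = None  # read a corpus instead of generating
    root_terms: tuple[str, ...] = DEFAULT_ROOT_TERMS
    drop_retweets: bool = False
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    bot_threshold: float = DEFAULT_BOT_THRESHOLD
    bot_feature_weights: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in FEATURE_NAMES}
    )
    human_mobile_fraction: float = DEFAULT_HUMAN_MOBILE_FRACTION
    follower_band_halfwidth: float = DEFAULT_FOLLOWER_BAND_HALFWIDTH
    human_pos_profile: tuple[float, float, float] = DEFAULT_HUMAN_POS_PROFILE
    human_compound_std: float = DEFAULT_HUMAN_COMPOUND_STD
    neutral_band: float = DEFAULT_NEUTRAL_BAND
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise TypeError("seed must be an integer")
        for name, value in (
            ("bot_threshold", self.bot_threshold),
            ("neutral_band", self.neutral_band),
            ("alpha", self.alpha),
        ):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise TypeError(f"{name} must be numeric")
        unknown = set(self.bot_feature_weights) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown bot feature weights: {sorted(unknown)}")
        gen_fields = {f.name for f in dataclasses.fields(GeneratorConfig)}
        unknown = set(self.generator) - gen_fields
        if unknown:
            raise ValueError(f"unknown generator keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("root_terms", "human_pos_profile"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def generator_config(self) -> GeneratorConfig:
        overrides = dict(self.generator)
        overrides.setdefault("seed", self.seed)
        for key in ("sentiment_mix", "bot_sentiment_mix", "marketing_keywords"):
            if key in overrides and isinstance(overrides[key], list):
                overrides[key] = tuple(overrides[key])
        return GeneratorConfig(**overrides)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["root_terms"] = list(self.root_terms)
        out["human_pos_profile"] = list(self.human_pos_profile)
        return out
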
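"""Pipeline configuration: every tunable threshold in one validated object.

Defaults mirror the published analysis rules: expressed means >2 RPKM in
at least one library, a differential call needs |log2 fold change| > 2
with mean >= 2 RPKM, dosage dependence needs p < 0.01 with positive r,
and co-expression edges must clear the 5th/95th percentile ranks of the
per-bait correlation distribution.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class ScreeningConfig:
    min_length: int = 150
    max_length: int = 450
    min_tm: int = 5
    min_motifs: int = 1


@dataclass
class TmConfig:
    window: int = 19
    threshold: float = 1.6
    min_length: int = 15
    merge_gap: int = 3


@dataclass
class AlignConfig:
    matrix: str = "BLOSUM62"
    gap_open: int = 10
    gap_extend: int = 1


@dataclass
class ClassifyConfig:
    # accept a classification when the alignment score reaches this
    # fraction of the best reference's self-alignment score
    min_score_fraction: float = 0.40
    low_identity_flag: float = 0.30


@dataclass
class MotifConfig:
    variants: str = "ASVLCTG"
    spacing_min: int = 85
    spacing_max: int = 150


@dataclass
class ExpressionConfig:
    expressed_rpkm: float = 2.0      # strict: > 2 RPKM in >= 1 library
    deg_log2fc: float = 2.0          # strict: |log2fc| > 2
    deg_min_rpkm: float = 2.0        # mean >= 2 RPKM in one condition
    log_pseudocount: float = 1.0
    lower_percentile: float = 5.0
    upper_percentile: float = 95.0
    percentile_null: str = "per_bait"  # or "global"
    dosage_alpha: float = 0.01


@dataclass
class PipelineConfig:
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    tm: TmConfig = field(default_factory=TmConfig)
    align: AlignConfig = field(default_factory=AlignConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 0

    def validate(self) -> None:
        s = self.screening
        if not 0 < s.min_length <= s.max_length:
            raise ConfigError("screening lengths must satisfy 0 < min <= max")
        if self.tm.window % 2 != 1 or self.tm.window < 3:
            raise ConfigError("tm.window must be an odd integer >= 3")
        if self.tm.min_length < 1 or self.tm.merge_gap < 0:
            raise ConfigError("tm.min_length/merge_gap out of range")
        if not 0 < self.classify.min_score_fraction <= 1:
            raise ConfigError("classify.min_score_fraction must be in (0, 1]")
        m = self.motif
        if not 0 <= m.spacing_min <= m.spacing_max:
            raise ConfigError("motif spacing window must satisfy 0 <= min <= max")
        e = self.expression
        if not 0 <= e.lower_percentile <= e.upper_percentile <= 100:
            raise ConfigError("percentile ranks must satisfy 0 <= lower <= upper <= 100")
        if e.percentile_null not in {"per_bait", "global"}:
            raise ConfigError("percentile_null must be per_bait or global")
        if not 0 < e.dosage_alpha < 1:
            raise ConfigError("dosage_alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


_SECTIONS = {f.name: f.type for f in fields(PipelineConfig) if f.name != "seed"}
_SECTION_TYPES = {
    "screening": ScreeningConfig, "tm": TmConfig, "align": AlignConfig,
    "classify": ClassifyConfig, "motif": MotifConfig,
    "expression": ExpressionConfig,
}


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated config, rejecting unknown keys exhaustively."""
    errors: list[str] = []
    cfg = PipelineConfig()
    for key, value in data.items():
        if key == "seed":
            cfg.seed = int(value)
            continue
        if key not in _SECTION_TYPES:
            errors.append(f"unknown config section {key!r}")
            continue
        section_cls = _SECTION_TYPES[key]
        section = getattr(cfg, key)
        valid = {f.name for f in fields(section_cls)}
        for sub, subval in (value or {}).items():
            if sub not in valid:
                errors.append(f"unknown config key {key}.{sub!r}")
            else:
                setattr(section, sub, subval)
    if errors:
        raise ConfigError("; ".join(errors))
    cfg.validate()
    return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file (None -> defaults)."""
    if path is None:
        cfg = PipelineConfig()
        cfg.validate()
        return cfg
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return config_from_dict(data)
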
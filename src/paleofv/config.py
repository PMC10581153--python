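"""Pipeline configuration: one flat YAML of thresholds, validated on load.

Every default is either a published screening/orthology/dating threshold
(screen 0.40/0.40/1e-5; 30,000 bp flanks; blocks >= 500 bp; similarity
> 0.90; coverage > 0.50; artifact repeats >= 0.90 identity / >= 500 bp;
R = 1.5e-9) or an internal chaining/window choice documented in
docs/methods.md. Unknown keys are rejected so silent typos cannot change an
analysis; normalisation is idempotent.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    # screening
    screen_min_identity: float = 0.40
    screen_min_coverage: float = 0.40
    screen_max_e: float = 1e-5
    screen_report_max_e: float = 1e-3
    merge_max_gap_bp: int = 5000
    lineage_identity_threshold: float = 0.80
    # LTR detection
    ltr_min_len: int = 100
    ltr_max_len: int = 2000
    ltr_min_identity: float = 0.70
    # how far beyond the protein-hit hull to search for LTRs: untranslated
    # leader/trailer plus unprobed accessory genes can put an LTR >1 kb
    # outside the hull
    ltr_flank_extension: int = 2500
    # orthology
    flank_len: int = 30_000
    ortholog_min_identity: float = 0.90
    ortholog_min_coverage: float = 0.50
    ortholog_min_block: int = 500
    ortholog_max_e: float = 1e-5
    # artifact flagging
    artifact_min_len: int = 500
    artifact_min_identity: float = 0.90
    artifact_max_adjacency_gap: int = 1000
    # dating
    substitution_rate: float = 1.5e-9
    dating_model: str = "p-distance"
    # run plumbing
    seed: int = 0
    output_dir: str = "paleofv_out"
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        frac_keys = ("screen_min_identity", "screen_min_coverage",
                     "lineage_identity_threshold", "ltr_min_identity",
                     "ortholog_min_identity", "ortholog_min_coverage",
                     "artifact_min_identity")
        for key in frac_keys:
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key} = {v} is outside [0, 1]")
        for key in ("screen_max_e", "screen_report_max_e", "ortholog_max_e"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        for key in ("merge_max_gap_bp", "ltr_min_len", "ltr_max_len",
                    "ltr_flank_extension", "flank_len", "ortholog_min_block",
                    "artifact_min_len", "artifact_max_adjacency_gap"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if self.ltr_min_len > self.ltr_max_len:
            raise ConfigError("ltr_min_len exceeds ltr_max_len")
        if self.substitution_rate <= 0:
            raise ConfigError("substitution_rate must be positive")
        if self.dating_model not in ("p-distance", "JC69"):
            raise ConfigError(f"dating_model {self.dating_model!r} unknown")
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigError(f"log_level {self.log_level!r} unknown")
        return self


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Build a validated config from YAML plus keyword overrides.

    Missing keys take the defaults above; unknown keys raise naming the key.
    Flag-style ``overrides`` win over the file.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data).validate()


def normalize(cfg: PipelineConfig) -> PipelineConfig:
    """Validated copy with canonical types; idempotent."""
    d = dataclasses.asdict(cfg)
    for f in dataclasses.fields(PipelineConfig):
        if f.type == "int":
            d[f.name] = int(d[f.name])
        elif f.type == "float":
            d[f.name] = float(d[f.name])
    d["log_level"] = d["log_level"].upper()
    return PipelineConfig(**d).validate()


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
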
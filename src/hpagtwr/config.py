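"""Pipeline configuration: YAML-backed settings with seed fan-out.

One global seed deterministically derives a per-stage seed (stage name
hashed together with the global seed), so rerunning a single stage or the
full pipeline with the same config is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stage seed < 2^31 from the global seed and the stage name."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Settings for the end-to-end pipeline.

    ``mode`` is ``"simulate"`` (generate everything synthetically) or
    ``"ingest"`` (read panel/corpus/lexicon from ``paths``).
    """

    mode: str = "simulate"
    seed: int = 0
    paths: dict = field(default_factory=dict)  # panel, corpus, seed_lexicon
    generator: dict = field(default_factory=lambda: {
        "n_cities": 100, "extent_km": 1000.0, "years": [2018, 2019, 2020, 2021],
        "noise_sd": 0.05, "doc_length": 5000,
        "n_health_words": 30, "n_seed_words": 10, "n_filler_words": 200,
        "cooccurrence_sentences": 800,
    })
    cbow: dict = field(default_factory=lambda: {
        "dim": 100, "window": 5, "epochs": 20, "min_count": 5})
    expansion: dict = field(default_factory=lambda: {
        "top_k": 50, "min_similarity": 0.5})
    kernel: dict = field(default_factory=lambda: {
        "kernel": "gaussian", "lambda_s": 1.0, "mu_t": None,
        "bandwidth": "auto", "lo": None, "hi": None, "tol": None})
    diagnostics: dict = field(default_factory=lambda: {
        "knn_k": 5, "n_perm": 999, "split_year": 2020})

    def __post_init__(self):
        if self.mode not in ("simulate", "ingest"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "ingest":
            for key in ("panel",):
                if key not in self.paths:
                    raise ConfigurationError(
                        f"ingest mode requires paths.{key}")
            for key, p in self.paths.items():
                if not Path(p).exists():
                    raise ConfigurationError(
                        f"paths.{key} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        base = cls()
        for key in ("generator", "cbow", "expansion", "kernel", "diagnostics"):
            if key in merged:
                merged[key] = {**getattr(base, key), **merged[key]}
        return cls(**merged)

    def content_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
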
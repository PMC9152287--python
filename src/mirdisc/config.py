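"""Declarative run configuration and the exported summary schema.

A run is described by one YAML file with nested sections; every CLI flag
overrides its config key. The summary written by ``mirdisc evaluate`` is
validated against :class:`Summary` (whose JSON schema is shipped via
:func:`summary_schema`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class SyntheticSection(BaseModel):
    n_mirna: int = 500
    n_gene: int = 2000
    n_pos: int = 100
    sim_within: float = 0.6
    sim_background: float = 0.15
    sim_noise: float = 0.05
    targets_per_mirna: int = 40
    shared_target_pool: int = 200
    share_prob: float = 0.7
    missing_frac: float = 0.1


class InputsSection(BaseModel):
    similarity: Optional[str] = None
    interactions: Optional[str] = None
    labels: Optional[str] = None
    synthetic: Optional[SyntheticSection] = None


class EmbeddingSection(BaseModel):
    embedder: Literal["node2vec", "deepwalk"] = "node2vec"
    p: float = 10.0
    q: float = 0.5
    dim: int = 512
    num_walks: int = 10
    walk_length: int = 80
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025


class EncoderSection(BaseModel):
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    patience: int = 10
    dropout: float = 0.5
    code_dim: int = 256
    conv_channels: int = 16
    standardize: bool = False


class ExperimentSection(BaseModel):
    ratios: list[int | str] = Field(default_factory=lambda: ["all"])
    feature_sources: list[str] = Field(default_factory=lambda: ["both"])
    variants: list[str] = Field(default_factory=lambda: ["full"])
    folds: int = 5

    @field_validator("ratios")
    @classmethod
    def _check_ratios(cls, v):
        for r in v:
            if r != "all" and int(r) < 1:
                raise ValueError(f"bad negative ratio: {r!r}")
        return v


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: str = "mirdisc-run"
    inputs: InputsSection = Field(default_factory=InputsSection)
    embedding: EmbeddingSection = Field(default_factory=EmbeddingSection)
    encoder: EncoderSection = Field(default_factory=EncoderSection)
    experiment: ExperimentSection = Field(default_factory=ExperimentSection)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)


class SummaryRow(BaseModel):
    ratio: int | str
    feature_source: str
    embedder: str
    variant: str
    mean_roc_auc: float = Field(ge=0.0, le=1.0)
    mean_pr_auc: float = Field(ge=0.0, le=1.0)
    mean_f1: float = Field(ge=0.0, le=1.0)


class Summary(BaseModel):
    seed: int
    rows: list[SummaryRow]


def summary_schema() -> dict:
    """JSON schema of the evaluate summary (the shipped contract)."""
    return Summary.model_json_schema()


def validate_summary(payload: dict) -> Summary:
    return Summary.model_validate(payload)


def write_summary(payload: dict, path: str | Path) -> None:
    validate_summary(payload)
    Path(path).write_text(json.dumps(payload, indent=2))
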
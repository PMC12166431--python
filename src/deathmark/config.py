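"""Declarative pipeline configuration (YAML), schema-validated before any
stage runs. All randomness in a run flows from the single master ``seed``."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["InputPaths", "PipelineParams", "PipelineConfig", "load_config", "config_hash"]


class InputPaths(BaseModel):
    dose_response: dict[str, str]  # inducer name -> Table-1 style CSV
    expression: str
    gene_effect: str
    model_map: str
    signatures: str  # GCTX, or long TSV when signatures_format = "tsv"
    sig_info: str
    gene_info: str
    counts: str
    design: str
    citations: str | None = None  # offline citation fixture (JSON)
    signatures_format: str = "gctx"

    @field_validator("signatures_format")
    @classmethod
    def _check_format(cls, v: str) -> str:
        if v not in ("gctx", "tsv"):
            raise ValueError("signatures_format must be 'gctx' or 'tsv'")
        return v


class PipelineParams(BaseModel):
    k: int = Field(default=20, ge=1)  # gene-set size per direction
    rho: float = Field(default=0.01, ge=0.0, lt=1.0)  # camera inter-gene correlation
    similarity_best: str = "positive"
    time_filter: str | None = "96H"
    key_genes: list[str] = Field(default_factory=list)
    top_n: int = Field(default=75, ge=1)
    text_mining_n: int = Field(default=100, ge=1)
    pubmed_terms: list[str] = Field(default_factory=list)
    consensus_filter: bool = False
    consensus_threshold: float = 9.0
    citation_max: int = 0
    umap_min_dist: float = 0.05
    umap_n_neighbors: int = 15
    min_cpm_samples: int = 3

    @field_validator("similarity_best")
    @classmethod
    def _check_polarity(cls, v: str) -> str:
        if v not in ("positive", "negative"):
            raise ValueError("similarity_best must be 'positive' or 'negative'")
        return v


class PipelineConfig(BaseModel):
    inputs: InputPaths
    params: PipelineParams = Field(default_factory=PipelineParams)
    seed: int = 42
    outdir: str = "deathmark_out"

    def resolve(self, base: Path | None = None) -> "PipelineConfig":
        """Resolve relative input paths against *base* (the config file's
        directory)."""
        if base is None:
            return self
        data = self.model_dump()
        for key, value in data["inputs"].items():
            if isinstance(value, str) and key != "signatures_format":
                data["inputs"][key] = str((base / value).resolve()) if not Path(value).is_absolute() else value
        data["inputs"]["dose_response"] = {
            k: (str((base / v).resolve()) if not Path(v).is_absolute() else v)
            for k, v in self.inputs.dose_response.items()
        }
        return PipelineConfig(**data)


def load_config(path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw).resolve(base=path.parent)


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
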
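"""Validated pipeline configuration, loadable from YAML."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class CohortSettings(BaseModel):
    """Synthetic-cohort design (mirrors synthetic_data.CohortConfig)."""

    model_config = ConfigDict(extra="forbid")

    n_train: int = 600
    n_internal: int = 300
    n_validation: int = 300
    n_snps: int = 50
    n_mqtl_cpgs: int = 120
    n_background_cpgs: int = 880
    case_fraction: float = 0.35
    mqtl_effect: float = 0.5
    case_effect: float = 0.1
    n_case_cpgs: int = 30
    noise_sd: float = 0.5
    tissues: list[str] = Field(default_factory=lambda: ["cervical"])


class InputPaths(BaseModel):
    """External inputs used when simulation is disabled."""

    model_config = ConfigDict(extra="forbid")

    beta_tsv: str | None = None
    genotypes: str | None = None
    genotype_format: str = "tsv"        # "tsv" | "vcf"
    phenotypes_csv: str | None = None
    prs_weights_tsv: str | None = None


class PipelineConfig(BaseModel):
    """Everything the end-to-end driver needs; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "widqt_run"
    seed: int = 0
    simulate: bool = True
    cohort: CohortSettings = Field(default_factory=CohortSettings)
    inputs: InputPaths = Field(default_factory=InputPaths)
    k_folds: int = 10
    penalties: list[str] = Field(default_factory=lambda: ["l1", "l2"])
    n_perm: int = 0                     # 0 disables the permutation stage
    n_perm_cpgs: int = 120
    variability_percentiles: list[float] = Field(
        default_factory=lambda: [1, 2, 5, 10, 15, 20])
    ic_bins: list[list[float]] = Field(
        default_factory=lambda: [[0.0, 0.25], [0.25, 0.75], [0.75, 1.0]])

    @model_validator(mode="after")
    def _check(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        bad = set(self.penalties) - {"l1", "l2"}
        if bad:
            raise ValueError(f"unknown penalties: {sorted(bad)}")
        if not self.simulate:
            missing = [k for k in ("beta_tsv", "genotypes", "phenotypes_csv")
                       if getattr(self.inputs, k) is None]
            if missing:
                raise ValueError(
                    f"simulation disabled but inputs missing: {missing}")
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        canon = json.dumps(self.model_dump(exclude={"out_dir"}),
                           sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
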
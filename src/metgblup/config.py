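"""Run configuration: YAML-backed settings with validated defaults.

Defaults mirror the standard protocol: five folds, ten repeats, MCMC
chains of 10 000 iterations with 3 000 burn-in and thinning 10.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .covstruct import KINDS, ResidualStructure
from .exceptions import ConfigError

__all__ = ["RunConfig", "SimSection", "load_config", "dump_config"]


class SimSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_lines: int = Field(300, gt=1)
    n_markers: int = Field(1000, gt=0)
    n_env: int = Field(3, gt=0)
    heritability: list[float] = [0.71, 0.47, 0.24]
    genomic_corr: float | list[list[float]] = 0.65
    residual: dict = {"kind": "IDH"}
    env_means: list[float] | None = None
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    missing_fraction: float = Field(0.0, ge=0.0, lt=1.0)
    family_size: int | None = None
    write_vcf: bool = False

    @field_validator("residual")
    @classmethod
    def _known_kind(cls, v):
        if v.get("kind", "IDH") not in KINDS:
            raise ValueError(f"unknown residual kind {v.get('kind')!r}")
        return v


class RunConfig(BaseModel):
    """Top-level configuration for the simulate / grm / fit / cv commands."""

    model_config = ConfigDict(extra="forbid")

    geno: str | None = None
    pheno: str | None = None
    kinship: str | None = None
    out: str = "."
    models: list[int] = [1]
    structures: list[str] = ["US"]
    method: str = "reml"
    schemes: list[str] = ["M_CV"]
    k: int = Field(5, gt=1)
    repeats: int = Field(10, gt=0)
    mcmc_iters: int = Field(10_000, gt=0)
    mcmc_burnin: int = Field(3_000, ge=0)
    mcmc_thin: int = Field(10, gt=0)
    maf_min: float = Field(0.05, ge=0.0, lt=0.5)
    max_missing: float = Field(0.20, ge=0.0, le=1.0)
    seed: int = 0
    log_level: str = "INFO"
    sim: SimSection = SimSection()

    @field_validator("structures")
    @classmethod
    def _known_structures(cls, v):
        bad = [s for s in v if s not in KINDS]
        if bad:
            raise ValueError(f"unknown residual kind(s) {bad}; choose from {KINDS}")
        return v

    @field_validator("models")
    @classmethod
    def _known_models(cls, v):
        bad = [m for m in v if m not in (1, 2, 3)]
        if bad:
            raise ValueError(f"unknown model(s) {bad}; choose from 1, 2, 3")
        return v

    @field_validator("method")
    @classmethod
    def _known_method(cls, v):
        if v not in ("reml", "mcmc", "both"):
            raise ValueError("method must be reml, mcmc or both")
        return v

    @field_validator("schemes")
    @classmethod
    def _known_schemes(cls, v):
        bad = [s for s in v if s.upper() not in ("M_CV", "S_CV")]
        if bad:
            raise ValueError(f"unknown scheme(s) {bad}; choose M_CV or S_CV")
        return [s.upper() for s in v]

    def require_files(self, *fields: str) -> None:
        for f in fields:
            value = getattr(self, f)
            if value is None:
                raise ConfigError(f"config field {f!r} is required for this command")
            if not Path(value).exists():
                raise ConfigError(f"{f}: file not found: {value}")


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config; an empty file yields all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {_format_validation_error(exc)}") from None


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def sim_config_from_section(sec: SimSection, seed: int):
    """Materialize a SimConfig (and optional family kinship) from a config."""
    from .simulate import SimConfig, family_kinship

    l = sec.n_env
    h2 = np.asarray(sec.heritability, float)
    if h2.size != l:
        raise ConfigError("sim.heritability length must equal sim.n_env")
    if np.isscalar(sec.genomic_corr) or isinstance(sec.genomic_corr, float):
        C = np.full((l, l), float(sec.genomic_corr))
        np.fill_diagonal(C, 1.0)
    else:
        C = np.asarray(sec.genomic_corr, float)
    rvar = (1 - h2) / h2
    rdict = dict(sec.residual)
    kind = rdict.pop("kind", "IDH")
    if rdict:
        rs = ResidualStructure.from_dict({"kind": kind, **rdict}, n_env=l)
    elif kind == "IDV":
        rs = ResidualStructure("IDV", l, np.array([float(rvar.mean())]))
    elif kind == "IDH":
        rs = ResidualStructure("IDH", l, rvar)
    else:
        raise ConfigError("sim.residual needs explicit parameters for US/ANT1")
    means = (
        np.asarray(sec.env_means, float)
        if sec.env_means is not None
        else np.linspace(10.0, 10.0 + 2.0 * (l - 1), l)
    )
    cfg = SimConfig(
        n_lines=sec.n_lines,
        n_markers=sec.n_markers,
        G0=C * np.outer(np.ones(l), np.ones(l)),
        residual_structure=rs,
        env_means=means,
        allele_freq_range=sec.allele_freq_range,
        missing_fraction=sec.missing_fraction,
        seed=seed,
    )
    kin = family_kinship(sec.n_lines, sec.family_size) if sec.family_size else None
    return cfg, kin
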
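"""Layered configuration for the pipeline: file < CLI flag < built-in default.

The config file is YAML with two top-level sections, ``inputs`` and
``params``, plus ``outdir`` and ``seed``.  Unknown keys are rejected before
any stage runs, so typos fail fast instead of silently falling back to
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .classify import ReferenceSet


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration."""


@dataclass
class PipelineConfig:
    # inputs (any may be None; stages without inputs are skipped)
    groups: str | None = None
    tblout: dict[str, str] = field(default_factory=dict)  # subfamily -> path
    refs: str | None = None
    fasta: str | None = None
    gff: str | None = None
    pairs: str | None = None
    cds: str | None = None
    cds_pairs: str | None = None
    fpkm: str | None = None
    # parameters
    completion_threshold: float = 0.5
    partial_keep_below: bool = False
    motifs: dict[str, str] = field(default_factory=dict)  # subfamily -> pattern
    pvalue_thresholds: tuple[float, float] = (1e-4, 1e-3)
    granularity: int = 1000
    min_block_size: int = 5
    max_gap: int = 25
    anchor_score: float = 1.0
    gap_penalty: float = 0.25
    proximal_rank: int = 10
    tandem_rank: int = 1
    control: str = "CK"
    direction: str = "treatment_minus_control"
    # run
    outdir: str = "genefam_out"
    seed: int = 0
    verbosity: str = "INFO"

    def validate(self) -> None:
        if not 0 < self.completion_threshold <= 1:
            raise ConfigError("completion_threshold must be in (0, 1]")
        for t in self.pvalue_thresholds:
            if not 0 < t < 1:
                raise ConfigError("p-value thresholds must be in (0, 1)")
        if self.granularity < 100:
            raise ConfigError("granularity must be >= 100")
        if self.min_block_size < 2:
            raise ConfigError("min_block_size must be >= 2")
        if self.max_gap < 0 or self.proximal_rank < 1 or self.tandem_rank < 1:
            raise ConfigError("gap/rank parameters must be positive")
        if self.direction not in (
            "treatment_minus_control",
            "control_minus_treatment",
        ):
            raise ConfigError(f"unknown direction {self.direction!r}")
        for path_attr in ("groups", "refs", "fasta", "gff", "pairs", "cds",
                          "cds_pairs", "fpkm"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{path_attr} file not found: {p}")
        for sub, p in self.tblout.items():
            if not Path(p).exists():
                raise ConfigError(f"tblout[{sub}] file not found: {p}")


_INPUT_KEYS = {
    "groups", "tblout", "refs", "fasta", "gff", "pairs", "cds", "cds_pairs",
    "fpkm",
}
_PARAM_KEYS = {
    f.name for f in fields(PipelineConfig)
} - _INPUT_KEYS - {"outdir", "seed", "verbosity"}


def config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    """Build a validated config from a nested mapping; unknown keys reject."""
    kwargs: dict[str, Any] = {}
    for section, allowed in (("inputs", _INPUT_KEYS), ("params", _PARAM_KEYS)):
        block = data.get(section, {}) or {}
        if not isinstance(block, Mapping):
            raise ConfigError(f"section {section!r} must be a mapping")
        unknown = set(block) - allowed
        if unknown:
            raise ConfigError(
                f"unknown {section} keys: {sorted(unknown)}; "
                f"allowed: {sorted(allowed)}"
            )
        kwargs.update(block)
    for key in set(data) - {"inputs", "params", "outdir", "seed", "verbosity"}:
        raise ConfigError(f"unknown top-level config key {key!r}")
    for key in ("outdir", "seed", "verbosity"):
        if key in data:
            kwargs[key] = data[key]
    if "pvalue_thresholds" in kwargs:
        kwargs["pvalue_thresholds"] = tuple(kwargs["pvalue_thresholds"])
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigError("config file must contain a YAML mapping")
    return config_from_dict(data)


def load_refs(path) -> ReferenceSet:
    """Reference members per subfamily from YAML.

    Schema: ``members: {SUBFAMILY: [ids...]}`` plus optional
    ``force_include: [gene ids]``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "members" not in data or not isinstance(data["members"], Mapping):
        raise ConfigError("refs file needs a 'members' mapping")
    unknown = set(data) - {"members", "force_include"}
    if unknown:
        raise ConfigError(f"unknown refs keys: {sorted(unknown)}")
    members = {
        str(sub): tuple(str(m) for m in ids)
        for sub, ids in data["members"].items()
    }
    for sub, ids in members.items():
        if not ids:
            raise ConfigError(f"refs for {sub!r} are empty")
    return ReferenceSet(
        members=members,
        force_include=frozenset(str(g) for g in data.get("force_include", [])),
    )
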
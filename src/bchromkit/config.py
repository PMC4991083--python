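"""Pipeline configuration: one schema for every stage, serializable to YAML.

Unknown keys are rejected (fail fast on typos) and a round-trip through
``to_dict``/``from_dict`` is the identity.  Defaults here are the single
source of truth for the CLI; a test asserts they match the module-level
defaults of each stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from . import coverage, dosage, pcr, primers

__all__ = ["PipelineConfig", "CONFIG_VERSION"]

CONFIG_VERSION = 1


@dataclass
class PipelineConfig:
    version: int = CONFIG_VERSION
    seed: int = 0
    verbose: bool = False

    # synthetic world
    scaffold_lengths: list[int] = field(default_factory=lambda: [20_000])
    b_blocks: list[list] = field(default_factory=lambda: [["scaffold_1", 8_000, 11_000, 10]])
    snv_rate_in_blocks: float = 0.01
    read_length: int = 100
    depth_per_haploid_copy: float = 20.0
    read_error_rate: float = 0.0
    ct_baseline: float = 28.0
    ct_noise_sd: float = 0.2
    a_complement_copies: int = 2
    n_contigs: int = 40
    ct_copies_per_b: int = 100

    # coverage scan
    window: int = coverage.DEFAULT_WINDOW
    alpha: float = coverage.DEFAULT_PSEUDOCOUNT
    theta: float = coverage.DEFAULT_THETA
    min_windows: int = coverage.DEFAULT_MIN_WINDOWS
    max_gap: int = coverage.DEFAULT_MAX_GAP
    min_mapq: int = 0

    # marker design
    min_flank: int = 20
    tm_lo: float = primers.DEFAULT_TM_WINDOW[0]
    tm_hi: float = primers.DEFAULT_TM_WINDOW[1]
    gel_gap: int = primers.DEFAULT_GEL_GAP
    tm_span: float = primers.DEFAULT_TM_SPAN
    ortholog_divergence: float = 0.005

    # in-silico PCR
    max_product: int = pcr.DEFAULT_MAX_PRODUCT
    m_internal: int = pcr.DEFAULT_INTERNAL_MISMATCHES

    # dose calling
    sd_flag: float = dosage.DEFAULT_SD_FLAG
    epsilon: float = dosage.DEFAULT_EPSILON
    dose_controls_per_class: int = 3
    dose_unknowns_per_class: int = 10

    def __post_init__(self) -> None:
        if self.version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {self.version}")
        if self.window < 50:
            raise ValueError("window must be >= 50")
        if self.theta <= 1:
            raise ValueError("theta must be > 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not self.tm_lo < self.tm_hi:
            raise ValueError("tm_lo must be below tm_hi")
        if self.epsilon < 0 or self.sd_flag < 0:
            raise ValueError("epsilon and sd_flag must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
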
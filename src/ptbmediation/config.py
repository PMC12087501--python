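"""Run configuration: schema, validation and YAML round-trip.

A run takes its cohort either from an input CSV (``input_path``) or from the
synthetic generator (``generator``), never both. The remaining switches map
onto the analysis' sensitivity variants: the preterm cutoff (37 or 34 weeks),
year as an extra confounder, dropping marital status, three-level smoking,
and complete-case analysis in place of multiple imputation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

CONFIG_VERSION = 1


@dataclass
class RunConfig:
    input_path: str | None = None
    generator: dict | None = None  # {"scenario": str, "n": int} (seed comes from `seed`)
    preterm_cutoff: int = 37
    include_year: bool = False
    include_marital: bool = True
    smoking_levels: int = 2
    complete_case: bool = False
    imputation: dict = field(default_factory=lambda: {"m": 10, "iterations": 10})
    k_expansions: int = 200
    bootstrap: dict = field(default_factory=lambda: {"b_per_imputation": 0})
    subsampling: dict = field(default_factory=lambda: {"n_subsamples": 0, "exponent": 0.7})
    seed: int = 0
    out_dir: str = "results"
    missing_token: str = ""
    version: int = CONFIG_VERSION

    def __post_init__(self):
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")
        if self.preterm_cutoff not in (37, 34):
            raise ValueError("preterm_cutoff must be 37 or 34")
        if self.smoking_levels not in (2, 3):
            raise ValueError("smoking_levels must be 2 or 3")
        if self.version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {self.version}")
        if self.generator is not None:
            unknown = set(self.generator) - {"scenario", "n"}
            if unknown:
                raise ValueError(f"unknown generator keys: {sorted(unknown)}")
        if self.k_expansions < 0:
            raise ValueError("k_expansions must be >= 0 (0 = exact enumeration)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
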
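"""Pipeline configuration with the method's published defaults.

Every run writes its resolved configuration (including the seed) next to
its outputs so any artifact can be regenerated exactly.
"""
from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    seed: int = 0
    # integration
    prior: float = 0.05
    pseudocount: float = 3.0           # n_s
    # analog calling
    analog_cutoff: float = 0.01
    binarize_cutoff: float = 0.5
    # classifiers
    svm_C: float = 100.0
    l1_lambda: float = 1.0
    n_trees: int = 61
    # transfer / evaluation
    transfer_mode: str = "fkt"         # fkt | sequence_only | none
    recall_level: float = 0.10
    kfold: int = 3
    # generator-calibrated acceptance thresholds for planted-truth recovery
    analog_recall_threshold: float = 0.8
    diverged_specificity_threshold: float = 0.9
    log_level: str = "INFO"

    def __post_init__(self):
        if self.transfer_mode not in ("fkt", "sequence_only", "none"):
            raise ConfigurationError(f"bad transfer_mode {self.transfer_mode!r}")
        if self.n_trees % 2 == 0:
            raise ConfigurationError("n_trees must be odd (vote ties)")

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def write_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def write_resolved(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.write_yaml(os.path.join(outdir, "resolved_config.yaml"))
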
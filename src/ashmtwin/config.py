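"""Run configuration: one YAML file driving every pipeline stage.

Every threshold that appears in outputs traces back to this object; the
config round-trips file -> memory -> file identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .inference import InferenceSettings, Priors
from .simulate import SimParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    sim: SimParams = field(default_factory=SimParams)
    fdr_q: float = 0.10
    min_depth: int = 8
    min_alt_reads: int = 1
    min_pdc_pairs: int = 2
    bf_discordant: float = 1.0
    bf_strong: float = 10.0
    bin_width: int = 500
    bin_step: int = 250
    r_threshold: float = 0.5
    p_threshold: float = 0.05
    priors: Priors = field(default_factory=Priors)
    inference: InferenceSettings = field(default_factory=InferenceSettings)
    seed: int = 0
    out_dir: str = "ashm_out"
    counts_tsv: str | None = None  # set -> ingest real data instead of simulating
    genotype_vcf: str | None = None
    cohort_tsv: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimParams(**d["sim"])
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = Priors(**d["priors"])
        if "inference" in d and isinstance(d["inference"], dict):
            d["inference"] = InferenceSettings(**d["inference"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
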
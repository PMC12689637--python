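"""Pipeline configuration: every numeric threshold in one place.

The defaults are the analysis constants the pipeline is built around: wTO
hard cutoff 0.5, differential-link presence cutoff 0.33, RWR restart 0.7,
top-decile assignment percentile, 20-link minimum cluster size, CPM filter
(>= 1 cpm in >= 70% of samples), DEG thresholds FDR < 0.05 and
|log2FC| > 0.3, and 10,000 permutations. Configs round-trip losslessly
through YAML and carry a content hash stamped on every output file.
"""
from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .synthdata import SynthConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    wto_cutoff: float = 0.5
    diff_cutoff: float = 0.33
    rwr_restart: float = 0.7
    rwr_tol: float = 1e-10
    assign_percentile: float = 90.0
    min_cluster_links: int = 20
    louvain_resolution: float = 1.0
    cpm_min: float = 1.0
    cpm_frac: float = 0.7
    de_fdr: float = 0.05
    de_lfc: float = 0.3
    enrich_alpha: float = 0.05
    min_term_size: int = 5
    n_perm: int = 10_000
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)

    def validate(self) -> None:
        for name, lo, hi in [("wto_cutoff", 0, 1), ("diff_cutoff", 0, 1),
                             ("rwr_restart", 0, 1), ("cpm_frac", 0, 1),
                             ("de_fdr", 0, 1), ("enrich_alpha", 0, 1),
                             ("assign_percentile", 0, 100)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.n_perm < 1 or self.min_cluster_links < 0:
            raise ValueError("n_perm >= 1 and min_cluster_links >= 0 required")
        self.synth.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        synth = d.pop("synth", {})
        if isinstance(synth, dict):
            synth = SynthConfig(**synth)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(synth=synth, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        payload = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
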
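"""Structured run configuration with full defaulting.

Every numeric pipeline threshold appears here exactly once; stage modules
import their defaults from their own namespaces, and RunConfig mirrors them
so a config file can override any of them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .calling import DEFAULT_EXPECTED_CELLS
from .embed import DEFAULT_K_NEIGHBORS, DEFAULT_N_COMPONENTS, NORMALIZE_SCALE
from .qc import MAD_K, MIN_CELL_FRACTION, MITO_CAP_PCT, RIBO_CAP_PCT
from .stats import EXACT_CAP_MW
from .types import FEMALE, MALE


@dataclass
class SampleSpec:
    sample_id: str
    recipient_sex: str
    donor_sex: str
    months_post_transplant: float = 0.0
    counts_dir: str | None = None  # read an existing triplet directory ...
    sim: dict = field(default_factory=dict)  # ... or simulate with these overrides
    use_reads: bool = False  # simulate at read level and demultiplex

    def validate(self) -> None:
        for sex in (self.recipient_sex, self.donor_sex):
            if sex not in (FEMALE, MALE):
                raise ValueError(f"sample {self.sample_id}: invalid sex {sex!r}")
        if self.counts_dir is None and self.sim is None:
            raise ValueError(f"sample {self.sample_id}: needs counts_dir or sim block")


@dataclass
class RunConfig:
    samples: list[SampleSpec] = field(default_factory=list)
    seed: int = 0
    expected_cells: int = DEFAULT_EXPECTED_CELLS
    mad_k: float = MAD_K
    one_sided_mad: bool = False
    mito_cap: float = MITO_CAP_PCT
    ribo_cap: float = RIBO_CAP_PCT
    min_cell_fraction: float = MIN_CELL_FRACTION
    normalize_scale: float = NORMALIZE_SCALE
    exact_cap: int = EXACT_CAP_MW
    cluster_enabled: bool = False
    n_components: int = DEFAULT_N_COMPONENTS
    k_neighbors: int = DEFAULT_K_NEIGHBORS
    gate_mode: str = "off"
    call_cells_enabled: bool = True

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("config needs at least one sample")
        for s in self.samples:
            s.validate()
        if self.expected_cells < 1:
            raise ValueError("expected_cells must be >= 1")
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")
        if not 0 <= self.mito_cap <= 100 or not 0 <= self.ribo_cap <= 100:
            raise ValueError("mito/ribo caps must be percentages in [0, 100]")
        if not 0 <= self.min_cell_fraction <= 1:
            raise ValueError("min_cell_fraction must be in [0, 1]")
        if self.normalize_scale <= 0:
            raise ValueError("normalize_scale must be positive")
        if self.gate_mode not in ("off", "any_positive", "all_positive"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        samples = [SampleSpec(**s) for s in data.pop("samples", [])]
        cfg = cls(samples=samples, **data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
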
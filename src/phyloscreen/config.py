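"""Run configuration (YAML) for the pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml


@dataclass
class Thresholds:
    inclusion_E: float = 1e-5
    domain_E: float = 1e-3
    family_E: Dict[str, float] = field(default_factory=dict)
    min_cov: int = 10
    min_alt_reads: int = 2
    solid_min: int = 4
    min_orf_len: int = 25
    het_frac_threshold: float = 1e-3
    balance_low: float = 0.4
    balance_high: float = 0.5
    balance_floor: float = 0.2
    min_ploidy_sites: int = 1000
    gap_open: float = 4.0
    gap_extend: float = 0.5
    alpha: float = 1.0
    max_iter: int = 10
    n_decoys: int = 200
    decoy_len: int = 100

    def __post_init__(self):
        for name in ("inclusion_E", "domain_E", "gap_open", "gap_extend"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimulateConfig:
    n_taxa: int = 8
    n_families: int = 20
    root_len: int = 120
    sub_rate: float = 0.4
    loss_rate: float = 0.15
    long_clade_fraction: float = 0.25
    long_multiplier: float = 2.0
    intergenic_len: int = 150
    hide_fraction: float = 0.1
    n_seed_rows: int = 4
    pileup_ploidy: int = 1
    pileup_sites: int = 20000
    pileup_cov: float = 30.0
    pileup_error: float = 0.005
    pileup_het_density: float = 0.01
    kmer_k: int = 17
    kmer_read_cov: float = 30.0
    kmer_dropout: float = 0.0


@dataclass
class RunConfig:
    outdir: str
    seed: int
    tree: Optional[str] = None
    alignments: Optional[str] = None  # directory of <family>.fasta seed MSAs
    domains: Optional[str] = None  # directory of <family>.dom*.fasta
    proteomes: Optional[str] = None  # directory of <taxon>.fasta
    genomes: Optional[str] = None  # directory of <taxon>.fasta
    complexes: Optional[str] = None  # TSV: complex, member
    pileup: Optional[str] = None  # TSV: site, A, C, G, T
    kmer_assembly: Optional[str] = None  # TSV: kmer, count
    kmer_reads: Optional[str] = None  # TSV: kmer, count
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: Optional[SimulateConfig] = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        thr = Thresholds(**raw.pop("thresholds", {}))
        sim = raw.pop("simulate", None)
        sim_cfg = SimulateConfig(**sim) if sim is not None else None
        return cls(thresholds=thr, simulate=sim_cfg, **raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
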
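"""Run configuration: every stage parameter with its published default,
round-trippable through YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .library import BUILTIN_PRIMERS, PrimerPair


@dataclass
class RunConfig:
    """All pipeline parameters.  Defaults are the protocol's published
    values: Q17 end-trimming, >= 35 nt overlap at >= 80% match for joining,
    10-read minimum cluster size, 20 clusters per sample, 95% identity floor
    for library matching, 1,000 bootstrap replicates."""

    library_fasta: str = ""
    barcodes_tsv: str = ""
    fastq1: str = ""
    fastq2: str = ""
    out_dir: str = "slatyper_out"
    primers: str = "short"          # builtin name, or a YAML file path
    q_min: int = 17
    min_overlap: int = 35
    min_match: float = 0.80
    min_reads: int = 10
    max_clusters: int = 20
    min_identity: float = 0.95
    length_tol: int = 15
    expected_insert_len: int | None = None   # derived from primers if unset
    dominant_fraction: float = 0.05
    nj_bootstrap: int = 1000
    max_dup_per_locus: int = 2
    population: str = "population"
    seed: int = 42

    def __post_init__(self):
        if not 0 <= self.min_match <= 1:
            raise ValueError("min_match must be in [0, 1]")
        if not 0 <= self.min_identity <= 1:
            raise ValueError("min_identity must be in [0, 1]")
        for name in ("q_min", "min_overlap", "min_reads", "max_clusters",
                     "length_tol", "nj_bootstrap", "max_dup_per_locus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def primer_pair(self) -> PrimerPair:
        if self.primers in BUILTIN_PRIMERS:
            return BUILTIN_PRIMERS[self.primers]
        with open(self.primers) as fh:
            d = yaml.safe_load(fh)
        return PrimerPair(d["name"], d["forward"], d["reverse"],
                          d.get("expected_product_nt"))

    def insert_len(self) -> int:
        if self.expected_insert_len is not None:
            return self.expected_insert_len
        pp = self.primer_pair()
        if pp.expected_product_nt is None:
            raise ValueError("expected_insert_len unset and primer pair has "
                             "no expected product size")
        return pp.expected_product_nt - len(pp.forward) - len(pp.reverse)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
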
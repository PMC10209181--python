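"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives here, under a
single dataclass, so that a run is fully described by one config object.
Defaults follow the 10x Chromium 3' v2 chemistry (16 nt cell barcode,
10 nt UMI) and the thresholds customary for long-read isoform annotation:
barcode matching tolerates up to 3 mismatches, novel-exon candidates need
inserts of >= 21 nt at exon junctions and confirmation by >= 2 reads,
novel transcripts need >= 5 reads spread over >= 3 samples, alignments
must reach 90% identity and 80% query coverage, and sub-5-bp microindels
at splice junctions are treated as alignment noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass(frozen=True)
class PipelineConfig:
    # --- read layout (10x 3' v2) ---
    barcode_length: int = 16
    umi_length: int = 10
    # --- demultiplexing ---
    max_hamming: int = 3
    min_tail_len: int = 20
    tail_max_mismatch_frac: float = 0.1
    # --- novel-exon discovery ---
    min_insert_len: int = 21
    min_exon_support: int = 2
    # --- novel-transcript filtering ---
    min_transcript_reads: int = 5
    min_transcript_samples: int = 3
    # --- alignment acceptance ---
    min_identity: float = 0.90
    min_coverage: float = 0.80
    # --- artifact handling ---
    twindow: int = 20
    microindel_max: int = 5
    # --- immunoglobulin segment detection ---
    min_v_len: int = 9
    min_j_len: int = 0
    ig_seed_k: int = 11
    ig_min_identity: float = 0.8
    # --- short-read QC provenance (recorded, not applied here) ---
    qc_min_genes: int = 1000
    qc_max_mito_pct: float = 5.0

    def __post_init__(self) -> None:
        positive = [
            "barcode_length", "umi_length", "max_hamming", "min_tail_len",
            "min_insert_len", "min_exon_support", "min_transcript_reads",
            "min_transcript_samples", "twindow", "microindel_max",
            "min_v_len", "ig_seed_k", "qc_min_genes",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive, got {getattr(self, name)}")
        if self.min_j_len < 0:
            raise ConfigError(f"min_j_len must be >= 0, got {self.min_j_len}")
        for name in ("min_identity", "min_coverage", "tail_max_mismatch_frac", "ig_min_identity"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0) and name != "tail_max_mismatch_frac":
                raise ConfigError(f"{name} must be in (0, 1], got {v}")
        if not (0.0 <= self.tail_max_mismatch_frac < 1.0):
            raise ConfigError(
                f"tail_max_mismatch_frac must be in [0, 1), got {self.tail_max_mismatch_frac}"
            )
        if self.qc_max_mito_pct < 0:
            raise ConfigError(f"qc_max_mito_pct must be >= 0, got {self.qc_max_mito_pct}")

    @property
    def prefix_length(self) -> int:
        """Bases occupied by barcode + UMI at the 5' end of a sense read."""
        return self.barcode_length + self.umi_length

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = PipelineConfig()
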
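"""Pipeline configuration: the thresholds of the discovery protocol.

Defaults collect the published screening protocol: BLAST-style E-value
cutoffs of 1e-3 (viral screen) and 1e-4 (inter-genome homology), ORFs of at
least 50 aa, end-trimming at Phred quality 30, a 200-bp contig length floor,
the <80% alignment-coverage rule for partial ORF calls, and 100-nt single-end
reads for the coverage arithmetic.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    min_contig_len: int = 200
    screen_evalue: float = 1e-3
    homolog_evalue: float = 1e-4
    min_orf_aa: int = 50
    partial_coverage_threshold: float = 0.8
    max_overlap_nt: int = 60
    read_length: int = 100
    qmin: int = 30
    max_mismatch: int = 2
    merge_min_len: int = 40
    merge_min_identity: float = 0.95
    bootstrap_reps: int = 100
    orf_prefix: str = "NV"
    seed: int = 0

    # input/output paths (None where a stage is skipped)
    contigs: str | None = None
    reads: str | None = None
    db_fasta: str | None = None
    db_meta: str | None = None
    outdir: str = "nudimine_out"

    def __post_init__(self) -> None:
        for name in (
            "min_contig_len",
            "screen_evalue",
            "homolog_evalue",
            "min_orf_aa",
            "read_length",
            "partial_coverage_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.partial_coverage_threshold <= 1:
            raise ValueError("partial_coverage_threshold must be in (0, 1]")
        if self.qmin < 0:
            raise ValueError("qmin must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def outpath(self, name: str) -> Path:
        out = Path(self.outdir)
        out.mkdir(parents=True, exist_ok=True)
        return out / name
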
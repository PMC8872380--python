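"""Pipeline thresholds, collected in one structured, serialisable object.

Defaults are the workflow's standard operating points: 75%/90% for the
library purge, 30 copies with 4000 bp flanks for curation, a
5000-locus × 500 bp × 1000 bp-flank × 250 bp-overlap calibration
design, 100 kb at ≥ 95% identity for the recent-expansion gate, an 80%
presence floor for the panel screen, and 70% identity / 50% coverage
for donor-consensus curation. Every value can be overridden from YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    # purge
    purge_coverage: float = 0.75
    purge_identity: float = 90.0
    # curation
    curation_copies: int = 30
    curation_flank: int = 4000
    flank_min_support: int = 2
    max_tsd: int = 20
    msa_method: str = "localpair"
    # annotation
    annotate_min_identity: float = 60.0
    annotate_min_len: int = 80
    overlap_tolerance: int = 10
    # calibration
    calib_sample_n: int = 5000
    calib_min_te_len: int = 500
    calib_flank: int = 1000
    calib_min_te_bp: int = 250
    calib_min_flank_bp: int = 250
    calib_min_pairs: int = 50
    ancestral_detect_override: float | None = 80.0
    # recent-expansion gate (the literal 95% operating point; the
    # calibrated recent_threshold is derived independently and reported)
    recent_identity: float = 95.0
    recent_min_mass: int = 100_000
    cluster_identity: float = 95.0
    expression_min_frac: float = 0.95
    # panel screen
    presence_threshold: float = 80.0
    presence_min_len: int = 100
    # donor curation / trees
    donor_identity: float = 70.0
    donor_coverage: float = 0.5
    donor_flank: int = 1000
    bimodal_gap: float = 8.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
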
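"""Pipeline configuration.

All similarity thresholds are stored as fractions in [0, 1]; percentage
inputs (as printed in methods sections) are converted once at load time.
Analysis stages are deterministic — ``rng_seed`` is consumed only by the
synthetic-community generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

#: Evidence streams accepted in annotation-hit tables (dbCAN-style provenance).
EVIDENCE_SOURCES = ("HMMER", "eCAMI", "DIAMOND")

#: Gut sections recognised in sample metadata.
SECTIONS = ("III", "IV", "V")


@dataclass
class PipelineConfig:
    """Tunable thresholds and switches shared by every pipeline stage.

    Defaults mirror the annotation acceptance rules used for marine
    herbivore hindgut MAG profiling: EC-linked CAZyme hits require target
    coverage >= 40% and identity >= 30%; sulfatase hits require coverage
    >= 50%, identity >= 30% and the formylglycine-sulfatase Pfam domain
    PF00884.
    """

    ec_min_coverage: float = 0.40
    ec_min_identity: float = 0.30
    sulf_min_coverage: float = 0.50
    sulf_min_identity: float = 0.30
    required_sulf_domain: str = "PF00884"
    evalue_cutoff: float = 1e-3
    min_completeness: float = 50.0   # percent, MIMAG medium quality
    max_contamination: float = 10.0  # percent, strict upper bound
    cgc_max_gap: int = 2
    cgc_min_degradative: int = 2
    density_unit: str = "per_1000_genes"  # or "per_mbp"
    corr_alpha: float = 0.05
    corr_min_r: float = 0.3
    group_cut_height: float = 0.7
    fc_pseudocount: float = 0.01  # percentage points
    expression_quantile: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ec_min_coverage", "ec_min_identity",
                     "sulf_min_coverage", "sulf_min_identity",
                     "corr_alpha", "corr_min_r", "expression_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.cgc_min_degradative < 1:
            raise ValueError("cgc_min_degradative must be >= 1")
        if self.cgc_max_gap < 0:
            raise ValueError("cgc_max_gap must be >= 0")
        if self.density_unit not in ("per_1000_genes", "per_mbp"):
            raise ValueError(f"unknown density_unit {self.density_unit!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def as_dict(self) -> dict:
        return asdict(self)
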
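"""Pipeline configuration: every threshold used anywhere in the pipeline.

The defaults are the operating point of the whole resource-building
procedure: homology models are accepted at >=90% template-detection
confidence and >20% template sequence identity, with no unmodeled run
longer than 30 residues, no consecutive-residue C-alpha distance above
3.8*g + 1.2 angstrom (g = residue-number gap), a normalized radius of
gyration below 0.8 and a gyration-tensor anisotropy below 4.0; only
sequences of at most 500 residues are modeled at all; experimental
structures must cover at least 80% of the canonical sequence; docking
keeps alignments with TM-score > 0.4 and releases models with combined
score > 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .errors import ConfigError


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds, with the pipeline's canonical defaults.

    Units: percentages for ``confidence_min``/``identity_min``, residues
    for ``max_missing_run``/``length_max``, angstrom for the geometric
    cutoffs, dimensionless otherwise.
    """

    confidence_min: float = 90.0      # % HHSearch-style probability, inclusive
    identity_min: float = 20.0        # % template identity, strict >
    max_missing_run: int = 30         # residues; runs of 31+ fail
    gap_slope: float = 3.8            # A per residue of numbering gap
    gap_intercept: float = 1.2        # A
    rg_ratio_max: float = 0.8         # Rg / Rmax, dimensionless
    anisotropy_max: float = 4.0       # lambda_max / lambda_min
    length_max: int = 500             # residues eligible for modeling
    coverage_min: float = 0.80        # fraction of canonical sequence
    tm_gate: float = 0.4              # per-chain TM-score gate, strict >
    score_gate: float = 0.5           # combined-score release gate, strict >
    contact_cutoff: float = 5.0       # A, interface residue definition
    clash_cutoff: float = 2.5         # A, cross-chain clash diagnostic
    probe: float = 1.4                # A, solvent probe radius
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        """Check invariants; return self so calls can be chained."""
        for f in dataclasses.fields(self):
            if f.name == "seed":
                continue
            v = getattr(self, f.name)
            if not (v > 0):
                raise ConfigError(f"config field {f.name!r} must be positive, got {v!r}")
        if not 0 < self.coverage_min <= 1:
            raise ConfigError(f"coverage_min must be in (0, 1], got {self.coverage_min}")
        return self

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_CONFIG = PipelineConfig()
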
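"""Homology-model quality control and candidate-selection logic.

A modeled chain is accepted only when the template search was confident
(confidence >= 90%), the template is a genuine homolog (identity strictly
> 20%), the model covers the sequence without any unmodeled run longer
than 30 residues (internal or terminal), consecutive modeled residues are
not torn apart (C-alpha distance <= 3.8*g + 1.2 A for a numbering gap g),
and the molecular envelope is compact (rg_ratio < 0.8, gyration-tensor
anisotropy < 4.0).  Only sequences of at most 500 residues are modeled.

Selection logic covers both routes into the resource: choosing a
representative experimental structure (coverage >= 80%, then a strict
lexicographic preference order) and choosing a modeling hit from a ranked
candidate table (top passing hit, with a human-template override).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import ContractError
from .geometry import shape_stats
from .structio import Chain

# template methods that qualify for the human-template override:
# single-crystal diffraction or single-particle cryo-EM
OVERRIDE_METHODS = {"xray", "electron-diffraction", "neutron", "cryoem"}

# preference order of experimental methods for representative selection
_METHOD_PRIORITY = {"xray": 0, "cryoem": 1, "nmr": 2}


@dataclass
class ModelMetadata:
    """Metadata of one ranked modeling hit (template-search output)."""
    confidence: float            # % probability from the template search
    template_identity: float     # % sequence identity to the template
    template_id: str = ""        # PDB id + chain
    template_species_human: bool = False
    template_method: str = "other"   # xray|electron-diffraction|neutron|cryoem|nmr|other
    rank: int = 1                # 1 = best E-value
    target_length: int = 0       # residues in the modeled sequence


@dataclass
class CheckResult:
    name: str
    passed: bool
    value: object = None
    threshold: object = None


@dataclass
class QCReport:
    checks: dict[str, CheckResult] = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def failed(self) -> list[str]:
        return [k for k, c in self.checks.items() if not c.passed]

    def to_dict(self) -> dict:
        return {
            "overall_pass": self.overall_pass,
            "checks": {k: {"passed": c.passed, "value": c.value,
                           "threshold": c.threshold}
                       for k, c in self.checks.items()},
        }


def check_length_eligible(target_length: int, length_max: int = 500) -> bool:
    """Only sequences of at most ``length_max`` residues are modeled."""
    if target_length < 1:
        raise ValueError("target length must be >= 1")
    return target_length <= length_max


def missing_segments(chain: Chain, canonical_length: int) -> list[tuple[int, int]]:
    """Maximal runs of canonical positions absent from the (renumbered)
    chain, including N- and C-terminal runs, as inclusive (start, end)."""
    numbers = chain.residue_numbers()
    if numbers and max(numbers) > canonical_length:
        raise ContractError(
            f"chain residue number {max(numbers)} exceeds canonical length "
            f"{canonical_length}; renumber first")
    present = set(numbers)
    runs: list[tuple[int, int]] = []
    start = None
    for pos in range(1, canonical_length + 1):
        if pos not in present:
            if start is None:
                start = pos
        elif start is not None:
            runs.append((start, pos - 1))
            start = None
    if start is not None:
        runs.append((start, canonical_length))
    return runs


def ca_gap_violations(chain: Chain, gap_slope: float = 3.8,
                      gap_intercept: float = 1.2
                      ) -> list[tuple[int, int, float, float]]:
    """Consecutive modeled residue pairs whose C-alpha distance exceeds
    ``gap_slope * g + gap_intercept`` where g is the residue-number gap
    (g = 1 for adjacent residues).  Returns (num_i, num_j, distance,
    threshold) tuples."""
    cas = [(r.number, r.ca.coord) for r in chain.residues if r.has_ca]
    if len(cas) < 2:
        return []
    out = []
    for (ni, ci), (nj, cj) in zip(cas, cas[1:]):
        g = nj - ni
        thr = gap_slope * g + gap_intercept
        d = float(np.linalg.norm(cj - ci))
        if d > thr:
            out.append((ni, nj, d, thr))
    return out


def qc_model(chain: Chain, meta: ModelMetadata, canonical_length: int,
             config: PipelineConfig = DEFAULT_CONFIG) -> QCReport:
    """Full acceptance report for one homology model (renumbered chain)."""
    rep = QCReport()
    rep.checks["confidence"] = CheckResult(
        "confidence", meta.confidence >= config.confidence_min,
        meta.confidence, config.confidence_min)
    rep.checks["identity"] = CheckResult(
        "identity", meta.template_identity > config.identity_min,
        meta.template_identity, config.identity_min)
    length = meta.target_length or canonical_length
    rep.checks["length_eligible"] = CheckResult(
        "length_eligible", check_length_eligible(length, config.length_max),
        length, config.length_max)
    runs = missing_segments(chain, canonical_length)
    longest = max((e - s + 1 for s, e in runs), default=0)
    rep.checks["missing_segment"] = CheckResult(
        "missing_segment", longest <= config.max_missing_run,
        longest, config.max_missing_run)
    viols = ca_gap_violations(chain, config.gap_slope, config.gap_intercept)
    rep.checks["ca_gap"] = CheckResult("ca_gap", len(viols) == 0, len(viols), 0)
    stats = shape_stats(chain.ca_coords())
    rep.checks["rg_ratio"] = CheckResult(
        "rg_ratio", stats.rg_ratio < config.rg_ratio_max,
        stats.rg_ratio, config.rg_ratio_max)
    rep.checks["anisotropy"] = CheckResult(
        "anisotropy", stats.anisotropy < config.anisotropy_max,
        stats.anisotropy, config.anisotropy_max)
    return rep


def select_hit(hits: Sequence[ModelMetadata], qc: Sequence[QCReport],
               max_considered: int = 20) -> Optional[ModelMetadata]:
    """Choose a modeling hit from a ranked candidate table.

    Default: the best-ranked (lowest E-value) hit passing QC.  Override: a
    passing hit whose template comes from a human protein is preferred,
    provided its coordinates were obtained by a single-crystal diffraction
    method (X-ray, electron or neutron) or single-particle cryo-EM.
    """
    if len(hits) != len(qc):
        raise ContractError("hits and QC reports must align")
    ranked = sorted(zip(hits, qc), key=lambda hq: hq[0].rank)[:max_considered]
    passing = [h for h, q in ranked if q.overall_pass]
    if not passing:
        return None
    for h in passing:
        if h.template_species_human and h.template_method in OVERRIDE_METHODS:
            return h
    return passing[0]


@dataclass
class RepresentativeEntry:
    """One candidate experimental structure for a protein."""
    entry_id: str
    coverage: float              # fraction of canonical sequence covered
    missing_count: int           # missing atoms/residues
    method: str                  # xray | cryoem | nmr
    resolution: Optional[float]  # A; absent for NMR
    deposition_date: Optional[date]


def _representative_key(e: RepresentativeEntry):
    res = e.resolution if e.resolution is not None else float("inf")
    day = e.deposition_date.toordinal() if e.deposition_date else -1
    return (-e.coverage, e.missing_count,
            _METHOD_PRIORITY.get(e.method, 3), res, -day, e.entry_id)


def select_representative(entries: Sequence[RepresentativeEntry],
                          coverage_min: float = 0.80
                          ) -> Optional[RepresentativeEntry]:
    """Pick the representative experimental structure.

    Only entries covering at least ``coverage_min`` of the canonical
    sequence qualify; among those the order of preference is largest
    coverage, fewest missing atoms/residues, method (X-ray, then cryo-EM,
    then NMR), best (smallest) resolution, latest deposition date — applied
    as a strict lexicographic sort.  Returns None when nothing qualifies
    (the protein is then routed to homology modeling).
    """
    eligible = [e for e in entries if e.coverage >= coverage_min]
    if not eligible:
        return None
    return min(eligible, key=_representative_key)
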
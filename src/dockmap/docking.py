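"""Template-based docking of two monomers by full-structure alignment.

Each target monomer is structurally aligned to one chain of a template
binary complex; when both alignments clear the TM-score gate (> 0.4) the
two rigid transforms place the targets in the template frame, producing a
docking model without any refinement.  Models are then scored and only
those with combined score > 0.5 are released; the default combined score
is the conservative surrogate min(TM_a, TM_b), and the scoring function
is pluggable so a trained one can be swapped in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

from .errors import ContractError, DegenerateInputError
from .geometry import AlignmentResult, InterfaceReport, interface_report, structural_align
from .structio import Chain, StructureModel, parse_pdb

log = logging.getLogger(__name__)

TM_GATE = 0.4
SCORE_GATE = 0.5

ScoreFn = Callable[[float, float, Optional[InterfaceReport]], float]


@dataclass
class TemplateEntry:
    """One binary complex from the template library."""
    id: str
    chain1: Chain
    chain2: Chain
    source: str = ""


@dataclass
class DockModel:
    chain_a: Chain                  # positioned in the template frame
    chain_b: Chain
    template_id: str
    tm_a: float                     # target/template TM-score, chain a
    tm_b: float
    combined_score: float
    provenance_class: str = ""      # experimental | PDB+PDB | PDB+model | model+model
    interface: Optional[InterfaceReport] = None
    alignment_a: Optional[AlignmentResult] = None
    alignment_b: Optional[AlignmentResult] = None

    def sidecar(self) -> dict:
        """JSON-serializable score/provenance summary."""
        return {
            "template_id": self.template_id,
            "tm_a": self.tm_a,
            "tm_b": self.tm_b,
            "combined_score": self.combined_score,
            "provenance_class": self.provenance_class,
            "interface_area": self.interface.interface_area if self.interface else None,
            "clash_count": self.interface.clash_count if self.interface else None,
        }


def combined_score(tm_a: float, tm_b: float,
                   interface: Optional[InterfaceReport] = None) -> float:
    """Surrogate combined docking score: min(TM_a, TM_b).

    Monotone non-decreasing in both TM arguments and bounded by [0, 1],
    so the release gate (> 0.5) keeps its meaning; any trained scoring
    function with the same signature can replace it via the ``scorer``
    arguments of :func:`dock_on_template` / :func:`dock_all`.
    """
    if not (0 <= tm_a <= 1 and 0 <= tm_b <= 1):
        raise ValueError("TM-scores must lie in [0, 1]")
    return min(tm_a, tm_b)


def classify_provenance(p1: StructureModel, p2: StructureModel) -> str:
    """Provenance class of a docked pair."""
    kinds = []
    for p in (p1, p2):
        if p.provenance == "experimental":
            kinds.append("pdb")
        elif p.provenance == "homology-model":
            kinds.append("model")
        else:
            raise ValueError(f"unknown provenance {p.provenance!r}")
    n_pdb = kinds.count("pdb")
    return {2: "PDB+PDB", 1: "PDB+model", 0: "model+model"}[n_pdb]


def _try_assignment(t1: Chain, t2: Chain, template: TemplateEntry
                    ) -> Optional[tuple[AlignmentResult, AlignmentResult]]:
    try:
        a1 = structural_align(t1, template.chain1)
        a2 = structural_align(t2, template.chain2)
    except DegenerateInputError as e:
        log.info("alignment failed on template %s: %s", template.id, e)
        return None
    return a1, a2


def dock_on_template(target1: Chain, target2: Chain, template: TemplateEntry,
                     tm_gate: float = TM_GATE,
                     scorer: ScoreFn = combined_score,
                     contact_cutoff: float = 5.0,
                     clash_cutoff: float = 2.5,
                     probe: float = 1.4) -> Optional[DockModel]:
    """Dock two targets on one template complex, or None if gated out.

    Both chain assignments (target1 on template chain 1 or chain 2) are
    tried and the one with the larger min TM-score kept.  If either chain's
    TM-score is <= ``tm_gate`` no model is built.  The retained coordinates
    are exact rigid transforms of the inputs — no refinement is applied.
    """
    candidates = []
    direct = _try_assignment(target1, target2, template)
    if direct:
        candidates.append((direct[0], direct[1], False))
    swapped = _try_assignment(target2, target1, template)
    if swapped:
        candidates.append((swapped[1], swapped[0], True))
    if not candidates:
        return None
    a1, a2, _ = max(candidates,
                    key=lambda c: (min(c[0].tm_score, c[1].tm_score),
                                   c[0].tm_score + c[1].tm_score))
    if min(a1.tm_score, a2.tm_score) <= tm_gate:
        log.info("template %s gated out: TM %.3f / %.3f",
                 template.id, a1.tm_score, a2.tm_score)
        return None
    placed1 = target1.transformed(a1.transform.rotation, a1.transform.translation)
    placed2 = target2.transformed(a2.transform.rotation, a2.transform.translation)
    iface = interface_report(placed1, placed2, contact_cutoff,
                             clash_cutoff, probe)
    score = scorer(a1.tm_score, a2.tm_score, iface)
    return DockModel(chain_a=placed1, chain_b=placed2, template_id=template.id,
                     tm_a=a1.tm_score, tm_b=a2.tm_score, combined_score=score,
                     interface=iface, alignment_a=a1, alignment_b=a2)


def dock_all(target1: Chain, target2: Chain,
             library: Sequence[TemplateEntry],
             tm_gate: float = TM_GATE, score_gate: float = SCORE_GATE,
             scorer: ScoreFn = combined_score,
             contact_cutoff: float = 5.0, clash_cutoff: float = 2.5,
             probe: float = 1.4) -> list[DockModel]:
    """Dock the target pair against every library template.

    Models passing the TM gate are scored; only combined score >
    ``score_gate`` is released.  Output is sorted by descending combined
    score with ties broken by template id, so the ranking is deterministic
    and independent of library order.
    """
    models = []
    for entry in library:
        m = dock_on_template(target1, target2, entry, tm_gate, scorer,
                             contact_cutoff, clash_cutoff, probe)
        if m is None:
            continue
        if m.combined_score > score_gate:
            models.append(m)
        else:
            log.info("template %s below release gate: score %.3f",
                     entry.id, m.combined_score)
    models.sort(key=lambda m: (-m.combined_score, m.template_id))
    return models


# ---------------------------------------------------------------------------
# Template library on disk: directory of two-chain PDB files + index TSV
# ---------------------------------------------------------------------------

def load_template_library(index_tsv: Path | str) -> list[TemplateEntry]:
    """Load a template library described by an index TSV with columns
    ``id``, ``file``, ``source``, ``chain1``, ``chain2``; ``file`` paths
    are relative to the index location."""
    index_tsv = Path(index_tsv)
    df = pd.read_csv(index_tsv, sep="\t", dtype=str)
    required = {"id", "file", "chain1", "chain2"}
    if not required.issubset(df.columns):
        raise ContractError(f"template index missing columns {required - set(df.columns)}")
    entries = []
    for row in df.itertuples(index=False):
        model = parse_pdb((index_tsv.parent / row.file).read_text())
        entries.append(TemplateEntry(
            id=row.id, chain1=model.chain(row.chain1),
            chain2=model.chain(row.chain2),
            source=getattr(row, "source", "") or ""))
    return entries


def write_dock_model(model: DockModel, pdb_path: Path, sidecar_path: Path,
                     method: str = "model") -> None:
    from .structio import StructureModel as SM, write_pdb
    pdb_path.write_text(write_pdb(SM(chains=[model.chain_a, model.chain_b],
                                     provenance="homology-model", method=method)))
    sidecar_path.write_text(json.dumps(model.sidecar(), indent=2, sort_keys=True) + "\n")
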
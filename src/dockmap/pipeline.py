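"""End-to-end orchestration: QC -> docking -> renumbering/labeling ->
variant mapping, with a run manifest for provenance.

``run_pipeline`` is the library entry point behind the command-line
``run`` subcommand: it takes two monomer coordinate files, their canonical
sequences, a variant table and a template library, and emits renumbered
A/B-labeled complex PDB files with score sidecars, mapped-variant tables,
and a JSON manifest recording configuration, input digests and per-stage
counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .config import DEFAULT_CONFIG, PipelineConfig
from .docking import DockModel, classify_provenance, dock_all, load_template_library, write_dock_model
from .errors import DockmapError
from .model_qc import ModelMetadata, QCReport, qc_model
from .structio import (StructureModel, atom_sequence, build_residue_map, parse_pdb,
                       read_fasta, relabel_complex, renumber_chain)
from .variants import map_variants, parse_variants, write_mapped_variants

log = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_NO_MODELS = 3


@dataclass
class RunManifest:
    """Provenance record of one pipeline run.

    Stage counts are non-increasing along QC -> TM gate -> release.
    """
    input_digests: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    qc: dict[str, dict] = field(default_factory=dict)
    released_models: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _prepare_monomer(pdb_path: Path, fasta_path: Path,
                     meta: Optional[ModelMetadata],
                     config: PipelineConfig,
                     manifest: RunManifest, tag: str):
    """Parse, map to canonical, renumber; QC if it is a homology model.
    Returns (renumbered chain, canonical seq, accession, StructureModel,
    passed_qc flag)."""
    model = parse_pdb(pdb_path.read_text(), first_nmr_model_only=True)
    chain = model.chains[0]
    seqs = read_fasta(fasta_path)
    acc, canonical = next(iter(seqs.items()))
    rmap = build_residue_map(atom_sequence(chain), canonical)
    chain = renumber_chain(chain, rmap)
    chain.uniprot_acc = acc
    passed = True
    if model.provenance == "homology-model":
        m = meta or ModelMetadata(confidence=100.0, template_identity=100.0,
                                  target_length=len(canonical))
        if not m.target_length:
            m.target_length = len(canonical)
        report = qc_model(chain, m, len(canonical), config)
        manifest.qc[tag] = report.to_dict()
        passed = report.overall_pass
        if not passed:
            manifest.warnings.append(
                f"{tag} failed QC on: {', '.join(report.failed())}")
    return chain, canonical, acc, model, passed


def run_pipeline(monomer1: Path | str, monomer2: Path | str,
                 canonical1: Path | str, canonical2: Path | str,
                 variants_tsv: Optional[Path | str],
                 library_index: Path | str,
                 outdir: Path | str,
                 config: PipelineConfig = DEFAULT_CONFIG,
                 meta1: Optional[ModelMetadata] = None,
                 meta2: Optional[ModelMetadata] = None) -> tuple[RunManifest, int]:
    """Run the whole pipeline; returns (manifest, exit_code).

    Exit code 0 means at least one docking model was released; 3 means the
    run completed cleanly but nothing passed the gates (including QC
    failures); errors raise.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"monomer1": Path(monomer1), "monomer2": Path(monomer2),
             "canonical1": Path(canonical1), "canonical2": Path(canonical2),
             "library_index": Path(library_index)}
    if variants_tsv is not None:
        paths["variants"] = Path(variants_tsv)
    for name, p in paths.items():
        if not p.is_file():
            raise DockmapError(f"input {name} not readable: {p}")

    manifest = RunManifest(config=config.to_dict(),
                           started=datetime.now(timezone.utc).isoformat())
    manifest.input_digests = {k: _digest(p) for k, p in paths.items()}

    c1, seq1, acc1, sm1, ok1 = _prepare_monomer(paths["monomer1"], paths["canonical1"],
                                                meta1, config, manifest, "monomer1")
    c2, seq2, acc2, sm2, ok2 = _prepare_monomer(paths["monomer2"], paths["canonical2"],
                                                meta2, config, manifest, "monomer2")
    manifest.counts["candidates_in"] = 2
    manifest.counts["passed_qc"] = int(ok1) + int(ok2)

    library = load_template_library(paths["library_index"])
    manifest.counts["templates_tried"] = 0
    manifest.counts["models_gated"] = 0
    manifest.counts["models_released"] = 0
    manifest.counts["variants_mapped"] = 0

    released: list[DockModel] = []
    if ok1 and ok2:
        manifest.counts["templates_tried"] = len(library)
        gated = dock_all(c1, c2, library, tm_gate=config.tm_gate,
                         score_gate=0.0,  # count TM-gated models first
                         contact_cutoff=config.contact_cutoff,
                         clash_cutoff=config.clash_cutoff, probe=config.probe)
        manifest.counts["models_gated"] = len(gated)
        released = [m for m in gated if m.combined_score > config.score_gate]
        manifest.counts["models_released"] = len(released)

    prov = classify_provenance(sm1, sm2)
    variants = None
    if variants_tsv is not None:
        variants, skipped = parse_variants(paths["variants"])
        if skipped:
            manifest.warnings.append(f"skipped {skipped} malformed variant rows")

    for k, model in enumerate(released, start=1):
        # A/B labels by canonical length; chain accessions decide the order
        la = len(seq1) if model.chain_a.uniprot_acc == acc1 else len(seq2)
        lb = len(seq1) if model.chain_b.uniprot_acc == acc1 else len(seq2)
        first_is_a = la > lb or (la == lb and (model.chain_a.uniprot_acc or "")
                                 <= (model.chain_b.uniprot_acc or ""))
        ca, cb = relabel_complex(model.chain_a, model.chain_b, la, lb)
        model.chain_a, model.chain_b = ca, cb
        if model.interface is not None and not first_is_a:
            model.interface.interface_residues_a, model.interface.interface_residues_b = \
                model.interface.interface_residues_b, model.interface.interface_residues_a
        model.provenance_class = prov
        stem = outdir / f"complex_{k:03d}"
        write_dock_model(model, stem.with_suffix(".pdb"),
                         Path(str(stem) + ".scores.json"))
        manifest.released_models.append(
            {"file": stem.with_suffix(".pdb").name, **model.sidecar()})
        if variants is not None:
            mapped, summary = map_variants(variants, model)
            write_mapped_variants(mapped, Path(str(stem) + ".variants.tsv"),
                                  Path(str(stem) + ".features.json"))
            if k == 1:
                manifest.counts["variants_mapped"] = summary.matched
            for acc, pos, wt, found in summary.wt_mismatches[:20]:
                manifest.warnings.append(
                    f"wild-type mismatch {acc} pos {pos}: table {wt}, structure {found}")

    manifest.finished = datetime.now(timezone.utc).isoformat()
    (outdir / "manifest.json").write_text(manifest.to_json())
    code = EXIT_OK if released else EXIT_NO_MODELS
    return manifest, code
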
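"""Missense-variant tables, categories, and mapping onto docked complexes.

Variants live on canonical UniProt coordinates and fall into four display
categories: *disease* (at least one experimental study links the variant
to a specific disease), *benign* (studies exist and none points to
disease), *predicted* (no studies, but a predictor score is available;
scores > 0.5 are flagged likely disease-causing) and *unknown* (neither).
Because docked complexes are renumbered to canonical positions, mapping a
variant is a direct residue-number lookup on the matching chain, plus an
interface-membership flag.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import VariantFormatError
from .geometry import InterfaceReport
from .docking import DockModel
from .structio import atom_sequence

log = logging.getLogger(__name__)

CATEGORIES = ("disease", "benign", "predicted", "unknown")
LIKELY_DISEASE_CUTOFF = 0.5
_CATEGORY_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}

REQUIRED_COLUMNS = ("accession", "position", "wt", "variant", "category", "source")


@dataclass
class VariantRecord:
    accession: str
    position: int                    # canonical 1-based
    wt_aa: str
    var_aa: str
    category: str = "unknown"
    prediction_score: Optional[float] = None
    source: str = ""


@dataclass
class MappedVariant:
    variant: VariantRecord
    chain_label: str                 # 'A' or 'B'
    residue_number: int
    modeled: bool
    at_interface: bool
    likely_disease: bool

    def to_row(self) -> dict:
        v = self.variant
        return {"accession": v.accession, "position": v.position,
                "wt": v.wt_aa, "variant": v.var_aa, "category": v.category,
                "prediction_score": v.prediction_score, "source": v.source,
                "chain": self.chain_label, "modeled": self.modeled,
                "at_interface": self.at_interface,
                "likely_disease": self.likely_disease}


def classify_variant(study_flags: Iterable[bool],
                     prediction_score: Optional[float]) -> str:
    """Category from experimental-study outcomes and an optional predictor
    score.  ``study_flags`` holds one boolean per experimental study (True =
    points to a disease)."""
    flags = list(study_flags)
    if any(flags):
        return "disease"
    if flags:
        return "benign"
    if prediction_score is not None:
        return "predicted"
    return "unknown"


def parse_variants(tsv: Path | str | pd.DataFrame) -> tuple[list[VariantRecord], int]:
    """Read a variant table; returns (records, skipped_row_count).

    Malformed rows (unparseable position, empty residue codes, unknown
    category) are logged and skipped.  Duplicate (accession, position,
    variant) rows are merged: sources are unioned and the category with
    the highest precedence (disease > benign > predicted > unknown) wins.
    """
    if isinstance(tsv, pd.DataFrame):
        df = tsv
    else:
        df = pd.read_csv(tsv, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantFormatError(f"variant table missing columns {missing}")
    records: dict[tuple[str, int, str], VariantRecord] = {}
    skipped = 0
    for row in df.to_dict("records"):
        try:
            pos = int(str(row["position"]).strip())
            wt = str(row["wt"]).strip().upper()
            var = str(row["variant"]).strip().upper()
            cat = str(row["category"]).strip().lower()
            if pos < 1 or len(wt) != 1 or len(var) != 1 or cat not in CATEGORIES:
                raise ValueError("bad field value")
            score_raw = str(row.get("prediction_score", "")).strip()
            score = float(score_raw) if score_raw else None
            if score is not None and not 0 <= score <= 1:
                raise ValueError("prediction score outside [0, 1]")
        except (ValueError, TypeError) as e:
            skipped += 1
            log.info("skipping malformed variant row %r: %s", row, e)
            continue
        key = (str(row["accession"]).strip(), pos, var)
        rec = VariantRecord(accession=key[0], position=pos, wt_aa=wt, var_aa=var,
                            category=cat, prediction_score=score,
                            source=str(row.get("source", "")).strip())
        if key in records:
            old = records[key]
            srcs = [s for s in old.source.split(";") if s]
            if rec.source and rec.source not in srcs:
                srcs.append(rec.source)
            old.source = ";".join(srcs)
            if _CATEGORY_PRIORITY[rec.category] < _CATEGORY_PRIORITY[old.category]:
                old.category = rec.category
            if old.prediction_score is None:
                old.prediction_score = rec.prediction_score
        else:
            records[key] = rec
    return list(records.values()), skipped


@dataclass
class MappingSummary:
    counts: dict[str, dict[str, int]] = field(default_factory=dict)  # chain -> category -> n
    matched: int = 0
    unmatched: list[VariantRecord] = field(default_factory=list)
    wt_mismatches: list[tuple[str, int, str, str]] = field(default_factory=list)


def map_variants(variants: Sequence[VariantRecord], complex_model: DockModel,
                 interface: Optional[InterfaceReport] = None
                 ) -> tuple[list[MappedVariant], MappingSummary]:
    """Place variants on a renumbered, A/B-labeled docked complex.

    Each variant goes to the chain whose UniProt accession matches; its
    ``modeled`` flag records whether the canonical position is present in
    the structure, and ``at_interface`` whether it belongs to the interface
    residue set of its chain.  The wild-type residue is cross-checked
    against the ATOM-derived sequence; mismatches are collected as warnings,
    not errors.  Variants matching neither chain go to an unmatched bucket.
    """
    iface = interface if interface is not None else complex_model.interface
    iface = iface or InterfaceReport()
    chains = {"A": complex_model.chain_a, "B": complex_model.chain_b}
    iface_sets = {"A": iface.interface_residues_a, "B": iface.interface_residues_b}
    seqs = {}
    for lab, ch in chains.items():
        seqs[lab] = {r.number: letter
                     for r, letter in zip(ch.residues, atom_sequence(ch))}
    summary = MappingSummary(counts={lab: {c: 0 for c in CATEGORIES} for lab in chains})
    mapped: list[MappedVariant] = []
    for v in variants:
        lab = next((l for l, ch in chains.items() if ch.uniprot_acc == v.accession), None)
        if lab is None:
            summary.unmatched.append(v)
            continue
        modeled = v.position in seqs[lab]
        if modeled and seqs[lab][v.position] != v.wt_aa:
            summary.wt_mismatches.append((v.accession, v.position, v.wt_aa,
                                          seqs[lab][v.position]))
        at_iface = modeled and v.position in iface_sets[lab]
        likely = v.prediction_score is not None and \
            v.prediction_score > LIKELY_DISEASE_CUTOFF
        mapped.append(MappedVariant(variant=v, chain_label=lab,
                                    residue_number=v.position, modeled=modeled,
                                    at_interface=at_iface, likely_disease=likely))
        summary.counts[lab][v.category] += 1
        summary.matched += 1
    return mapped, summary


def mapped_to_dataframe(mapped: Sequence[MappedVariant]) -> pd.DataFrame:
    return pd.DataFrame([m.to_row() for m in mapped])


def to_protvista_features(mapped: Sequence[MappedVariant]) -> list[dict]:
    """Minimal sequence-feature JSON (one feature per variant) suitable for
    track viewers: position, category, description."""
    feats = []
    for m in mapped:
        v = m.variant
        feats.append({
            "type": "VARIANT",
            "category": v.category,
            "begin": v.position,
            "end": v.position,
            "wildType": v.wt_aa,
            "alternativeSequence": v.var_aa,
            "description": f"{v.wt_aa}{v.position}{v.var_aa} ({v.category};"
                           f" chain {m.chain_label};"
                           f"{' interface;' if m.at_interface else ''}"
                           f" source {v.source or 'n/a'})",
        })
    return feats


def write_mapped_variants(mapped: Sequence[MappedVariant], tsv_path: Path,
                          json_path: Optional[Path] = None) -> None:
    mapped_to_dataframe(mapped).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        json_path.write_text(json.dumps(to_protvista_features(mapped), indent=2) + "\n")
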
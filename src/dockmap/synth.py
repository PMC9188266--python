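"""Deterministic synthetic structures, sequences and variant tables.

Real inputs to the pipeline are homology models, experimental complexes
and UniProt variant exports; none of those can ship with the package, so
this module generates idealized stand-ins with the geometric properties
the pipeline's filters actually probe:

* compact "globular" C-alpha folds (a serpentine space-filling trace with
  ideal 3.8 A virtual bonds) that pass the shape filters,
* ideal alpha-helices (elongated; fail the anisotropy filter when long),
* circular-arc "banana" traces (fail the normalized radius-of-gyration
  filter),
* excluded-volume random coils as docking decoys,
* binary complexes built from two compact monomers with a designed
  interface gap,
* canonical sequences consistent with the structures (optionally with
  extra unmodeled termini, to exercise renumbering), and
* variant tables drawn from the four display categories at the observed
  proportions of a large variant export (disease 0.137, benign 0.003,
  unknown 0.043, predicted 0.817; 54% of predictions scoring > 0.5).

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structio import AtomRecord, Chain, Residue, StructureModel, write_pdb

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
       "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
       "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
       "W": "TRP", "Y": "TYR"}
AA1 = {v: k for k, v in AA3.items()}

CA_STEP = 3.8  # A, ideal virtual C-alpha bond

# category proportions of the emulated variant export
VARIANT_PROPORTIONS = {"disease": 0.137, "benign": 0.003,
                       "unknown": 0.043, "predicted": 0.817}
PREDICTED_LIKELY_DISEASE_FRACTION = 0.54


# ---------------------------------------------------------------------------
# C-alpha traces
# ---------------------------------------------------------------------------

def serpentine_ca(n: int, step: float = CA_STEP) -> np.ndarray:
    """Compact globular toy fold: a boustrophedon space-filling trace on a
    cubic grid with ideal consecutive C-alpha spacing.  Near-isotropic and
    compact, so it passes both molecular-envelope filters."""
    if n < 1:
        raise ValueError("need at least one residue")
    side = max(2, math.ceil(n ** (1.0 / 3.0)))
    pts: list[tuple[int, int, int]] = []
    for iz in range(side):
        layer = []
        for iy in range(side):
            xs = range(side) if iy % 2 == 0 else range(side - 1, -1, -1)
            layer.extend((ix, iy, iz) for ix in xs)
        if iz % 2 == 1:  # reversed snake keeps consecutive cells adjacent
            layer.reverse()
        pts.extend(layer)
        if len(pts) >= n:
            break
    return np.array(pts[:n], dtype=float) * step


def helix_ca(n: int, radius: float = 2.3, rise: float = 1.5,
             twist_deg: float = 100.0) -> np.ndarray:
    """Ideal alpha-helical C-alpha trace along z (elongated when long)."""
    t = np.arange(n) * math.radians(twist_deg)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            np.arange(n) * rise])


def arc_ca(n: int, step: float = CA_STEP, sweep_deg: float = 330.0) -> np.ndarray:
    """C-alpha trace along a circular arc ("banana"): mass sits at the rim,
    pushing the normalized radius of gyration toward 1."""
    sweep = math.radians(sweep_deg)
    radius = step / (2 * math.sin(sweep / (2 * (n - 1))))
    t = np.linspace(0.0, sweep, n)
    return np.column_stack([radius * np.cos(t), radius * np.sin(t),
                            np.zeros(n)])


def random_coil_ca(n: int, rng: np.random.Generator,
                   step: float = CA_STEP, min_sep: float = 3.4,
                   max_tries: int = 60) -> np.ndarray:
    """Excluded-volume random walk with ideal bond length: an unfolded
    decoy that no compact template should align to."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        placed = False
        for _ in range(max_tries):
            v = rng.normal(size=3)
            v *= step / np.linalg.norm(v)
            cand = pts[-1] + v
            d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) if len(pts) > 1 else [min_sep + 1]
            if np.min(d) >= min_sep:
                pts.append(cand)
                placed = True
                break
        if not placed:  # dead end: back off one step
            pts.pop()
            if not pts:
                pts = [np.zeros(3)]
    return np.array(pts)


def perturb(coords: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian coordinate noise, sigma in angstrom per component."""
    return coords + rng.normal(scale=sigma, size=coords.shape)


def smooth_perturb(coords: np.ndarray, sigma: float, rng: np.random.Generator,
                   window: int = 15) -> np.ndarray:
    """Correlated coordinate noise along the chain.

    Homology-model error is smooth — neighboring residues shift together,
    so virtual C-alpha bonds stay near 3.8 A even at ~1 A overall
    displacement.  Implemented as per-component Gaussian noise smoothed by
    a moving average over ``window`` residues and rescaled to a per-atom
    component std of ``sigma``."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    raw = rng.normal(size=(n + window - 1, 3))
    kernel = np.ones(window) / window
    smooth = np.stack([np.convolve(raw[:, k], kernel, mode="valid")
                       for k in range(3)], axis=1)
    smooth *= sigma * math.sqrt(window)   # restore per-atom std
    return coords + smooth


def random_rigid_motion(rng: np.random.Generator, tmax: float = 30.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random proper rotation (QR of a Gaussian matrix) and a
    random translation with components in [-tmax, tmax]."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    t = rng.uniform(-tmax, tmax, size=3)
    return Q, t


# ---------------------------------------------------------------------------
# Chains, monomers, complexes
# ---------------------------------------------------------------------------

def random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def chain_from_ca(coords: np.ndarray, seq: str, label: str = "A",
                  start_number: int = 1, uniprot_acc: str = "") -> Chain:
    """Build a C-alpha-only chain from a trace and a one-letter sequence."""
    coords = np.asarray(coords, dtype=float)
    if len(seq) != coords.shape[0]:
        raise ValueError("sequence length must match coordinate count")
    residues = []
    for k, (aa, (x, y, z)) in enumerate(zip(seq, coords)):
        num = start_number + k
        resname = AA3[aa]
        atom = AtomRecord(serial=k + 1, name="CA", resname=resname,
                          chain_id=label, resseq=num, icode=" ",
                          x=float(x), y=float(y), z=float(z),
                          occupancy=1.0, element="C")
        residues.append(Residue(resname=resname, number=num, atoms=[atom]))
    return Chain(label=label, residues=residues, source_chain=label,
                 uniprot_acc=uniprot_acc)


def delete_segment(chain: Chain, start: int, end: int) -> Chain:
    """Remove residues with numbers in [start, end] (an unmodeled run)."""
    from dataclasses import replace
    kept = [r for r in chain.residues if not start <= r.number <= end]
    return replace(chain, residues=kept)


@dataclass
class SyntheticComplex:
    """A designed binary complex plus everything the pipeline needs."""
    model: StructureModel            # two chains, in complex frame
    seq_a: str                       # canonical sequence of chain A's protein
    seq_b: str
    acc_a: str
    acc_b: str
    offset_a: int                    # canonical position of chain's 1st residue
    offset_b: int


def make_complex(seed: int = 0, n_a: int = 64, n_b: int = 48,
                 gap: float = CA_STEP, tail_a: int = 0, tail_b: int = 0,
                 acc_a: str = "P10001", acc_b: str = "P10002") -> SyntheticComplex:
    """Two compact monomers facing each other across a ``gap``-angstrom
    interface.  The facing faces are offset by half a grid step so each
    interface residue packs against two partners, as side chains do in a
    real interface (C-alpha-only traces would otherwise give each residue
    a single, fragile contact).  ``tail_a``/``tail_b`` add unmodeled
    canonical termini (the canonical sequence gains that many extra
    residues on each side, and the chain's structure covers positions
    tail+1 .. tail+n)."""
    rng = np.random.default_rng(seed)
    ca_a = serpentine_ca(n_a)
    ca_b = serpentine_ca(n_b)
    # face the B cube against A along +x, interdigitated by half a step in y
    shift = np.array([ca_a[:, 0].max() + gap - ca_b[:, 0].min(),
                      CA_STEP / 2.0, 0.0])
    ca_b = ca_b + shift
    mod_a = random_sequence(n_a, rng)
    mod_b = random_sequence(n_b, rng)
    seq_a = random_sequence(tail_a, rng) + mod_a + random_sequence(tail_a, rng)
    seq_b = random_sequence(tail_b, rng) + mod_b + random_sequence(tail_b, rng)
    chain_a = chain_from_ca(ca_a, mod_a, "A", start_number=tail_a + 1,
                            uniprot_acc=acc_a)
    chain_b = chain_from_ca(ca_b, mod_b, "B", start_number=tail_b + 1,
                            uniprot_acc=acc_b)
    model = StructureModel(chains=[chain_a, chain_b],
                           provenance="experimental", method="xray",
                           resolution=2.0)
    return SyntheticComplex(model=model, seq_a=seq_a, seq_b=seq_b,
                            acc_a=acc_a, acc_b=acc_b,
                            offset_a=tail_a, offset_b=tail_b)


def make_tetramer(seed: int = 0, n: int = 40) -> StructureModel:
    """Homotetramer with one engineered large interface (chains A-B close,
    C and D dispersed): exercises largest-interface selection."""
    rng = np.random.default_rng(seed)
    base = serpentine_ca(n)
    seq = random_sequence(n, rng)
    width = base[:, 0].max()
    placements = {"A": np.array([0.0, 0.0, 0.0]),
                  "B": np.array([width + 4.4, 0.0, 0.0]),     # tight interface
                  "C": np.array([0.0, width + 9.0, 0.0]),     # marginal contact
                  "D": np.array([120.0, 120.0, 0.0])}         # far away
    chains = [chain_from_ca(base + t, seq, lab, uniprot_acc="P20000")
              for lab, t in placements.items()]
    return StructureModel(chains=chains, provenance="experimental", method="xray")


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

def make_variant_table(accession: str, canonical_seq: str, n_variants: int,
                       rng: np.random.Generator,
                       proportions: Optional[dict[str, float]] = None,
                       wt_mismatch_rate: float = 0.0) -> pd.DataFrame:
    """Synthetic variant export in the pipeline's TSV schema.

    Categories are drawn at ``proportions`` (default: the emulated export
    proportions); predicted variants get a score with 54% above 0.5.
    ``wt_mismatch_rate`` injects rows whose stated wild-type disagrees with
    the canonical sequence, to exercise the mismatch warnings.
    """
    props = proportions or VARIANT_PROPORTIONS
    cats = list(props)
    p = np.array([props[c] for c in cats], dtype=float)
    p /= p.sum()
    L = len(canonical_seq)
    rows = []
    for _ in range(n_variants):
        pos = int(rng.integers(1, L + 1))
        wt = canonical_seq[pos - 1]
        if wt_mismatch_rate and rng.random() < wt_mismatch_rate:
            wt = rng.choice([a for a in AA20 if a != wt])
        var = rng.choice([a for a in AA20 if a != wt])
        cat = cats[int(rng.choice(len(cats), p=p))]
        score = ""
        if cat == "predicted":
            if rng.random() < PREDICTED_LIKELY_DISEASE_FRACTION:
                score = f"{rng.uniform(0.501, 1.0):.3f}"
            else:
                score = f"{rng.uniform(0.0, 0.499):.3f}"
        src = rng.choice(["uniprot-reviewed", "large-scale-study"])
        rows.append({"accession": accession, "position": pos, "wt": wt,
                     "variant": var, "category": cat,
                     "prediction_score": score, "source": src})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk fixture bundles
# ---------------------------------------------------------------------------

def make_fixture_bundle(outdir: Path | str, seed: int = 0,
                        n_a: int = 64, n_b: int = 48,
                        tail: int = 5, n_decoy_templates: int = 3,
                        n_variants: int = 120,
                        monomer_sigma: float = 0.8) -> dict:
    """Write a complete synthetic input bundle for the pipeline.

    Produces two monomer PDB files (homology-model-style, mildly perturbed
    copies of the complex chains in random frames), canonical FASTA files,
    a variant TSV, and a template library directory (the true complex plus
    random-coil decoy templates) with its index TSV.  Returns a manifest of
    the written paths.  Identical ``seed`` -> identical bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    cx = make_complex(seed=seed, n_a=n_a, n_b=n_b, tail_a=tail, tail_b=tail)

    # monomers: perturbed copies of the complex chains in their own frames
    paths = {}
    for name, chain, acc, seq in (("monomer1", cx.model.chains[0], cx.acc_a, cx.seq_a),
                                  ("monomer2", cx.model.chains[1], cx.acc_b, cx.seq_b)):
        ca = np.array([r.ca.coord for r in chain.residues])
        R, t = random_rigid_motion(rng)
        ca = smooth_perturb(ca @ R.T + t, monomer_sigma, rng)
        mono_seq = "".join(AA1[r.resname] for r in chain.residues)
        mono = chain_from_ca(ca, mono_seq, "A",
                             start_number=chain.residues[0].number,
                             uniprot_acc=acc)
        sm = StructureModel(chains=[mono], provenance="homology-model",
                            method="model")
        p = outdir / f"{name}.pdb"
        p.write_text(write_pdb(sm))
        paths[name] = p
        fasta = outdir / f"{name}.fasta"
        fasta.write_text(f">sp|{acc}|SYNTH_HUMAN synthetic\n{seq}\n")
        paths[f"{name}_fasta"] = fasta

    # variant tables for both proteins, concatenated
    va = make_variant_table(cx.acc_a, cx.seq_a, n_variants, rng)
    vb = make_variant_table(cx.acc_b, cx.seq_b, n_variants, rng)
    variants = outdir / "variants.tsv"
    pd.concat([va, vb], ignore_index=True).to_csv(variants, sep="\t", index=False)
    paths["variants"] = variants

    # template library: the true complex plus coil decoys
    libdir = outdir / "templates"
    libdir.mkdir(exist_ok=True)
    index_rows = [{"id": "tpl_true", "file": "tpl_true.pdb",
                   "source": "synthetic", "chain1": "A", "chain2": "B"}]
    (libdir / "tpl_true.pdb").write_text(write_pdb(cx.model))
    for k in range(n_decoy_templates):
        c1 = random_coil_ca(n_a, rng)
        c2 = random_coil_ca(n_b, rng) + np.array([c1[:, 0].max() + 6.0, 0, 0])
        decoy = StructureModel(chains=[
            chain_from_ca(c1, random_sequence(n_a, rng), "A"),
            chain_from_ca(c2, random_sequence(n_b, rng), "B")],
            provenance="experimental", method="xray")
        fname = f"tpl_decoy{k}.pdb"
        (libdir / fname).write_text(write_pdb(decoy))
        index_rows.append({"id": f"tpl_decoy{k}", "file": fname,
                           "source": "synthetic", "chain1": "A", "chain2": "B"})
    index = libdir / "index.tsv"
    pd.DataFrame(index_rows).to_csv(index, sep="\t", index=False)
    paths["library_index"] = index
    paths["complex"] = cx
    return paths
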
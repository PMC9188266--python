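"""PDB-format structure I/O, ATOM-derived sequences, and UniProt renumbering.

The resource ships every binary complex as a two-chain PDB file whose
residues are renumbered to the positions of the full canonical UniProt
sequence, with the larger protein labeled chain ``A`` and the smaller
chain ``B``.  This module provides the plumbing for that convention:
parsing monomer/complex coordinate files (via gemmi), extracting the
one-letter sequence from the ATOM records, aligning it to the canonical
sequence to build a residue-position map, and rewriting coordinates with
canonical numbering and A/B chain labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.IUPACData import protein_letters_3to1

from .errors import ContractError, MappingError, PDBParseError, PDBWriteError

log = logging.getLogger(__name__)

# 3-letter -> 1-letter for the 20 standard amino acids (title case keys).
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    serial: int
    name: str
    resname: str
    chain_id: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    element: str = "C"

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_standard_aa(self) -> bool:
        return self.resname in _THREE_TO_ONE


@dataclass
class Residue:
    resname: str
    number: int                  # post-renumbering: canonical UniProt position
    atoms: list[AtomRecord] = field(default_factory=list)
    icode: str = " "

    @property
    def has_ca(self) -> bool:
        return any(a.name == "CA" for a in self.atoms)

    @property
    def ca(self) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == "CA":
                return a
        return None


@dataclass
class Chain:
    label: str
    residues: list[Residue] = field(default_factory=list)
    source_chain: str = ""
    uniprot_acc: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """N x 3 array of C-alpha coordinates, residues lacking CA skipped."""
        pts = [r.ca.coord for r in self.residues if r.has_ca]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coord for r in self.residues for a in r.atoms if a.element != "H"]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Chain":
        """Copy of the chain with every atom rigidly moved: x -> R x + t."""
        new_res = []
        for r in self.residues:
            new_atoms = []
            for a in r.atoms:
                x, y, z = rotation @ a.coord + translation
                new_atoms.append(replace(a, x=float(x), y=float(y), z=float(z)))
            new_res.append(replace(r, atoms=new_atoms))
        return replace(self, residues=new_res)


@dataclass
class StructureModel:
    chains: list[Chain]
    provenance: str = "experimental"      # "experimental" | "homology-model"
    method: str = "unknown"               # xray | cryoem | nmr | model | unknown
    resolution: Optional[float] = None
    deposition_date: Optional[date] = None
    model_index: int = 1                  # NMR ensemble member used

    def chain(self, label: str) -> Chain:
        for c in self.chains:
            if c.label == label:
                return c
        raise KeyError(f"no chain {label!r}")


@dataclass
class ResidueMap:
    """1-based correspondence between ATOM-sequence indices and canonical
    UniProt positions.  ``pairs`` is strictly increasing in both coordinates;
    unmapped indices/positions are listed separately."""

    pairs: list[tuple[int, int]]
    unmapped_atom: list[int] = field(default_factory=list)
    unmapped_canonical: list[int] = field(default_factory=list)
    identity: float = 1.0

    def atom_to_canonical(self) -> dict[int, int]:
        return dict(self.pairs)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_METHOD_MAP = [
    ("X-RAY", "xray"),
    ("ELECTRON MICROSCOPY", "cryoem"),
    ("ELECTRON CRYSTALLOGRAPHY", "xray"),
    ("NEUTRON", "xray"),
    ("NMR", "nmr"),
    ("THEORETICAL MODEL", "model"),
]


def _scan_header(text: str) -> tuple[str, Optional[float], Optional[date]]:
    method, resolution, dep = "unknown", None, None
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "EXPDTA":
            expdta = line[6:].strip().upper()
            for key, val in _METHOD_MAP:
                if key in expdta:
                    method = val
                    break
        elif rec == "HEADER" and len(line) >= 59:
            raw = line[50:59].strip()
            try:
                dep = datetime.strptime(raw, "%d-%b-%y").date()
            except ValueError:
                pass
        elif rec == "REMARK" and line[6:10].strip() == "2" and "RESOLUTION" in line:
            for tok in line.split():
                try:
                    resolution = float(tok)
                    break
                except ValueError:
                    continue
    return method, resolution, dep


def _validate_atom_lines(text: str) -> int:
    """Check fixed-column numeric fields of ATOM/HETATM lines; return count."""
    n = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if line.startswith("ATOM"):
            n += 1
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record shorter than 54 columns")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fldtxt = line[lo:hi]
            try:
                v = float(fldtxt)
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: malformed {what} coordinate field {fldtxt!r}"
                ) from None
            if not np.isfinite(v):
                raise PDBParseError(f"line {lineno}: non-finite {what} coordinate")
    return n


def parse_pdb(text: str, first_nmr_model_only: bool = True) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Multi-model (NMR-style) files keep only MODEL 1 when
    ``first_nmr_model_only`` is set.  Alternate locations keep the highest
    occupancy conformer (ties: first encountered).  Raises
    :class:`PDBParseError` on missing ATOM records or malformed coordinate
    fields (naming the offending line).
    """
    if _validate_atom_lines(text) == 0:
        raise PDBParseError("no ATOM records found")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:  # pragma: no cover - gemmi is lenient
        raise PDBParseError(str(e)) from e

    method, resolution, dep = _scan_header(text)
    if st.resolution:
        resolution = float(st.resolution)
    provenance = "homology-model" if method == "model" else "experimental"

    models = list(st)
    used = models[:1] if first_nmr_model_only else models
    chains: list[Chain] = []
    for model in used:
        for gch in model:
            residues: list[Residue] = []
            for gres in gch:
                # altloc policy: per atom name keep highest occupancy, ties first
                best: dict[str, gemmi.Atom] = {}
                order: list[str] = []
                for at in gres:
                    if at.name not in best:
                        best[at.name] = at
                        order.append(at.name)
                    elif at.occ > best[at.name].occ:
                        best[at.name] = at
                atoms = []
                for name in order:
                    at = best[name]
                    atoms.append(AtomRecord(
                        serial=at.serial, name=name, resname=gres.name,
                        chain_id=gch.name, resseq=gres.seqid.num,
                        icode=gres.seqid.icode or " ",
                        x=at.pos.x, y=at.pos.y, z=at.pos.z,
                        occupancy=at.occ, element=at.element.name,
                    ))
                residues.append(Residue(
                    resname=gres.name, number=gres.seqid.num, atoms=atoms,
                    icode=gres.seqid.icode or " ",
                ))
            if residues:
                chains.append(Chain(label=gch.name, residues=residues,
                                    source_chain=gch.name))
        if first_nmr_model_only:
            break
    if not chains:
        raise PDBParseError("no ATOM records found")
    return StructureModel(chains=chains, provenance=provenance, method=method,
                          resolution=resolution, deposition_date=dep,
                          model_index=1)


# ---------------------------------------------------------------------------
# Sequences and residue mapping
# ---------------------------------------------------------------------------

def atom_sequence(chain: Chain, nonstandard_map: Optional[dict[str, str]] = None) -> str:
    """One-letter sequence from the ATOM records, in residue order.

    Non-standard residues become ``X`` unless ``nonstandard_map`` provides a
    translation (e.g. ``{"MSE": "M"}``).
    """
    if not chain.residues:
        raise ValueError("cannot extract a sequence from an empty chain")
    extra = nonstandard_map or {}
    out = []
    for r in chain.residues:
        out.append(_THREE_TO_ONE.get(r.resname, extra.get(r.resname, "X")))
    return "".join(out)


def _make_aligner(mismatch: Optional[float] = None) -> PairwiseAligner:
    aligner = PairwiseAligner()
    if mismatch is None:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    else:
        aligner.match_score = 1.0
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    # do not penalize canonical overhangs: ATOM sequences are substrings
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def build_residue_map(atom_seq: str, canonical_seq: str,
                      mismatch: Optional[float] = None,
                      min_identity: float = 0.30) -> ResidueMap:
    """Globally align the ATOM-derived sequence to the canonical sequence and
    return the 1-based index correspondence.

    Raises :class:`MappingError` when the aligned identity falls below
    ``min_identity`` (default 0.30) — such a map would place variants on the
    wrong residues.
    """
    if not atom_seq or not canonical_seq:
        raise MappingError("cannot align empty sequences")
    aligner = _make_aligner(mismatch)
    aln = aligner.align(atom_seq, canonical_seq)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (c0, c1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            i, j = int(a0) + k, int(c0) + k
            pairs.append((i + 1, j + 1))
            if atom_seq[i] == canonical_seq[j]:
                matches += 1
    if not pairs:
        raise MappingError("alignment produced no aligned positions")
    identity = matches / len(pairs)
    if identity < min_identity:
        raise MappingError(
            f"ATOM/canonical alignment identity {identity:.2f} below floor {min_identity:.2f}"
        )
    mapped_a = {p[0] for p in pairs}
    mapped_c = {p[1] for p in pairs}
    return ResidueMap(
        pairs=pairs,
        unmapped_atom=[i for i in range(1, len(atom_seq) + 1) if i not in mapped_a],
        unmapped_canonical=[j for j in range(1, len(canonical_seq) + 1) if j not in mapped_c],
        identity=identity,
    )


def renumber_chain(chain: Chain, rmap: ResidueMap) -> Chain:
    """Replace residue numbers by canonical UniProt positions.

    Residues whose ATOM-sequence index is unmapped are dropped (and logged).
    Insertion codes are cleared: canonical numbering has none.
    """
    n = len(chain.residues)
    covered = {p[0] for p in rmap.pairs} | set(rmap.unmapped_atom)
    if covered != set(range(1, n + 1)):
        raise ContractError(
            f"residue map covers {len(covered)} indices but chain has {n} residues"
        )
    lookup = rmap.atom_to_canonical()
    out: list[Residue] = []
    dropped = []
    for idx, res in enumerate(chain.residues, start=1):
        if idx in lookup:
            num = lookup[idx]
            atoms = [replace(a, resseq=num, icode=" ") for a in res.atoms]
            out.append(replace(res, number=num, atoms=atoms, icode=" "))
        else:
            dropped.append(idx)
    if dropped:
        log.info("renumber_chain: dropped %d unmapped residues (chain %s)",
                 len(dropped), chain.label)
    numbers = [r.number for r in out]
    if any(b <= a for a, b in zip(numbers, numbers[1:])):
        raise ContractError("renumbered positions are not strictly increasing")
    return replace(chain, residues=out)


def relabel_complex(a: Chain, b: Chain, len_a: int, len_b: int) -> tuple[Chain, Chain]:
    """Label the chain of the longer canonical sequence 'A', the other 'B'.

    Ties are broken by lexicographically smaller UniProt accession -> 'A'.
    Returns ``(chain_A, chain_B)``.
    """
    if len_a <= 0 or len_b <= 0:
        raise ValueError("canonical lengths must be positive")
    if len_a != len_b:
        big, small = (a, b) if len_a > len_b else (b, a)
    else:
        big, small = (a, b) if (a.uniprot_acc or "") <= (b.uniprot_acc or "") else (b, a)
    return replace(big, label="A"), replace(small, label="B")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_EXPDTA = {"xray": "X-RAY DIFFRACTION", "cryoem": "ELECTRON MICROSCOPY",
           "nmr": "SOLUTION NMR", "model": "THEORETICAL MODEL"}


def write_pdb(model: StructureModel) -> str:
    """Serialize to fixed-column PDB ATOM records.

    Round-trips through :func:`parse_pdb` preserving chain labels, residue
    numbers and coordinates to 3 decimals.  Residue numbers above 9999 or
    serials above 99999 do not fit the fixed columns and raise
    :class:`PDBWriteError`.
    """
    lines = []
    if model.method in _EXPDTA:
        lines.append(f"EXPDTA    {_EXPDTA[model.method]}")
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            if res.number > 9999 or res.number < -999:
                raise PDBWriteError(
                    f"residue number {res.number} exceeds PDB column capacity")
            for at in res.atoms:
                serial += 1
                if serial > 99999:
                    raise PDBWriteError("atom serial exceeds PDB column capacity")
                name = at.name if len(at.name) >= 4 else f" {at.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{'':1s}{res.resname:>3s} "
                    f"{chain.label:1s}{res.number:4d}{res.icode:1s}   "
                    f"{at.x:8.3f}{at.y:8.3f}{at.z:8.3f}"
                    f"{at.occupancy:6.2f}{0.0:6.2f}          {at.element:>2s}"
                )
        serial += 1
        lines.append(f"TER   {serial:5d}      {chain.residues[-1].resname:>3s} "
                     f"{chain.label:1s}{chain.residues[-1].number:4d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_fasta(path) -> dict[str, str]:
    """Read canonical sequences; keys are accessions (first ``|``-field that
    looks like one, else the record id)."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ident = rec.id
        if "|" in ident:  # sp|P12345|NAME_HUMAN style
            parts = ident.split("|")
            ident = parts[1] if len(parts) > 1 and parts[1] else parts[0]
        seqs[ident] = str(rec.seq)
    return seqs
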
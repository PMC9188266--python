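"""Rigid superposition, TM-score, structural alignment, shape descriptors,
solvent-accessible surface area and interface analysis.

These are the numerical primitives behind both the homology-model shape
filters and the template-based docking protocol: a Kabsch least-squares
superposition engine, the length-normalized TM-score with its standard
``d0`` scaling, a fragment-seeded sequence-order-dependent structural
aligner in the spirit of TM-align, gyration-tensor shape statistics, and
Shrake-Rupley SASA (via biotite) used to measure interface areas as half
the surface buried on complexation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import biotite.structure as bstruct
from scipy.spatial import cKDTree

from .errors import DegenerateInputError
from .structio import Chain, StructureModel


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class Transform:
    """Proper rigid motion x -> R x + t."""
    rotation: np.ndarray      # 3x3, orthonormal, det +1
    translation: np.ndarray   # 3-vector, angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class ShapeStats:
    rg_ratio: float       # Rg / Rmax, in (0, 1]
    anisotropy: float     # lambda_max / lambda_min of gyration tensor, >= 1


@dataclass
class AlignmentResult:
    pairs: list[tuple[int, int]]   # (target index, template index), 0-based
    transform: Transform           # maps target coords into the template frame
    rmsd: float                    # A over paired C-alpha
    tm_score: float                # normalized by target length
    tm_score_template: float       # same superposition, template-length norm
    seq_identity: float            # fraction of pairs with equal residue type


@dataclass
class InterfaceReport:
    interface_residues_a: set[int] = field(default_factory=set)
    interface_residues_b: set[int] = field(default_factory=set)
    interface_area: float = 0.0    # A^2, (SASA_a + SASA_b - SASA_ab)/2
    clash_count: int = 0           # cross-chain heavy-atom pairs < clash cutoff


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[Transform, float]:
    """Least-squares proper rigid superposition of P onto Q.

    Returns the transform minimizing RMSD(R P + t, Q) with a reflection
    correction so det(R) = +1, and the minimized RMSD.  Requires N >= 3
    non-collinear points.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching N x 3 arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateInputError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    if np.linalg.matrix_rank(P0) < 2:
        raise DegenerateInputError("points are collinear or coincident")
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return Transform(R, t), rmsd


# ---------------------------------------------------------------------------
# TM-score
# ---------------------------------------------------------------------------

def tm_d0(L: int) -> float:
    """Standard TM-score distance scale, floored at 0.5 A; defined for L > 15."""
    if L <= 15:
        raise DegenerateInputError(f"d0 undefined for target length {L} <= 15")
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)


def _tm_sum(d2: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / (d0 * d0))))


def tm_from_distances(distances: np.ndarray, L_target: int) -> float:
    """Closed-form TM-score of a correspondence with known pair distances
    (no superposition search): (1/L) sum 1/(1+(d_i/d0)^2)."""
    d = np.asarray(distances, dtype=float)
    d0 = tm_d0(L_target)
    return _tm_sum(d * d, d0) / L_target


def tm_score(pairs: np.ndarray, coords_target: np.ndarray,
             coords_template: np.ndarray, L_target: int,
             max_iter: int = 20) -> tuple[float, Transform]:
    """Length-normalized TM-score of a fixed residue correspondence,
    maximized over rigid superpositions.

    score = (1/L_target) * sum_i 1 / (1 + (d_i/d0)^2) over the paired set,
    with d0 = 1.24 (L_target - 15)^(1/3) - 1.8 (floored at 0.5 A).  The
    superposition search follows the standard protocol: superpose on seed
    windows of the paired set at several sizes, then iteratively re-superpose
    on the close pairs (d < cutoff) until the selected subset is stable,
    keeping the best score seen.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if pairs.shape[0] == 0:
        raise DegenerateInputError("TM-score needs a non-empty correspondence")
    d0 = tm_d0(L_target)
    P = np.asarray(coords_target, dtype=float)[pairs[:, 0]]
    Q = np.asarray(coords_template, dtype=float)[pairs[:, 1]]
    n = P.shape[0]
    best_score, best_tr = -1.0, Transform.identity()

    seeds: list[np.ndarray] = []
    Lw = n
    while Lw >= 4:
        for start in range(0, n - Lw + 1, max(1, Lw // 2)):
            seeds.append(np.arange(start, start + Lw))
        Lw //= 2
    if n < 4:
        seeds.append(np.arange(n))

    for seed in seeds:
        subset = seed
        prev: Optional[np.ndarray] = None
        for _ in range(max_iter):
            if subset.size < 3:
                break
            try:
                tr, _ = kabsch(P[subset], Q[subset])
            except DegenerateInputError:
                break
            d2 = ((tr.apply(P) - Q) ** 2).sum(axis=1)
            score = _tm_sum(d2, d0) / L_target
            if score > best_score:
                best_score, best_tr = score, tr
            cut = max(d0, 1.0)
            new = np.where(d2 < cut * cut)[0]
            while new.size < 3 and cut < 50.0:
                cut += 0.5
                new = np.where(d2 < cut * cut)[0]
            if prev is not None and new.size == prev.size and np.all(new == prev):
                break
            prev, subset = subset, new
    return best_score, best_tr


# ---------------------------------------------------------------------------
# Structural alignment (fragment-seeded, TM-align-style heuristic)
# ---------------------------------------------------------------------------

_FRAG_LEN = 8
_FRAG_STRIDE = 4


def _monotone_pairs_dp(score: np.ndarray) -> np.ndarray:
    """Best monotone (sequence-order-preserving) pairing maximizing the sum
    of ``score``; gaps are free.  Returns k x 2 index pairs."""
    n, m = score.shape
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        cand = np.maximum(H[i - 1, :-1] + score[i - 1], H[i - 1, 1:])
        H[i, 1:] = np.maximum.accumulate(cand)
    # traceback, preferring matches
    out = []
    i, j = n, m
    while i > 0 and j > 0:
        if H[i, j] == H[i - 1, j - 1] + score[i - 1, j - 1]:
            out.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j]:
            i -= 1
        else:
            j -= 1
    return np.array(out[::-1], dtype=int).reshape(-1, 2)


def structural_align(target: Chain, template: Chain,
                     n_refine_seeds: int = 5, max_iter: int = 10) -> AlignmentResult:
    """Sequence-independent structural alignment of two chains.

    Gapless fragments (length 8, stride 4) of the target are superposed on
    fragments of the template; each seed's gapless extension is TM-scored,
    and the best seeds are refined by alternating (i) a monotone dynamic-
    programming pairing under the current superposition, scoring residue
    pairs by 1/(1+(d/d0)^2), and (ii) Kabsch re-superposition on the close
    pairs, until the paired set is stable.  The result with maximal
    target-normalized TM-score is returned.
    """
    T = target.ca_coords()
    M = template.ca_coords()
    Lt, Lm = len(T), len(M)
    if Lt < _FRAG_LEN or Lm < _FRAG_LEN:
        raise DegenerateInputError(
            f"structural_align needs >= {_FRAG_LEN} C-alpha atoms per chain")
    if Lt <= 15:
        raise DegenerateInputError("target too short for TM-score (L <= 15)")
    d0 = tm_d0(Lt)
    d0m = tm_d0(Lm) if Lm > 15 else d0

    # --- seed stage: gapless diagonal extensions, cheaply scored
    scored_seeds: list[tuple[float, int, int]] = []
    for i in range(0, Lt - _FRAG_LEN + 1, _FRAG_STRIDE):
        for j in range(0, Lm - _FRAG_LEN + 1, _FRAG_STRIDE):
            try:
                tr, _ = kabsch(T[i:i + _FRAG_LEN], M[j:j + _FRAG_LEN])
            except DegenerateInputError:
                continue
            lo = min(i, j)
            hi = min(Lt - i, Lm - j)
            ti = np.arange(i - lo, i + hi)
            mj = np.arange(j - lo, j + hi)
            d2 = ((tr.apply(T[ti]) - M[mj]) ** 2).sum(axis=1)
            scored_seeds.append((_tm_sum(d2, d0) / Lt, i, j))
    if not scored_seeds:
        raise DegenerateInputError("no usable alignment seeds")
    scored_seeds.sort(key=lambda s: (-s[0], s[1], s[2]))

    best = None  # (tm, pairs, transform)
    for _, i, j in scored_seeds[:n_refine_seeds]:
        tr, _ = kabsch(T[i:i + _FRAG_LEN], M[j:j + _FRAG_LEN])
        pairs = None
        for _ in range(max_iter):
            d2 = ((tr.apply(T)[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
            S = 1.0 / (1.0 + d2 / (d0 * d0))
            new_pairs = _monotone_pairs_dp(S)
            if pairs is not None and new_pairs.shape == pairs.shape \
                    and np.all(new_pairs == pairs):
                break
            pairs = new_pairs
            if pairs.shape[0] < 3:
                break
            # cheap update: re-superpose on the close pairs only
            dp = d2[pairs[:, 0], pairs[:, 1]]
            cut = max(d0, 1.0)
            close = pairs[dp < cut * cut]
            if close.shape[0] < 3:
                close = pairs
            try:
                tr, _ = kabsch(T[close[:, 0]], M[close[:, 1]])
            except DegenerateInputError:
                break
        if pairs is None or pairs.shape[0] < 3:
            continue
        tm, tr = tm_score(pairs, T, M, Lt)
        if best is None or tm > best[0]:
            best = (tm, pairs, tr)
    if best is None:
        raise DegenerateInputError("alignment failed on all seeds")
    tm, pairs, tr = best
    d2 = ((tr.apply(T[pairs[:, 0]]) - M[pairs[:, 1]]) ** 2).sum(axis=1)
    rmsd = float(np.sqrt(d2.mean()))
    tm_templ = _tm_sum(d2, d0m) / Lm
    names_t = [r.resname for r in target.residues if r.has_ca]
    names_m = [r.resname for r in template.residues if r.has_ca]
    ident = float(np.mean([names_t[a] == names_m[b] for a, b in pairs]))
    return AlignmentResult(pairs=[(int(a), int(b)) for a, b in pairs],
                           transform=tr, rmsd=rmsd, tm_score=tm,
                           tm_score_template=tm_templ, seq_identity=ident)


# ---------------------------------------------------------------------------
# Shape statistics
# ---------------------------------------------------------------------------

def shape_stats(ca_coords: np.ndarray) -> ShapeStats:
    """Gyration-tensor shape descriptors of a C-alpha point cloud.

    ``anisotropy`` is the ratio of the largest to the smallest eigenvalue of
    the gyration tensor (1 for an isotropic distribution, larger for prolate
    or oblate shapes; infinite for planar/collinear sets).  ``rg_ratio`` is
    the radius of gyration divided by the maximum centroid distance; a
    uniformly filled ball gives sqrt(3/5) ~ 0.775, elongated or flattened
    envelopes approach 1.
    """
    X = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    if X.shape[0] < 4:
        raise DegenerateInputError("shape statistics need at least 4 points")
    C = X - X.mean(axis=0)
    r2 = (C ** 2).sum(axis=1)
    rmax = float(np.sqrt(r2.max()))
    if rmax == 0.0:
        raise DegenerateInputError("all points coincident")
    rg = float(np.sqrt(r2.mean()))
    gyr = (C.T @ C) / X.shape[0]
    ev = np.linalg.eigvalsh(gyr)
    lam_min, lam_max = float(ev[0]), float(ev[-1])
    aniso = np.inf if lam_min <= 0 else lam_max / lam_min
    return ShapeStats(rg_ratio=rg / rmax, anisotropy=float(aniso))


# ---------------------------------------------------------------------------
# SASA and interfaces
# ---------------------------------------------------------------------------

# van der Waals radii (A) for elements common in protein heavy atoms
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "SE": 1.90, "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85,
             "I": 1.98, "FE": 1.80, "ZN": 1.39, "MG": 1.73, "CA": 1.97}
DEFAULT_RADIUS = 1.80
SASA_POINTS = 960


def _chains_to_atoms(chains: list[Chain]):
    """Flatten chains to coordinate/element/key arrays for SASA."""
    coords, elements, keys = [], [], []
    for ch in chains:
        for res in ch.residues:
            for at in res.atoms:
                if at.element == "H":
                    continue
                coords.append((at.x, at.y, at.z))
                elements.append(at.element.upper())
                keys.append((ch.label, res.number))
    return (np.asarray(coords, dtype=float).reshape(-1, 3), elements, keys)


def _radii_for(elements: list[str]) -> np.ndarray:
    radii = np.empty(len(elements))
    unknown = set()
    for k, el in enumerate(elements):
        r = VDW_RADII.get(el)
        if r is None:
            unknown.add(el)
            r = DEFAULT_RADIUS
        radii[k] = r
    if unknown:
        warnings.warn(f"unknown elements {sorted(unknown)}; "
                      f"using default radius {DEFAULT_RADIUS} A")
    return radii


def sasa(model: StructureModel, probe: float = 1.4) -> dict[tuple[str, int], float]:
    """Per-residue solvent-accessible surface area (Shrake-Rupley, 960
    sphere points).  Keys are ``(chain label, residue number)``; unknown
    elements get a default radius with a warning."""
    coords, elements, keys = _chains_to_atoms(model.chains)
    if coords.shape[0] == 0:
        return {}
    radii = _radii_for(elements)
    arr = bstruct.AtomArray(coords.shape[0])
    arr.coord = coords.astype(np.float32)
    arr.element = np.array(elements)
    per_atom = bstruct.sasa(arr, probe_radius=probe, point_number=SASA_POINTS,
                            vdw_radii=radii, ignore_ions=False)
    out: dict[tuple[str, int], float] = {}
    for key, a in zip(keys, per_atom):
        out[key] = out.get(key, 0.0) + float(a)
    return out


def _total_sasa(chains: list[Chain], probe: float) -> float:
    m = StructureModel(chains=chains)
    return float(sum(sasa(m, probe).values()))


def interface_report(a: Chain, b: Chain, contact_cutoff: float = 5.0,
                     clash_cutoff: float = 2.5, probe: float = 1.4) -> InterfaceReport:
    """Interface between two positioned chains.

    Interface area is half the SASA buried on complexation,
    (SASA(a) + SASA(b) - SASA(ab)) / 2.  Interface residues are those with
    any cross-chain heavy-atom pair within ``contact_cutoff``; pairs closer
    than ``clash_cutoff`` are counted as clashes (a diagnostic, never a
    filter).
    """
    if not a.residues or not b.residues:
        raise ValueError("interface_report needs two non-empty chains")
    ca_, ea, ka = _chains_to_atoms([a])
    cb_, eb, kb = _chains_to_atoms([b])
    tree_a, tree_b = cKDTree(ca_), cKDTree(cb_)
    contact = tree_a.query_ball_tree(tree_b, contact_cutoff)
    res_a: set[int] = set()
    res_b: set[int] = set()
    for ia, hits in enumerate(contact):
        if hits:
            res_a.add(ka[ia][1])
            for ib in hits:
                res_b.add(kb[ib][1])
    clash_count = int(tree_a.count_neighbors(tree_b, clash_cutoff))
    if res_a or res_b:
        area = (_total_sasa([a], probe) + _total_sasa([b], probe)
                - _total_sasa([a, b], probe)) / 2.0
        area = max(0.0, float(area))
    else:
        area = 0.0
    return InterfaceReport(interface_residues_a=res_a, interface_residues_b=res_b,
                           interface_area=area, clash_count=clash_count)


def largest_interface_pair(oligomer: StructureModel,
                           contact_cutoff: float = 5.0,
                           probe: float = 1.4) -> tuple[tuple[str, str], InterfaceReport]:
    """Among all unordered chain pairs of an oligomer, the pair with the
    largest interface area (ties broken by lexicographic chain labels)."""
    chains = oligomer.chains
    if len(chains) < 2:
        raise ValueError("largest_interface_pair needs >= 2 chains")
    best_key = None
    best: tuple[tuple[str, str], InterfaceReport] | None = None
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            pair = tuple(sorted((chains[i].label, chains[j].label)))
            rep = interface_report(chains[i], chains[j], contact_cutoff, probe=probe)
            key = (-rep.interface_area, pair)
            if best_key is None or key < best_key:
                best_key, best = key, (pair, rep)
    assert best is not None
    return best
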
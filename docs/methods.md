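# Methods

This note documents the models, conventions and numerical choices behind
`dockmap`, what the synthetic data emulates, and what the tests do and do
not demonstrate about real data.

## Coordinate conventions and renumbering

All variant positions refer to the canonical UniProt sequence, 1-based.
Structures are renumbered by globally aligning the ATOM-derived
one-letter sequence to the canonical sequence (Needleman–Wunsch, BLOSUM62
substitution scores, affine gaps: open 10, extend 0.5, free end gaps so
that ATOM sequences — typically substrings of the canonical sequence —
are not penalized for missing termini). A mapping whose aligned identity
falls below 0.30 is rejected outright: placing variants through a dubious
alignment is worse than placing none. Residues the alignment cannot map
are dropped (and logged), insertion codes are cleared, and the output
numbering is required to be strictly increasing. Each chain is mapped
against its own canonical sequence independently.

Chain labels follow the resource convention: `A` is the protein with the
longer canonical sequence, `B` the shorter; equal lengths fall back to
the lexicographically smaller accession. Altloc conformers keep the
highest occupancy (ties: first encountered); multi-model NMR-style files
keep model 1 only.

## Superposition and structural similarity

Rigid superposition is the closed-form Kabsch solution (SVD of the
covariance, with the determinant correction so only proper rotations are
returned). TM-score uses its standard published form, normalized by the
*target* length with `d0 = 1.24·(L−15)^⅓ − 1.8` floored at 0.5 Å; both
target- and template-normalized values are reported on every alignment,
and the docking gate uses the target-normalized one. The score of a fixed
correspondence is maximized over superpositions by the usual iterative
subset refinement (seed windows of the paired set at several sizes,
re-superpose on pairs closer than `max(d0, 1 Å)` until stable, keep the
best score seen).

`structural_align` is a deliberately simple TM-align-flavoured heuristic,
not a port: gapless fragment seeds (length 8, stride 4) are superposed by
Kabsch, each seed's gapless extension is TM-scored cheaply, and the best
five seeds are refined by alternating a monotone dynamic-programming
pairing (pair score `1/(1+(d/d0)²)`, gaps free) with re-superposition on
the close pairs, until the paired set stabilizes. Its contract is
behavioural: self-alignment yields TM = 1 exactly with the full diagonal
pairing; 0.5 Å perturbed copies score > 0.9; unrelated random coils score
below the 0.4 gate. Sequence-order-independent (non-sequential)
alignment is out of scope.

## Shape filters

The compactness tests on homology models use the gyration tensor of the
Cα cloud. *Anisotropy* is `λ_max/λ_min` of its eigenvalues: exactly 1 for
any point set with three equal gyration eigenvalues (spheres, octahedra,
cubic lattices), larger for prolate or oblate shapes, infinite for
degenerate planar or collinear sets. *rg_ratio* is `R_g/R_max` — the RMS
centroid distance over the maximum centroid distance. The published
filter value "radius of gyration < 0.8" is dimensionless only under some
normalization and the prose does not pin one down; `R_g/R_max` was
adopted because a uniformly filled ball gives `√(3/5) ≈ 0.775`, sitting
just below 0.8, so compact globular mass distributions pass while rings,
arcs ("banana" shapes) and hollow envelopes — whose mass sits at the rim
— approach 1 and fail. This is one defensible reading, and the threshold
is configurable.

Both filters apply to homology models only; experimental structures are
taken as-is.

## QC boundary semantics

Taken literally from the published criteria: confidence ≥ 90 inclusive;
identity > 20 strict; a missing run fails only when longer than 30
residues (31 fails, 30 passes), terminal runs included; the Cα gap bound
is `3.8·g + 1.2 Å` where `g` is the residue-number difference of
consecutive modeled residues, so adjacent residues (g = 1) are allowed up
to 5.0 Å — the ideal virtual bond plus slack — and each missing residue
adds one 3.8 Å bond. Clash counting (cross-chain heavy-atom pairs
< 2.5 Å) is a diagnostic only, never a filter, consistent with the
no-refinement stance. Hit selection takes the best-ranked passing hit,
except that a passing human-template hit obtained by single-crystal
diffraction (X-ray/electron/neutron) or single-particle cryo-EM is
preferred; NMR-derived templates never trigger the override.
Representative-structure selection resolves the published "and/or" as a
strict lexicographic order: coverage (≥ 0.80 required), missing count,
method (X-ray ≻ cryo-EM ≻ NMR), resolution, latest deposition date.

## Docking protocol

Both chain assignments (target 1 on template chain 1 or 2) are aligned
and the assignment with the larger `min(TM_a, TM_b)` kept. Models are
built only when both TM-scores strictly exceed 0.4, by applying the two
alignment transforms to the full target chains — the retained coordinates
are exact rigid motions of the inputs, asserted in tests via invariance
of all intra-chain distances. The trained combined scoring function used
by the original resource is not published; the default surrogate is
`min(TM_a, TM_b)`, which is bounded in [0, 1], monotone in both
arguments, and preserves the semantics of the 0.5 release gate. The
scorer is a plain callable argument, so a trained function can be swapped
in without touching the gates. Rankings sort by descending combined
score with template-id tie-breaks, making the output order independent of
library order.

## SASA and interfaces

Solvent-accessible surface area is Shrake–Rupley with 960 sphere points
and a 1.4 Å probe (computed by `biotite.structure.sasa`, with an explicit
per-element van-der-Waals radius table; unknown elements get 1.8 Å with a
warning). Interface area is `(SASA_a + SASA_b − SASA_ab)/2` — half the
surface buried on complexation. Interface residues are those with any
cross-chain heavy-atom pair within 5.0 Å (k-d tree, verified against an
all-pairs scan in tests). Among oligomer chain pairs, the representative
interface is the one with the largest area, ties by chain label.

## Synthetic data: what it emulates, what it does not

The generator replaces three real input classes:

* **Monomer structures.** Compact folds are serpentine traces on a cubic
  lattice with ideal 3.8 Å virtual bonds — isotropic and compact by
  construction (anisotropy ≈ 1, rg_ratio ≈ 0.75 for a filled cube).
  Model error is emulated as *correlated* Gaussian noise (moving-average
  smoothed over 15 residues, rescaled to 0.8 Å per-component std, in line
  with sub-Å Cα deviations of high-identity homology models): real model
  error displaces whole segments, it does not tear consecutive residues
  apart, so the virtual bonds stay inside the 5.0 Å gap bound.
  Deliberately failing decoys are generated too: long ideal helices
  (anisotropy ≫ 4), circular arcs (rg_ratio > 0.8), segment deletions
  (> 30-residue runs), and excluded-volume random coils.
* **Complexes.** Two lattice folds face each other with interdigitated
  faces at lattice-contact distance (3.8 Å), so every interface residue
  packs against two partners roughly 1 Å inside the 5.0 Å contact cutoff
  — a stand-in for the side-chain packing that Cα-only traces lack, and
  the reason the designed interface survives sub-Å model noise (mean
  interface recall ≈ 96 % at 0.5 Å noise over 20 replicates).
* **Variant tables.** Categories are drawn at proportions observed in a
  large per-complex variant export — disease 0.137, benign 0.003,
  unknown 0.043, predicted 0.817 — with 54 % of predictions scoring
  above the 0.5 likely-disease split; wild-type letters come from the
  canonical sequence (an optional mismatch rate exercises the warnings).

What passing tests therefore show: the filters, gates, transforms and
bookkeeping behave exactly as specified on inputs whose ground truth is
known. What they do not show: docking accuracy on real folds (lattice
toys are far easier to align than remote homologs), the behaviour of the
trained combined score, side-chain-level interface chemistry, or the
selectivity of the shape filters on real model pathologies.

## Problem sizes and determinism

Default study sizes are 48–64-residue monomers, template libraries of a
few entries, hundreds of decoy pairings, and 1,000-table selection
oracles; these make every property checkable in seconds while leaving
all thresholds at their published values. All randomness flows through
`numpy` generators seeded from a single integer; the fixture bundles and
all pipeline data outputs are byte-identical across runs (the manifest's
two wall-clock timestamps are the only exception, and are excluded from
the determinism contract).

## Known limitations

* The structural aligner is sequential-only and fragment-seeded; it can
  undersample alignments between folds with internal repeats.
* PDB output is fixed-column, so residue numbers above 9999 (possible
  for very long canonical sequences) cannot be written.
* The combined-score surrogate ignores interface features entirely; its
  ranking beyond the gate should not be over-interpreted.
* Biounit composition is consumed as metadata (the homodimer retention
  rule is a predicate on provided composition); biounit generation from
  crystal symmetry is not implemented.
* mmCIF input, HETATM chemistry, flexible refinement and free docking
  are out of scope.
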
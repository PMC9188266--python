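"""Template-based docking by full-structure alignment.

Creates a designed binary complex, extracts its two monomers into random
frames with 0.5 A model noise, and docks them against a small template
library (the true complex plus random-coil decoys).  Only alignments with
TM-score > 0.4 on both chains build a model; only combined score > 0.5 is
released.
"""

import numpy as np

from dockmap import synth
from dockmap.docking import TemplateEntry, dock_all

cx = synth.make_complex(seed=1)
a, b = cx.model.chains

rng = np.random.default_rng(7)
targets = []
for ch in (a, b):
    R, t = synth.random_rigid_motion(rng)
    ca = synth.perturb(ch.ca_coords() @ R.T + t, 0.5, rng)
    seq = "".join(synth.AA1[r.resname] for r in ch.residues)
    targets.append(synth.chain_from_ca(ca, seq, ch.label, uniprot_acc=ch.uniprot_acc))

library = [TemplateEntry("tpl_true", a, b)]
for k in range(3):
    c1 = synth.chain_from_ca(synth.random_coil_ca(64, rng),
                             synth.random_sequence(64, rng), "A")
    c2 = synth.chain_from_ca(synth.random_coil_ca(48, rng) + [40.0, 0, 0],
                             synth.random_sequence(48, rng), "B")
    library.append(TemplateEntry(f"tpl_decoy{k}", c1, c2))

models = dock_all(targets[0], targets[1], library)
print(f"library size {len(library)}, released models: {len(models)}")
for m in models:
    print(f"  template {m.template_id}: TM_a={m.tm_a:.3f} TM_b={m.tm_b:.3f} "
          f"combined={m.combined_score:.3f} "
          f"interface={m.interface.interface_area:.0f} A^2 "
          f"clashes={m.interface.clash_count}")

# Only the true template survives: both targets align to its chains at
# TM ~0.9 (0.5 A noise on a 48-64 residue fold), while the coil decoys sit
# far below the 0.4 gate.  The released coordinates are exact rigid
# placements of the inputs - no refinement.
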
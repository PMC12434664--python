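"""Project an unfolding ensemble onto 2D with the ELViM workflow:
Q_w dissimilarities -> force-scheme embedding -> KDE density -> local
conformational signature of the densest region.
"""

import numpy as np

from rnalandscape import (
    datasets,
    dissimilarity_matrix,
    force_scheme,
    kde_density,
    local_signature,
    morph_ensemble,
    native_contacts,
    q_series,
)
from rnalandscape.elvim import region_from_density

cg, _ = datasets.synthetic_riboswitch()
nc = native_contacts(cg)
traj = morph_ensemble(cg, n_frames=200, unfold_fraction=1.0, noise=0.4, seed=11)
q = q_series(traj.rna, nc)

D = dissimilarity_matrix(traj.rna, cg.bead_residues)   # sigma0 = 3 A, eps = 0.15
print(f"dissimilarity matrix: {len(D)} frames, max delta = {D.values.max():.3f} "
      "(0 = identical conformations, 1 = unrelated)")

emb = force_scheme(D, n_iter=100, seed=3)
print(f"force-scheme embedding: stress {emb.stress_history[0]:.3f} -> "
      f"{emb.stress:.3f} over {emb.n_iter} iterations")

kde_density(emb)
region = region_from_density(emb, quantile=0.75, label="densest basin")
sig = local_signature(region, traj.rna)
print(f"densest-basin region: {len(region)} conformations")
print(f"local signature: centroid frame {sig.centroid_index} "
      f"(Q = {q[sig.centroid_index]:.2f}), mean dRMSD to region "
      f"{sig.mean_drmsd:.2f} A")
print("the centroid is the region's representative conformation: the frame "
      "minimizing average dRMSD to all others in the region")
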
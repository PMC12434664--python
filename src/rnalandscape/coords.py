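"""Reaction coordinates and structural metrics.

Q, the fraction of native contacts, is the order parameter used throughout
the pipeline: a contact is counted as formed when its bead-bead distance is
within a factor lambda (default 1.2, the usual structure-based-model
convention) of the native distance.  RMSD and distance-RMSD complement Q
for coloring embeddings and picking representative conformations.
"""

from __future__ import annotations

import numpy as np
from MDAnalysis.analysis import rms as _mda_rms
from scipy.spatial.distance import pdist

from .rna_model import NativeContactSet

__all__ = ["fraction_native", "q_series", "rmsd", "drmsd", "q_series_to_tsv"]

#: Contact-formation tolerance: formed if r < LAMBDA_Q * r_native.
LAMBDA_Q = 1.2


def fraction_native(
    frame_xyz: np.ndarray, nc: NativeContactSet, lam: float = LAMBDA_Q
) -> float:
    """Fraction of native contacts formed in one frame.

    Q = (# pairs with r_ij < lam * r_ij^native) / N_c, in [0, 1].
    """
    if len(nc) == 0:
        raise ValueError("empty native contact set")
    xyz = np.asarray(frame_xyz, dtype=float)
    d = np.linalg.norm(xyz[nc.pairs[:, 0]] - xyz[nc.pairs[:, 1]], axis=1)
    return float(np.count_nonzero(d < lam * nc.native_distances) / len(nc))


def q_series(
    frames: np.ndarray, nc: NativeContactSet, lam: float = LAMBDA_Q
) -> np.ndarray:
    """Vectorized Q over a (n_frames, n_beads, 3) stack of frames."""
    if len(nc) == 0:
        raise ValueError("empty native contact set")
    frames = np.asarray(frames, dtype=float)
    d = np.linalg.norm(
        frames[:, nc.pairs[:, 0]] - frames[:, nc.pairs[:, 1]], axis=-1
    )
    return (d < lam * nc.native_distances).mean(axis=1)


def rmsd(a_xyz: np.ndarray, b_xyz: np.ndarray) -> float:
    """Minimum RMSD between two frames over rigid rotations + translations."""
    a = np.asarray(a_xyz, dtype=float)
    b = np.asarray(b_xyz, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have equal bead counts")
    if a.shape[0] < 3:
        raise ValueError("RMSD needs at least 3 beads")
    return float(_mda_rms.rmsd(a, b, center=True, superposition=True))


def drmsd(a_xyz: np.ndarray, b_xyz: np.ndarray) -> float:
    """Distance-RMSD: RMS difference of all internal pairwise distances.

    Superposition-free, hence invariant under rigid motion of either frame.
    """
    a = np.asarray(a_xyz, dtype=float)
    b = np.asarray(b_xyz, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have equal bead counts")
    if a.shape[0] < 2:
        raise ValueError("dRMSD needs at least 2 beads")
    return float(np.sqrt(np.mean((pdist(a) - pdist(b)) ** 2)))


def q_series_to_tsv(q: np.ndarray, lam: float = LAMBDA_Q, contact_set_id: str = "") -> str:
    lines = [f"# lambda={lam}\tcontact_set={contact_set_id}", "frame\tQ"]
    lines += [f"{i}\t{v:.6f}" for i, v in enumerate(np.asarray(q))]
    return "\n".join(lines) + "\n"
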
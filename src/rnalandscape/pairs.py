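"""Native base-pair and stacking formation analysis.

At coarse-grained resolution an annotated interaction (a native base pair
or stack between residues i and j) is counted as formed in a frame when
the distance between the two base beads is within a tolerance factor
lambda (default 1.2) of its native base-bead distance.  Leontis-Westhof
class labels on the annotations are carried through as opaque text; no
hydrogen-bond geometry is recomputed, because the beads carry none.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rna_model import AnnotationList, CGStructure

__all__ = [
    "InteractionState",
    "detect_interactions",
    "interaction_states",
    "frequency_vs_q",
    "ensemble_map",
]

LAMBDA_PAIR = 1.2


def _b_bead(res: int) -> int:
    """Base-bead index of a 1-based residue."""
    return 3 * (res - 1) + 2


@dataclass
class InteractionState:
    """Formed/not-formed booleans for every annotated interaction.

    ``formed`` has one row per frame; columns follow the annotation order:
    base pairs first, then stacks (see ``AnnotationList.labels``).
    """

    formed: np.ndarray                 # (n_frames, n_interactions) bool
    annotations: AnnotationList
    lam: float

    def __post_init__(self) -> None:
        self.formed = np.atleast_2d(np.asarray(self.formed, dtype=bool))
        if self.formed.shape[1] != self.annotations.n_interactions:
            raise ValueError("state width must match the annotation list")

    @property
    def n_frames(self) -> int:
        return self.formed.shape[0]

    def nativeness(self) -> np.ndarray:
        """Per-frame fraction of annotated interactions formed."""
        return self.formed.mean(axis=1)


def _interaction_pairs(ann: AnnotationList) -> np.ndarray:
    pairs = [(i, j) for i, j, _ in ann.base_pairs] + list(ann.stacks)
    return np.asarray(pairs, dtype=int)


def _native_b_distances(cg_native: CGStructure, pairs: np.ndarray) -> np.ndarray:
    if pairs.max() > cg_native.n_residues:
        raise ValueError("annotation residue index outside the structure")
    bi = np.array([_b_bead(i) for i in pairs[:, 0]])
    bj = np.array([_b_bead(j) for j in pairs[:, 1]])
    return np.linalg.norm(cg_native.xyz[bi] - cg_native.xyz[bj], axis=1), bi, bj


def detect_interactions(
    frame_xyz: np.ndarray,
    cg_native: CGStructure,
    annotations: AnnotationList,
    lam: float = LAMBDA_PAIR,
) -> InteractionState:
    """Formation state of every annotated interaction in a single frame."""
    return interaction_states(
        np.asarray(frame_xyz)[None], cg_native, annotations, lam
    )


def interaction_states(
    frames: np.ndarray,
    cg_native: CGStructure,
    annotations: AnnotationList,
    lam: float = LAMBDA_PAIR,
) -> InteractionState:
    """Vectorized formation states over a stack of frames."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    pairs = _interaction_pairs(annotations)
    if len(pairs) == 0:
        return InteractionState(
            formed=np.zeros((len(frames), 0), dtype=bool),
            annotations=annotations, lam=lam,
        )
    r_nat, bi, bj = _native_b_distances(cg_native, pairs)
    d = np.linalg.norm(frames[:, bi] - frames[:, bj], axis=-1)
    return InteractionState(formed=d < lam * r_nat, annotations=annotations,
                            lam=lam)


def frequency_vs_q(
    states: InteractionState,
    q_series: np.ndarray,
    bin_width: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-Q-bin formation frequency of every interaction.

    Returns (matrix, bin_edges) with one row per Q bin (low to high);
    rows with no frames are NaN.
    """
    q = np.asarray(q_series, dtype=float)
    if len(q) != states.n_frames:
        raise ValueError("q_series must be aligned with states")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    idx = np.clip(np.digitize(q, edges[1:-1]), 0, n_bins - 1)
    out = np.full((n_bins, states.formed.shape[1]), np.nan)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            out[b] = states.formed[sel].mean(axis=0)
    return out, edges


def ensemble_map(
    states: InteractionState,
    region_frames: np.ndarray | None = None,
    n_residues: int | None = None,
) -> np.ndarray:
    """Residue-by-residue interaction frequency map over a frame subset.

    Cell (i, j) holds the formation frequency of the annotated interaction
    between residues i+1 and j+1 (the maximum if both a base pair and a
    stack are annotated for the same residue pair); symmetric.
    """
    ann = states.annotations
    n_res = n_residues or ann.n_residues
    if n_res is None:
        n_res = int(_interaction_pairs(ann).max())
    sel = (
        np.arange(states.n_frames)
        if region_frames is None
        else np.asarray(region_frames, dtype=int)
    )
    if len(sel) == 0:
        raise ValueError("region must contain at least one frame")
    freq = states.formed[sel].mean(axis=0)
    out = np.zeros((n_res, n_res))
    for (i, j), f in zip(_interaction_pairs(ann), freq):
        a, b = i - 1, j - 1
        out[a, b] = max(out[a, b], f)
        out[b, a] = out[a, b]
    return out
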
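"""Divalent-ion coordination analytics.

Three views of how explicit divalent cations organize around the RNA
backbone: the ion-phosphate radial distribution function (whose first
minimum sets the coordination cutoff), per-phosphate ion occupancy
resolved along the folding coordinate Q, and the probability map of
ion-mediated "bridges" — frames in which a single ion sits within the
cutoff of two sequence-distant phosphates at once, screening their mutual
repulsion.

Distances use the minimum-image convention; the distance test is strict
(r < cutoff), so an ion at exactly the cutoff does not count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "RDF",
    "OccupancyHeatmap",
    "BridgeMap",
    "rdf_mg_phosphate",
    "occupancy",
    "occupancy_vs_q",
    "bridging_map",
    "excess_ions",
]

#: Default ion-phosphate coordination cutoff (A); normally re-derived from
#: the first minimum of the RDF of the trajectory under study.
DEFAULT_CUTOFF = 8.0


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


def _ion_phosphate_dists(traj: Trajectory, frame: int) -> np.ndarray:
    """(n_ions, n_phosphates) minimum-image distances in one frame."""
    p = traj.rna[frame, 0::3]
    d = traj.ions[frame][:, None, :] - p[None, :, :]
    return np.linalg.norm(_min_image(d, traj.box_edge), axis=2)


@dataclass
class RDF:
    """Shell-normalized radial distribution function g(r)."""

    r: np.ndarray
    g: np.ndarray
    bin_width: float
    n_frames: int
    first_minimum: float | None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(self.g < 0):
            raise ValueError("g(r) must be non-negative")

    def to_tsv(self) -> str:
        lines = [f"# first_minimum={self.first_minimum}", "r\tg"]
        lines += [f"{r:.4f}\t{g:.6f}" for r, g in zip(self.r, self.g)]
        return "\n".join(lines) + "\n"


def rdf_mg_phosphate(traj: Trajectory, bin_width: float = 0.25,
                     r_max: float = 25.0) -> RDF:
    """g(r) of ions around phosphate beads, against the ideal-gas density.

    The first-minimum estimate — the r of the minimum of the smoothed g(r)
    after its first peak — is the data-driven coordination cutoff used by
    the occupancy and bridging analyses when no cutoff is supplied.
    """
    if traj.n_ions == 0:
        raise ValueError("trajectory has no ions")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    counts = np.zeros(len(centers))
    for f in range(traj.n_frames):
        d = _ion_phosphate_dists(traj, f).ravel()
        counts += np.histogram(d, bins=edges)[0]

    n_phos = traj.n_beads // 3
    rho = traj.n_ions / traj.box_edge**3
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (traj.n_frames * n_phos * rho * shell)

    first_min = _first_minimum(centers, g)
    return RDF(r=centers, g=g, bin_width=bin_width, n_frames=traj.n_frames,
               first_minimum=first_min)


def _first_minimum(r: np.ndarray, g: np.ndarray) -> float | None:
    """Location of the minimum of smoothed g(r) after its first peak."""
    if len(g) < 5 or g.max() <= 0:
        return None
    kernel = np.ones(5) / 5.0
    gs = np.convolve(g, kernel, mode="same")
    peak = int(np.argmax(gs))
    if peak >= len(gs) - 2:
        return None
    tail = gs[peak:]
    # first local minimum after the peak; fall back to the global tail min
    for k in range(1, len(tail) - 1):
        if tail[k] <= tail[k - 1] and tail[k] <= tail[k + 1]:
            return float(r[peak + k])
    return float(r[peak + int(np.argmin(tail))])


def occupancy(traj: Trajectory, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Per-frame, per-phosphate ion counts within the cutoff sphere.

    An ion close to two phosphates counts toward both — the row sum is a
    coordination count, not a distinct-ion count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n_phos = traj.n_beads // 3
    out = np.zeros((traj.n_frames, n_phos), dtype=int)
    if traj.n_ions == 0:
        return out
    for f in range(traj.n_frames):
        out[f] = (_ion_phosphate_dists(traj, f) < cutoff).sum(axis=0)
    return out


@dataclass
class OccupancyHeatmap:
    """Mean ion count per phosphate, stratified by Q bin.

    Rows are Q bins from low to high; bins with no frames are NaN
    (missing), never zero.
    """

    matrix: np.ndarray                 # (n_bins, n_phosphates)
    bin_edges: np.ndarray
    frames_per_bin: np.ndarray
    cutoff: float
    bin_width: float

    def to_tsv(self) -> str:
        n_bins, n_phos = self.matrix.shape
        header = "Q_bin\t" + "\t".join(f"P{r + 1}" for r in range(n_phos))
        lines = [header]
        for b in range(n_bins):
            mid = 0.5 * (self.bin_edges[b] + self.bin_edges[b + 1])
            row = "\t".join(
                "NA" if np.isnan(v) else f"{v:.4f}" for v in self.matrix[b]
            )
            lines.append(f"{mid:.3f}\t{row}")
        return "\n".join(lines) + "\n"


def occupancy_vs_q(counts: np.ndarray, q_series: np.ndarray,
                   bin_width: float = 0.05,
                   cutoff: float = DEFAULT_CUTOFF) -> OccupancyHeatmap:
    """Bin per-frame occupancy by Q and average within each bin."""
    counts = np.asarray(counts)
    q = np.asarray(q_series, dtype=float)
    if len(counts) != len(q):
        raise ValueError("counts and q_series must be aligned by frame")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.minimum(np.arange(n_bins + 1) * bin_width, 1.0)
    idx = np.clip(np.digitize(q, edges[1:-1]), 0, n_bins - 1)
    matrix = np.full((n_bins, counts.shape[1]), np.nan)
    nper = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        nper[b] = sel.sum()
        if nper[b]:
            matrix[b] = counts[sel].mean(axis=0)
    return OccupancyHeatmap(matrix=matrix, bin_edges=edges, frames_per_bin=nper,
                            cutoff=cutoff, bin_width=bin_width)


@dataclass
class BridgeMap:
    """Probability that an ion simultaneously coordinates two phosphates."""

    matrix: np.ndarray                 # (n_res, n_res), symmetric
    cutoff: float
    min_sep: int
    n_frames: int

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T):
            raise ValueError("bridge map must be symmetric")
        if m.min() < 0 or m.max() > 1:
            raise ValueError("bridge probabilities must lie in [0, 1]")

    def top_pair(self) -> tuple[int, int, float]:
        """Highest-probability residue pair (1-based) and its probability."""
        iu = np.triu_indices_from(self.matrix, k=1)
        k = int(np.argmax(self.matrix[iu]))
        i, j = iu[0][k], iu[1][k]
        return int(i) + 1, int(j) + 1, float(self.matrix[i, j])

    def to_tsv(self) -> str:
        n = len(self.matrix)
        lines = ["res\t" + "\t".join(str(r + 1) for r in range(n))]
        for i in range(n):
            lines.append(
                f"{i + 1}\t" + "\t".join(f"{v:.4f}" for v in self.matrix[i])
            )
        return "\n".join(lines) + "\n"


def bridging_map(traj: Trajectory, cutoff: float = DEFAULT_CUTOFF,
                 min_sep: int = 4) -> BridgeMap:
    """Ion-mediated contact probability between nonlocal phosphates.

    P(i, j) is the fraction of frames with at least one ion within the
    cutoff of both phosphate i and phosphate j, for |i - j| >= min_sep.
    """
    if min_sep < 1:
        raise ValueError("min_sep must be >= 1")
    n_phos = traj.n_beads // 3
    acc = np.zeros((n_phos, n_phos))
    if traj.n_ions:
        for f in range(traj.n_frames):
            within = _ion_phosphate_dists(traj, f) < cutoff
            acc += (within.T.astype(int) @ within.astype(int)) > 0
    prob = acc / traj.n_frames
    ri = np.arange(n_phos)
    prob[np.abs(ri[:, None] - ri[None, :]) < min_sep] = 0.0
    return BridgeMap(matrix=prob, cutoff=cutoff, min_sep=min_sep,
                     n_frames=traj.n_frames)


def excess_ions(
    traj: Trajectory,
    q_series: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF,
    q_folded: float = 0.85,
    q_unfolded: float = 0.4,
    mc_samples: int = 20_000,
    seed: int = 0,
) -> dict[str, float]:
    """Mean excess of distinct ions near the backbone, per folding state.

    "Near" means within the cutoff of at least one phosphate; the excess
    subtracts the ideal-bulk expectation (bulk ion density times the union
    volume of the cutoff spheres, estimated by seeded Monte Carlo
    integration on a subsample of frames).
    """
    q = np.asarray(q_series, dtype=float)
    if len(q) != traj.n_frames:
        raise ValueError("q_series must be aligned with the trajectory")
    rng = np.random.default_rng(seed)
    rho = traj.n_ions / traj.box_edge**3

    def state_excess(mask: np.ndarray) -> float:
        frames = np.flatnonzero(mask)
        if len(frames) == 0:
            return float("nan")
        near = []
        vol = []
        sub = frames[:: max(1, len(frames) // 50)]
        for f in frames:
            near.append((_ion_phosphate_dists(traj, f) < cutoff).any(axis=1).sum())
        for f in sub:
            pts = rng.uniform(0.0, traj.box_edge, size=(mc_samples, 3))
            p = traj.rna[f, 0::3]
            d = np.linalg.norm(_min_image(pts[:, None, :] - p[None, :, :],
                                          traj.box_edge), axis=2)
            frac = np.mean((d < cutoff).any(axis=1))
            vol.append(frac * traj.box_edge**3)
        return float(np.mean(near) - rho * np.mean(vol))

    return {
        "folded": state_excess(q >= q_folded),
        "unfolded": state_excess(q < q_unfolded),
    }
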
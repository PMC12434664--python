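"""Energy-landscape visualization: Q_w dissimilarity, force-scheme
projection, density estimation, region handling, and local signatures.

The pipeline maps every pair of conformations to a dissimilarity

    delta_kl = 1 - (1/N_p) sum_{i<j} exp(-(r_ij^k - r_ij^l)^2 / (2 sigma_ij^2)),

a Gaussian-weighted comparison of internal bead-bead distances in which
the width grows slowly with sequence separation,
sigma_ij = sigma0 * |n_i - n_j|^eps (sigma0 = 3 A, eps = 0.15).  The n x n
dissimilarity matrix is then embedded in 2D with the force-scheme
algorithm, and the embedded point cloud is summarized by a Gaussian KDE
and by Local Conformational Signatures (the dRMSD centroid of a selected
region and its nearest neighbors).

Intra-residue bead pairs are excluded from the pair set: their sequence
separation is zero, which would make sigma_ij vanish and the Gaussian
singular.  N_p is the size of the included set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import gaussian_kde

__all__ = [
    "sigma_ij",
    "qw_dissimilarity",
    "dissimilarity_matrix",
    "DissimilarityMatrix",
    "Embedding",
    "Region",
    "LocalSignature",
    "force_scheme",
    "kde_density",
    "region_from_polygon",
    "region_from_density",
    "local_signature",
    "drmsd_matrix",
]

SIGMA0_DEFAULT = 3.0
EPS_DEFAULT = 0.15


def sigma_ij(delta_n: np.ndarray | float, sigma0: float = SIGMA0_DEFAULT,
             eps: float = EPS_DEFAULT) -> np.ndarray | float:
    """Sequence-distance-dependent Gaussian width sigma0 * |dn|^eps (A)."""
    return sigma0 * np.abs(delta_n) ** eps


def _pair_set(bead_residues: np.ndarray):
    """Indices and widths of all bead pairs on different residues."""
    res = np.asarray(bead_residues)
    n = len(res)
    ii, jj = np.triu_indices(n, k=1)
    keep = res[ii] != res[jj]
    ii, jj = ii[keep], jj[keep]
    return ii, jj, sigma_ij(res[ii] - res[jj])


def _pair_distances(frames: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                    ) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return np.linalg.norm(frames[:, ii] - frames[:, jj], axis=-1)


def qw_dissimilarity(
    frame_k: np.ndarray,
    frame_l: np.ndarray,
    bead_residues: np.ndarray,
    sigma0: float = SIGMA0_DEFAULT,
    eps: float = EPS_DEFAULT,
) -> float:
    """Dissimilarity delta = 1 - q_w between two conformations.

    Zero for identical conformations, approaching one for structurally
    unrelated ones; depends only on internal distances, hence invariant
    under rigid motion of either frame.
    """
    fk = np.asarray(frame_k, dtype=float)
    fl = np.asarray(frame_l, dtype=float)
    if fk.shape != fl.shape:
        raise ValueError("frames must have equal bead counts")
    res = np.asarray(bead_residues)
    ii, jj, _ = _pair_set(res)
    if len(ii) == 0:
        raise ValueError("empty pair set: need beads on at least two residues")
    sig = sigma_ij(res[ii] - res[jj], sigma0, eps)
    dk = np.linalg.norm(fk[ii] - fk[jj], axis=-1)
    dl = np.linalg.norm(fl[ii] - fl[jj], axis=-1)
    qw = float(np.mean(np.exp(-((dk - dl) ** 2) / (2.0 * sig**2))))
    return 1.0 - qw


@dataclass
class DissimilarityMatrix:
    """Symmetric all-pairs conformational dissimilarity."""

    values: np.ndarray
    sigma0: float = SIGMA0_DEFAULT
    eps: float = EPS_DEFAULT
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")
        self.values = v
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(v))

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self) -> str:
        rows = ["\t".join(f"{x:.6f}" for x in row) for row in self.values]
        return "\n".join(rows) + "\n"

    def save(self, path) -> None:
        """Binary export (.npz: values, sigma0, eps, frame_ids)."""
        np.savez(path, values=self.values, sigma0=self.sigma0, eps=self.eps,
                 frame_ids=self.frame_ids)

    @classmethod
    def load(cls, path) -> "DissimilarityMatrix":
        with np.load(path) as data:
            return cls(values=data["values"], sigma0=float(data["sigma0"]),
                       eps=float(data["eps"]), frame_ids=data["frame_ids"])


def dissimilarity_matrix(
    frames: np.ndarray,
    bead_residues: np.ndarray,
    sigma0: float = SIGMA0_DEFAULT,
    eps: float = EPS_DEFAULT,
) -> DissimilarityMatrix:
    """All-pairs delta matrix over a stack of frames.

    Equivalent to calling :func:`qw_dissimilarity` on every pair; computed
    blockwise from precomputed internal distances, so the result is
    independent of evaluation order.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("frames must have shape (n_frames, n_beads, 3)")
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames")
    res = np.asarray(bead_residues)
    if frames.shape[1] != len(res):
        raise ValueError("bead count inconsistent with bead_residues")

    ii, jj, _ = _pair_set(res)
    if len(ii) == 0:
        raise ValueError("empty pair set")
    sig2 = 2.0 * sigma_ij(res[ii] - res[jj], sigma0, eps) ** 2
    D = _pair_distances(frames, ii, jj)      # (n_frames, n_pairs)

    n = len(frames)
    out = np.zeros((n, n))
    for k in range(n - 1):
        diff = D[k + 1:] - D[k]
        qw = np.mean(np.exp(-(diff**2) / sig2), axis=1)
        out[k, k + 1:] = 1.0 - qw
        out[k + 1:, k] = out[k, k + 1:]
    np.clip(out, 0.0, 1.0, out=out)
    return DissimilarityMatrix(values=out, sigma0=sigma0, eps=eps)


@dataclass
class Embedding:
    """2D projection of an ensemble with optional per-point density."""

    points: np.ndarray                    # (n, 2)
    stress: float
    stress_history: np.ndarray
    n_iter: int
    seed: int
    density: np.ndarray | None = None
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite embedding coordinates")
        if self.frame_ids is None:
            self.frame_ids = np.arange(len(self.points))

    def __len__(self) -> int:
        return len(self.points)

    def to_tsv(self, q: np.ndarray | None = None,
               rmsd: np.ndarray | None = None) -> str:
        n = len(self)
        dens = self.density if self.density is not None else np.full(n, np.nan)
        qv = q if q is not None else np.full(n, np.nan)
        rv = rmsd if rmsd is not None else np.full(n, np.nan)
        lines = ["frame_id\tx\ty\tdensity\tQ\trmsd"]
        for i in range(n):
            lines.append(
                f"{self.frame_ids[i]}\t{self.points[i, 0]:.6f}\t"
                f"{self.points[i, 1]:.6f}\t{dens[i]:.6g}\t{qv[i]:.4f}\t{rv[i]:.4f}"
            )
        return "\n".join(lines) + "\n"


def _normalized_stress(delta: np.ndarray, points: np.ndarray) -> float:
    d = squareform(pdist(points))
    iu = np.triu_indices(len(points), k=1)
    num = float(np.sum((delta[iu] - d[iu]) ** 2))
    den = float(np.sum(delta[iu] ** 2))
    return num / den if den > 0 else 0.0


def force_scheme(
    D: DissimilarityMatrix,
    n_iter: int = 100,
    step_fraction: float = 1.0 / 8.0,
    seed: int = 0,
) -> Embedding:
    """Force-scheme multidimensional projection onto the plane.

    Points start at seeded random positions; in each iteration every point
    serves once as a pivot (shuffled order) and every other point moves
    along the pivot-to-point direction by ``step_fraction`` times the
    difference between the target dissimilarity and the current embedded
    distance.  Records the normalized stress sum (delta - d)^2 / sum
    delta^2 after every iteration.  Deterministic given the seed.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    delta = np.asarray(D.values, dtype=float)
    dmax = delta.max()
    if dmax > 0:                            # min-max scale to [0, 1]
        delta = delta / dmax
    n = len(delta)
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, 2))

    history = np.empty(n_iter)
    for it in range(n_iter):
        for p in rng.permutation(n):
            v = X - X[p]
            d = np.linalg.norm(v, axis=1)
            d[p] = 1.0                       # pivot does not move
            move = step_fraction * (delta[p] - d)
            move[p] = 0.0
            X += (move / np.maximum(d, 1e-9))[:, None] * v
        history[it] = _normalized_stress(delta, X)

    return Embedding(
        points=X,
        stress=float(history[-1]),
        stress_history=history,
        n_iter=n_iter,
        seed=seed,
        frame_ids=np.asarray(D.frame_ids),
    )


def kde_density(E: Embedding, bandwidth_rule: str | float = "scott") -> np.ndarray:
    """Gaussian KDE of the embedded points, evaluated at each point.

    Uses Scott's rule by default; stores the densities on the embedding
    and returns them.  Degenerate (all-identical) point sets are rejected.
    """
    pts = E.points
    if len(pts) < 2:
        raise ValueError("need at least two points for a KDE")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate point set: all points identical")
    try:
        kde = gaussian_kde(pts.T, bw_method=bandwidth_rule)
        dens = kde(pts.T)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"degenerate point set: {err}") from err
    E.density = dens
    return dens


@dataclass
class Region:
    """A subset of embedded points (by point index) with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) == 0:
            raise ValueError("region must be nonempty")

    def __len__(self) -> int:
        return len(self.indices)


def region_from_polygon(E: Embedding, vertices: np.ndarray, label: str = "") -> Region:
    """Points inside a polygon drawn on the embedding (the programmatic
    equivalent of manually circling a basin)."""
    from matplotlib.path import Path

    inside = Path(np.asarray(vertices, dtype=float)).contains_points(E.points)
    return Region(indices=np.flatnonzero(inside), label=label)


def write_polygon(vertices: np.ndarray) -> str:
    """Region polygon as TSV of x/y vertices."""
    lines = ["x\ty"]
    lines += [f"{x:.6f}\t{y:.6f}" for x, y in np.asarray(vertices, dtype=float)]
    return "\n".join(lines) + "\n"


def read_polygon(text: str) -> np.ndarray:
    rows = [
        line.split("\t") for line in text.strip().splitlines()[1:] if line
    ]
    return np.array(rows, dtype=float)


def region_from_density(E: Embedding, quantile: float = 0.75,
                        label: str = "") -> Region:
    """Points whose KDE density exceeds the given quantile (basin cores)."""
    if E.density is None:
        kde_density(E)
    thresh = np.quantile(E.density, quantile)
    return Region(indices=np.flatnonzero(E.density >= thresh), label=label)


def drmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """All-pairs distance-RMSD over a stack of frames."""
    frames = np.asarray(frames, dtype=float)
    P = np.stack([pdist(f) for f in frames])
    n = len(frames)
    out = np.zeros((n, n))
    for k in range(n - 1):
        out[k, k + 1:] = np.sqrt(np.mean((P[k + 1:] - P[k]) ** 2, axis=1))
        out[k + 1:, k] = out[k, k + 1:]
    return out


@dataclass
class LocalSignature:
    """Representative conformation of a region: the dRMSD centroid."""

    centroid_index: int                   # global frame index
    neighbor_indices: np.ndarray          # m nearest by dRMSD, global indices
    mean_drmsd: float


def local_signature(region: Region, frames: np.ndarray,
                    n_neighbors: int = 5) -> LocalSignature:
    """Centroid frame of a region and its nearest dRMSD neighbors.

    The centroid minimizes the mean dRMSD to all other frames of the
    region; ties break toward the lowest frame index.  A single-frame
    region is its own centroid with no neighbors.
    """
    frames = np.asarray(frames, dtype=float)
    sub = frames[region.indices]
    if len(sub) == 1:
        return LocalSignature(int(region.indices[0]), np.array([], dtype=int), 0.0)
    M = drmsd_matrix(sub)
    mean_d = M.sum(axis=1) / (len(sub) - 1)
    c = int(np.argmin(mean_d))            # argmin takes the first minimum
    order = np.argsort(M[c], kind="stable")
    neigh = [i for i in order if i != c][:n_neighbors]
    return LocalSignature(
        centroid_index=int(region.indices[c]),
        neighbor_indices=region.indices[np.array(neigh, dtype=int)],
        mean_drmsd=float(mean_d[c]),
    )
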
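"""Free-energy reconstruction from umbrella windows (WHAM) and Q-state
classification.

Given histograms of the reaction coordinate collected under harmonic
biases, the weighted histogram analysis method solves the self-consistent
equations

    P(b) = sum_w n_w(b) / sum_w N_w exp(f_w - u_w(b))
    exp(-f_w) = sum_b P(b) exp(-u_w(b))

for the unbiased distribution P and per-window free-energy offsets f_w
(all energies in k_B T).  The profile is F(Q) = -ln P(Q), shifted so its
minimum is zero.

Folding states along Q follow the conventional thresholds: unfolded below
0.4, partially open in [0.4, 0.55), partially folded in [0.55, 0.85),
folded at or above 0.85 — boundaries belong to the higher state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cg_sim import UmbrellaWindow
from .trajectory import Trajectory

__all__ = [
    "FreeEnergyProfile",
    "StateLabel",
    "wham_solve",
    "classify_state",
    "umbrella_histograms",
    "STATE_THRESHOLDS",
]

#: Q thresholds separating unfolded / partially open / partially folded /
#: folded ensembles.
STATE_THRESHOLDS = (0.4, 0.55, 0.85)


@dataclass
class FreeEnergyProfile:
    """F(Q) on a grid, in k_B T, with solver diagnostics."""

    q: np.ndarray                       # bin centers
    f: np.ndarray                       # free energy, min-shifted to 0
    offsets: np.ndarray                 # converged per-window f_w
    residual: float
    n_iter: int
    counts: np.ndarray                  # total samples per bin
    components: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        finite = np.isfinite(self.f)
        if finite.any() and abs(float(np.nanmin(self.f[finite]))) > 1e-9:
            raise ValueError("profile must be shifted to min F = 0")

    def barrier_height(self) -> float:
        """Highest finite F between the two outermost local minima."""
        finite = np.flatnonzero(np.isfinite(self.f))
        if len(finite) < 3:
            return float("nan")
        f = self.f[finite]
        minima = [k for k in range(1, len(f) - 1)
                  if f[k] <= f[k - 1] and f[k] <= f[k + 1]]
        if len(minima) < 2:
            return float("nan")
        lo, hi = minima[0], minima[-1]
        return float(f[lo:hi + 1].max() - min(f[lo], f[hi]))

    def to_tsv(self) -> str:
        lines = ["Q\tF_kBT\tcounts"]
        for q, f, c in zip(self.q, self.f, self.counts):
            fs = "inf" if not np.isfinite(f) else f"{f:.6f}"
            lines.append(f"{q:.4f}\t{fs}\t{int(c)}")
        return "\n".join(lines) + "\n"


def _overlap_components(hists: np.ndarray) -> list[list[int]]:
    """Connected components of windows linked by shared occupied bins."""
    n_w = len(hists)
    occupied = hists > 0
    parent = list(range(n_w))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(n_w):
        for b in range(a + 1, n_w):
            if np.any(occupied[a] & occupied[b]):
                parent[find(a)] = find(b)
    groups: dict[int, list[int]] = {}
    for w in range(n_w):
        groups.setdefault(find(w), []).append(w)
    return list(groups.values())


def wham_solve(
    window_histograms: np.ndarray,
    window_biases: np.ndarray,
    temperature: float = 1.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    q_grid: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """Self-consistent WHAM solution of the unbiased profile.

    ``window_histograms``: (n_windows, n_bins) sample counts;
    ``window_biases``: (n_windows, n_bins) bias energy at each bin center,
    in the same energy units as ``temperature`` (u = U/(k_B T) is formed
    internally).  Adding a constant to any window's bias leaves the
    profile unchanged.  Windows whose histograms share no occupied bins
    are reported as disconnected components with a warning.
    """
    hists = np.asarray(window_histograms, dtype=float)
    biases = np.asarray(window_biases, dtype=float)
    if hists.ndim != 2 or hists.shape != biases.shape:
        raise ValueError("histograms and biases must share the (windows, bins) shape")
    if hists.shape[0] < 1:
        raise ValueError("need at least one window")

    n_w, n_bins = hists.shape
    if q_grid is None:
        q_grid = (np.arange(n_bins) + 0.5) / n_bins
    components = _overlap_components(hists)
    if len(components) > 1:
        warnings.warn(
            f"umbrella windows form {len(components)} disconnected groups; "
            "relative free energies between groups are undefined",
            RuntimeWarning,
        )

    u = biases / temperature
    u = u - u.min(axis=1, keepdims=True)      # numerical conditioning only
    N_w = hists.sum(axis=1)
    total = hists.sum(axis=0)
    f_w = np.zeros(n_w)

    residual = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # P(b) = total(b) / sum_w N_w exp(f_w - u_w(b))
        denom = np.einsum("w,wb->b", N_w, np.exp(f_w[:, None] - u))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(total > 0, total / denom, 0.0)
        z = (p[None, :] * np.exp(-u)).sum(axis=1)
        f_new = -np.log(np.maximum(z, 1e-300))
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f_w)))
        f_w = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )

    denom = np.einsum("w,wb->b", N_w, np.exp(f_w[:, None] - u))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(total > 0, total / denom, 0.0)
        F = -np.log(p)
    F[~np.isfinite(F)] = np.inf
    F -= F[np.isfinite(F)].min()

    return FreeEnergyProfile(
        q=np.asarray(q_grid, dtype=float),
        f=F,
        offsets=f_w,
        residual=residual,
        n_iter=it,
        counts=total,
        components=components,
    )


def umbrella_histograms(
    trajs: list[Trajectory],
    windows: list[UmbrellaWindow],
    n_bins: int = 50,
    burn_in: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Histograms and bias tables for WHAM from umbrella trajectories.

    Frames are histogrammed on the smooth Q recorded during the biased
    runs (the coordinate the bias actually acts on); the bias energy at
    each bin center is 0.5 k (Q - q0)^2 of the matching window.  Returns
    (histograms, biases, bin centers).
    """
    if len(trajs) != len(windows):
        raise ValueError("one window spec per trajectory required")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    hists = np.zeros((len(trajs), n_bins))
    biases = np.zeros((len(trajs), n_bins))
    for w, (traj, win) in enumerate(zip(trajs, windows)):
        if traj.q_smooth is None:
            raise ValueError(f"trajectory {w} carries no recorded Q_smooth")
        qs = traj.q_smooth[burn_in:]
        hists[w] = np.histogram(qs, bins=edges)[0]
        biases[w] = 0.5 * win.k_q * (centers - win.q0) ** 2
    return hists, biases, centers


@dataclass(frozen=True)
class StateLabel:
    """Folding-state assignment of a Q value."""

    label: str                          # one of U, PO, PF, F
    thresholds: tuple[float, float, float] = STATE_THRESHOLDS

    def __str__(self) -> str:
        return self.label


def classify_state(q: float,
                   thresholds: tuple[float, float, float] = STATE_THRESHOLDS
                   ) -> StateLabel:
    """Assign U / PO / PF / F by Q; boundary values go to the higher state."""
    q1, q2, q3 = thresholds
    if not 0.0 < q1 < q2 < q3 < 1.0:
        raise ValueError("thresholds must satisfy 0 < q1 < q2 < q3 < 1")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"Q must lie in [0, 1], got {q}")
    if q < q1:
        label = "U"
    elif q < q2:
        label = "PO"
    elif q < q3:
        label = "PF"
    else:
        label = "F"
    return StateLabel(label=label, thresholds=thresholds)
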
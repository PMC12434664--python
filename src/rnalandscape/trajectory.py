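"""Trajectory container and on-disk formats.

A trajectory is a stack of frames, each holding the RNA bead coordinates,
the explicit ion coordinates, the (cubic) box edge, and — for biased runs —
the smooth collective variable and bias energy.  Frames are stored
in memory as float64 arrays; the binary file format uses a fixed layout
(int64 step index followed by float32 coordinate blocks) and a JSON header,
with an optional plain-text Q/bias log alongside.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trajectory", "write_trajectory", "read_trajectory"]

_MAGIC = b"RNLTRJ1\n"


@dataclass
class Trajectory:
    """Time series of coarse-grained frames with explicit ions."""

    rna: np.ndarray                  # (n_frames, n_beads, 3) Angstrom
    ions: np.ndarray                 # (n_frames, n_ions, 3) Angstrom
    box_edge: float                  # Angstrom
    steps: np.ndarray                # (n_frames,) integrator step index
    q_smooth: np.ndarray | None = None
    bias_energy: np.ndarray | None = None
    window_id: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rna = np.asarray(self.rna, dtype=float)
        self.ions = np.asarray(self.ions, dtype=float)
        self.steps = np.asarray(self.steps, dtype=np.int64)
        if self.rna.ndim != 3 or self.rna.shape[2] != 3:
            raise ValueError("rna must have shape (n_frames, n_beads, 3)")
        if self.ions.ndim != 3:
            self.ions = self.ions.reshape(self.rna.shape[0], -1, 3)
        if self.ions.shape[0] != self.rna.shape[0]:
            raise ValueError("ion frames must match rna frames")
        if len(self.steps) != self.rna.shape[0]:
            raise ValueError("steps must match frame count")
        if not (np.all(np.isfinite(self.rna)) and np.all(np.isfinite(self.ions))):
            raise ValueError("non-finite coordinates in trajectory")

    @property
    def n_frames(self) -> int:
        return self.rna.shape[0]

    @property
    def n_beads(self) -> int:
        return self.rna.shape[1]

    @property
    def n_ions(self) -> int:
        return self.ions.shape[1]

    def __len__(self) -> int:
        return self.n_frames

    def concat(self, other: "Trajectory") -> "Trajectory":
        if other.n_beads != self.n_beads or other.n_ions != self.n_ions:
            raise ValueError("incompatible trajectories")
        opt = {}
        for name in ("q_smooth", "bias_energy"):
            a, b = getattr(self, name), getattr(other, name)
            opt[name] = None if a is None or b is None else np.concatenate([a, b])
        return Trajectory(
            rna=np.concatenate([self.rna, other.rna]),
            ions=np.concatenate([self.ions, other.ions]),
            box_edge=self.box_edge,
            steps=np.concatenate([self.steps, other.steps]),
            window_id=self.window_id,
            meta=dict(self.meta),
            **opt,
        )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write the documented binary layout: JSON header, then per frame an
    int64 step and float32 RNA / ion coordinate blocks."""
    path = Path(path)
    header = {
        "n_frames": traj.n_frames,
        "n_beads": traj.n_beads,
        "n_ions": traj.n_ions,
        "box_edge": traj.box_edge,
        "window_id": traj.window_id,
        "meta": traj.meta,
    }
    hjson = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<q", len(hjson)))
        fh.write(hjson)
        for f in range(traj.n_frames):
            fh.write(struct.pack("<q", int(traj.steps[f])))
            fh.write(traj.rna[f].astype("<f4").tobytes())
            fh.write(traj.ions[f].astype("<f4").tobytes())


def read_trajectory(path: str | Path) -> Trajectory:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError(f"{path}: not a trajectory file")
        (hlen,) = struct.unpack("<q", fh.read(8))
        header = json.loads(fh.read(hlen))
        nf, nb, ni = header["n_frames"], header["n_beads"], header["n_ions"]
        steps = np.empty(nf, dtype=np.int64)
        rna = np.empty((nf, nb, 3))
        ions = np.empty((nf, ni, 3))
        for f in range(nf):
            (steps[f],) = struct.unpack("<q", fh.read(8))
            rna[f] = np.frombuffer(fh.read(nb * 12), dtype="<f4").reshape(nb, 3)
            ions[f] = np.frombuffer(fh.read(ni * 12), dtype="<f4").reshape(ni, 3)
    return Trajectory(
        rna=rna,
        ions=ions,
        box_edge=header["box_edge"],
        steps=steps,
        window_id=header["window_id"],
        meta=header.get("meta", {}),
    )


def write_q_log(
    path: str | Path,
    steps: np.ndarray,
    q_hard: np.ndarray,
    q_smooth: np.ndarray | None = None,
    bias_energy: np.ndarray | None = None,
    window_id: int | None = None,
) -> None:
    """Plain-text per-frame log: step, Q_hard, Q_smooth, bias_energy, window."""
    n = len(steps)
    qs = q_smooth if q_smooth is not None else [float("nan")] * n
    be = bias_energy if bias_energy is not None else [float("nan")] * n
    wid = window_id if window_id is not None else -1
    with open(path, "w") as fh:
        fh.write("step\tQ_hard\tQ_smooth\tbias_energy\twindow_id\n")
        for s, qh, q, b in zip(steps, q_hard, qs, be):
            fh.write(f"{int(s)}\t{qh:.6f}\t{q:.6f}\t{b:.6f}\t{wid}\n")
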
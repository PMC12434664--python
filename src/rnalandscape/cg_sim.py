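"""Desk-scale coarse-grained RNA simulator with explicit divalent ions.

This is a deliberately small surrogate for the production simulations that
folding-landscape studies are built on: a three-bead-per-nucleotide chain
evolved by Langevin dynamics under a structure-based (Go-like) potential —
harmonic bonds and angles along the bead chain, Gaussian wells at the
native contact distances, purely repulsive excluded volume elsewhere — plus
Debye-Hueckel electrostatics between charged sites.  Implicit monovalent
salt enters only through the fixed Debye length; divalent cations are
explicit point charges with a hydrated-ion excluded-volume radius,
diffusing in a periodic cubic box.

Reduced units: energies in units of the contact well depth scale
(epsilon_0 = 1), k_B = 1, bead mass 1, lengths in Angstrom.  The folding
temperature of the surrogate is calibrated by a temperature scan, not
taken from any production-model scale.

A fast ``morph_ensemble`` generator produces unfolded-to-folded fixture
trajectories (with optionally scripted "bridging" ions) without running
dynamics, for analysis-stage tests with designed ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .rna_model import CGStructure, NativeContactSet
from .trajectory import Trajectory
from .datasets import extended_chain

__all__ = [
    "SimConfig",
    "UmbrellaWindow",
    "BridgeSpec",
    "Topology",
    "build_topology",
    "run_langevin",
    "umbrella_run",
    "morph_ensemble",
    "smooth_q",
    "dh_pair_energy",
    "debye_length_from_conc",
]


def debye_length_from_conc(monovalent_mM: float) -> float:
    """Debye screening length (A) of 1:1 salt at 298 K in water."""
    return 3.04 / np.sqrt(monovalent_mM / 1000.0)


def dh_pair_energy(q1: float, q2: float, r: float, debye_length: float,
                   coulomb_strength: float = 1.0) -> float:
    """Screened-Coulomb pair energy  C * q1 q2 * exp(-r/lambda_D) / r."""
    return coulomb_strength * q1 * q2 * np.exp(-r / debye_length) / r


@dataclass
class SimConfig:
    """Simulation parameters in reduced units (lengths in A, box in nm).

    Defaults follow the surrogate's own desk-scale calibration: a 15 nm
    box (a production-scale 75 nm box is accepted via ``box_nm``), unit
    bead mass and drag, timestep 0.001 tau.
    """

    timestep: float = 0.001
    n_steps: int = 10_000
    save_interval: int = 100
    temperature: float = 1.0
    friction: float = 1.0
    bead_mass: float = 1.0
    box_nm: float = 15.0
    n_mg: int = 0
    phosphate_charge: float = -1.0
    mg_charge: float = 2.0
    debye_length: float = 10.0          # A; ~100 mM monovalent salt
    coulomb_strength: float = 7.0       # A*epsilon_0; Bjerrum-like prefactor
    ion_radius: float = 3.5             # hydrated divalent ion EV radius, A
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_mg < 0:
            raise ValueError("n_mg must be non-negative")
        if self.box_nm <= 0:
            raise ValueError("box edge must be positive")

    @property
    def box_edge(self) -> float:
        """Box edge in Angstrom."""
        return self.box_nm * 10.0


@dataclass
class UmbrellaWindow:
    """One harmonic umbrella along Q: bias = 0.5 k (Q_smooth - q0)^2."""

    q0: float
    k_q: float
    window_id: int = 0
    n_steps: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.q0 <= 1.0:
            raise ValueError("q0 must lie in [0, 1]")
        if self.k_q < 0:
            raise ValueError("k_q must be non-negative")


@dataclass
class BridgeSpec:
    """Scripted persistent ion bridging two phosphates in a fraction of frames."""

    res_i: int = 28
    res_j: int = 38
    fraction: float = 0.7
    jitter: float = 0.15


@dataclass
class Topology:
    """Interaction lists of the surrogate potential (flat index arrays)."""

    n_beads: int
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    k_bond: float
    ang_i: np.ndarray
    ang_j: np.ndarray
    ang_k: np.ndarray
    theta0: np.ndarray
    k_angle: float
    con_i: np.ndarray
    con_j: np.ndarray
    con_r0: np.ndarray
    eps_contact: float
    contact_width: float
    ev_i: np.ndarray
    ev_j: np.ndarray
    ev_sigma: np.ndarray
    charges: np.ndarray                 # per bead; P beads carry the charge
    pp_i: np.ndarray                    # charged (P-P) pair list
    pp_j: np.ndarray
    contacts: NativeContactSet = field(repr=False, default=None)

    @property
    def n_bonds(self) -> int:
        return len(self.bond_i)

    @property
    def n_angles(self) -> int:
        return len(self.ang_i)


def build_topology(
    cg: CGStructure,
    nc: NativeContactSet,
    cfg: SimConfig,
    k_bond: float = 100.0,
    k_angle: float = 10.0,
    eps_contact: float = 2.0,
    contact_width: float = 1.0,
    ev_sigma: float = 4.0,
) -> Topology:
    """Assemble the structure-based potential for a native conformation.

    The bead chain is treated as linear in bead order (P,S,B per residue),
    giving 3N-1 bonds and 3N-2 angles.  Native contacts become Gaussian
    wells of depth ``eps_contact`` at their native distance; every other
    non-bonded bead pair is purely repulsive, with a per-pair diameter
    capped below the native separation so the native structure is an
    exact minimum of the unscreened potential.
    """

    x = cg.xyz
    n = cg.n_beads
    if len(nc.pairs) and nc.pairs.max() >= n:
        raise ValueError("contact references a bead index outside the structure")
    if len(nc.native_distances) and cfg.box_edge <= 2.0 * nc.native_distances.max():
        raise ValueError("box edge must exceed twice the largest native distance")

    bi = np.arange(n - 1)
    bj = bi + 1
    br0 = np.linalg.norm(x[bj] - x[bi], axis=1)

    ai = np.arange(n - 2)
    aj = ai + 1
    ak = ai + 2
    u = x[ai] - x[aj]
    v = x[ak] - x[aj]
    cosang = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    theta0 = np.arccos(np.clip(cosang, -1.0, 1.0))

    # Excluded-volume pair list: all i<j except bonded (|i-j|<=2, which the
    # bond/angle terms govern) and native-contact pairs.
    ii, jj = np.triu_indices(n, k=3)
    contact_keys = set(map(tuple, nc.pairs))
    keep = np.array([(a, b) not in contact_keys for a, b in zip(ii, jj)])
    ev_i, ev_j = ii[keep], jj[keep]
    r_nat = np.linalg.norm(x[ev_j] - x[ev_i], axis=1)
    sigma = np.minimum(ev_sigma, 0.8 * r_nat)

    charges = np.zeros(n)
    charges[0::3] = cfg.phosphate_charge
    p_idx = np.arange(0, n, 3)
    pi, pj = np.triu_indices(len(p_idx), k=1)

    return Topology(
        n_beads=n,
        bond_i=bi, bond_j=bj, bond_r0=br0, k_bond=k_bond,
        ang_i=ai, ang_j=aj, ang_k=ak, theta0=theta0, k_angle=k_angle,
        con_i=nc.pairs[:, 0].copy(), con_j=nc.pairs[:, 1].copy(),
        con_r0=nc.native_distances.copy(),
        eps_contact=eps_contact, contact_width=contact_width,
        ev_i=ev_i, ev_j=ev_j, ev_sigma=sigma,
        charges=charges, pp_i=p_idx[pi], pp_j=p_idx[pj],
        contacts=nc,
    )


# --------------------------------------------------------------------------
# Energies and forces
# --------------------------------------------------------------------------

def _accumulate(F: np.ndarray, idx_i: np.ndarray, idx_j: np.ndarray,
                fvec: np.ndarray) -> None:
    """Add +fvec to rows idx_i and -fvec to rows idx_j of F."""
    np.add.at(F, idx_i, fvec)
    np.add.at(F, idx_j, -fvec)


def _wca(r: np.ndarray, sigma: np.ndarray | float, eps: float = 1.0):
    """Purely repulsive (WCA) energy and dV/dr, zero beyond 2^(1/6) sigma."""
    rc = 2.0 ** (1.0 / 6.0) * sigma
    active = r < rc
    sr6 = np.where(active, (sigma / np.maximum(r, 1e-9)) ** 6, 0.0)
    e = np.where(active, 4.0 * eps * (sr6**2 - sr6) + eps, 0.0)
    dvdr = np.where(active, 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6)
                    / np.maximum(r, 1e-9), 0.0)
    return e, dvdr


def energy_forces(
    x_rna: np.ndarray,
    x_ions: np.ndarray,
    top: Topology,
    cfg: SimConfig,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Total potential energy and forces on beads and ions.

    Minimum-image displacements are used for every pair involving an ion
    and for screened electrostatics; the RNA itself is kept whole.
    """

    box = cfg.box_edge
    F = np.zeros_like(x_rna)
    Fi = np.zeros_like(x_ions) if len(x_ions) else np.zeros((0, 3))
    E = 0.0

    # bonds
    d = x_rna[top.bond_j] - x_rna[top.bond_i]
    r = np.linalg.norm(d, axis=1)
    dr = r - top.bond_r0
    E += 0.5 * top.k_bond * float(dr @ dr)
    fvec = (top.k_bond * dr / r)[:, None] * d
    _accumulate(F, top.bond_i, top.bond_j, fvec)

    # angles
    if len(top.ang_i):
        u = x_rna[top.ang_i] - x_rna[top.ang_j]
        v = x_rna[top.ang_k] - x_rna[top.ang_j]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
        th = np.arccos(c)
        dth = th - top.theta0
        E += 0.5 * top.k_angle * float(dth @ dth)
        pref = top.k_angle * dth / s
        gi = (pref / nu)[:, None] * (v / nv[:, None] - (c / nu)[:, None] * u)
        gk = (pref / nv)[:, None] * (u / nu[:, None] - (c / nv)[:, None] * v)
        np.add.at(F, top.ang_i, gi)
        np.add.at(F, top.ang_k, gk)
        np.add.at(F, top.ang_j, -(gi + gk))

    # native-contact Gaussian wells with a hard core
    if len(top.con_i):
        d = x_rna[top.con_j] - x_rna[top.con_i]
        r = np.linalg.norm(d, axis=1)
        w2 = top.contact_width**2
        s_core = 0.8 * top.con_r0
        g = np.exp(-((r - top.con_r0) ** 2) / (2.0 * w2))
        sr12 = (s_core / r) ** 12
        E += top.eps_contact * float(np.sum((1.0 + sr12) * (1.0 - g) - 1.0))
        dvdr = top.eps_contact * (
            -12.0 * sr12 / r * (1.0 - g)
            + (1.0 + sr12) * g * (r - top.con_r0) / w2
        )
        fvec = (dvdr / r)[:, None] * d
        _accumulate(F, top.con_i, top.con_j, fvec)

    # excluded volume between non-bonded, non-contact bead pairs
    if len(top.ev_i):
        d = x_rna[top.ev_j] - x_rna[top.ev_i]
        r = np.linalg.norm(d, axis=1)
        e, dvdr = _wca(r, top.ev_sigma)
        E += float(e.sum())
        fvec = (dvdr / r)[:, None] * d
        _accumulate(F, top.ev_i, top.ev_j, fvec)

    # Debye-Hueckel electrostatics
    lam = cfg.debye_length
    rc_dh = min(4.0 * lam, box / 2.0)
    C = cfg.coulomb_strength

    def dh(qq: np.ndarray, d: np.ndarray, r: np.ndarray):
        active = r < rc_dh
        rr = np.maximum(r, 1e-9)
        e = np.where(active, C * qq * np.exp(-rr / lam) / rr, 0.0)
        dvdr = np.where(active, -e * (1.0 / lam + 1.0 / rr), 0.0)
        return e, dvdr

    if len(top.pp_i):
        qq = top.charges[top.pp_i] * top.charges[top.pp_j]
        d = x_rna[top.pp_j] - x_rna[top.pp_i]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=1)
        e, dvdr = dh(qq, d, r)
        E += float(e.sum())
        fvec = (dvdr / np.maximum(r, 1e-9))[:, None] * d
        _accumulate(F, top.pp_i, top.pp_j, fvec)

    n_ion = len(x_ions)
    if n_ion:
        # ion - RNA
        d = x_rna[None, :, :] - x_ions[:, None, :]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d, axis=2)
        e_ev, dvdr_ev = _wca(r, cfg.ion_radius + 1.5)
        qq = cfg.mg_charge * top.charges[None, :]
        e_dh, dvdr_dh = dh(qq, d, r)
        E += float(e_ev.sum() + e_dh.sum())
        coef = -(dvdr_ev + dvdr_dh) / np.maximum(r, 1e-9)
        fvec = coef[:, :, None] * d          # force on RNA beads
        F += fvec.sum(axis=0)
        Fi -= fvec.sum(axis=1)

        if n_ion > 1:
            ii, jj = np.triu_indices(n_ion, k=1)
            d = x_ions[jj] - x_ions[ii]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d, axis=1)
            e_ev, dvdr_ev = _wca(r, 2.0 * cfg.ion_radius)
            e_dh, dvdr_dh = dh(np.full(len(r), cfg.mg_charge**2), d, r)
            E += float(e_ev.sum() + e_dh.sum())
            fvec = ((dvdr_ev + dvdr_dh) / np.maximum(r, 1e-9))[:, None] * d
            _accumulate(Fi, ii, jj, fvec)

    return E, F, Fi


# --------------------------------------------------------------------------
# Smooth (differentiable) fraction of native contacts
# --------------------------------------------------------------------------

#: Sigmoid steepness (1/A) and tolerance factor of the smooth Q used for biasing.
SMOOTH_Q_BETA = 5.0
SMOOTH_Q_LAMBDA = 1.2


def smooth_q(x_rna: np.ndarray, top: Topology,
             beta: float = SMOOTH_Q_BETA, lam: float = SMOOTH_Q_LAMBDA):
    """Differentiable Q and its gradient with respect to bead coordinates.

    Q_s = (1/N_c) sum 1 / (1 + exp(beta (r_ij - lam r_ij^nat))).  Used only
    for umbrella biasing; the hard Q is used for all reporting.
    """
    d = x_rna[top.con_j] - x_rna[top.con_i]
    r = np.linalg.norm(d, axis=1)
    z = beta * (r - lam * top.con_r0)
    f = 1.0 / (1.0 + np.exp(np.clip(z, -60, 60)))
    q = float(f.mean())
    dfdr = -beta * f * (1.0 - f) / len(f)
    grad = np.zeros_like(x_rna)
    gvec = (dfdr / r)[:, None] * d
    np.add.at(grad, top.con_j, gvec)
    np.add.at(grad, top.con_i, -gvec)
    return q, grad


# --------------------------------------------------------------------------
# Langevin dynamics (BAOAB)
# --------------------------------------------------------------------------

def _init_ions(rng: np.random.Generator, n_ions: int, x_rna: np.ndarray,
               box: float, min_dist: float = 6.0) -> np.ndarray:
    ions = np.empty((n_ions, 3))
    placed = 0
    tries = 0
    while placed < n_ions:
        tries += 1
        if tries > 10_000:
            raise RuntimeError("could not place ions without overlap")
        cand = rng.uniform(0.0, box, size=3)
        d = x_rna - cand
        d -= box * np.round(d / box)
        if np.min(np.linalg.norm(d, axis=1)) < min_dist:
            continue
        if placed:
            d = ions[:placed] - cand
            d -= box * np.round(d / box)
            if np.min(np.linalg.norm(d, axis=1)) < min_dist:
                continue
        ions[placed] = cand
        placed += 1
    return ions


def run_langevin(
    top: Topology,
    cfg: SimConfig,
    x0_rna: np.ndarray | None = None,
    x0_ions: np.ndarray | None = None,
    bias: "UmbrellaWindow | None" = None,
) -> Trajectory:
    """Integrate Langevin dynamics with the BAOAB splitting.

    The same (config, seed) pair reproduces the trajectory bit for bit.
    Ions are wrapped into the periodic box each step; the RNA is kept whole
    and interacts with periodic images only through minimum-image
    displacements.  Raises on non-finite forces, reporting the step index.
    """

    rng = np.random.default_rng(cfg.seed)
    if x0_rna is None:
        raise ValueError("an initial RNA conformation is required")
    x = np.array(x0_rna, dtype=float)
    box = cfg.box_edge
    if x0_ions is not None:
        xi = np.array(x0_ions, dtype=float)
        if cfg.n_mg and len(xi) != cfg.n_mg:
            raise ValueError("x0_ions inconsistent with cfg.n_mg")
    elif cfg.n_mg:
        xi = _init_ions(rng, cfg.n_mg, x, box)
    else:
        xi = np.zeros((0, 3))

    m = cfg.bead_mass
    dt = cfg.timestep
    v = np.zeros_like(x)
    vi = np.zeros_like(xi)
    c1 = np.exp(-cfg.friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1)) * np.sqrt(cfg.temperature / m)

    def total_forces(x, xi):
        E, F, Fi = energy_forces(x, xi, top, cfg)
        eb = 0.0
        qs = np.nan
        if bias is not None:
            qs, grad = smooth_q(x, top)
            eb = 0.5 * bias.k_q * (qs - bias.q0) ** 2
            F = F - bias.k_q * (qs - bias.q0) * grad
        return E + eb, F, Fi, qs, eb

    _, F, Fi, qs, eb = total_forces(x, xi)

    frames_rna, frames_ion, steps, qss, ebs = [], [], [], [], []

    def save(step: int) -> None:
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(xi))):
            raise RuntimeError(f"non-finite coordinates at step {step}")
        frames_rna.append(x.copy())
        frames_ion.append(xi.copy())
        steps.append(step)
        qss.append(qs)
        ebs.append(eb)

    save(0)
    n_steps = bias.n_steps if (bias is not None and bias.n_steps) else cfg.n_steps
    for step in range(1, n_steps + 1):
        v += 0.5 * dt * F / m
        x += 0.5 * dt * v
        if len(xi):
            vi += 0.5 * dt * Fi / m
            xi += 0.5 * dt * vi
        v = c1 * v + c2 * rng.standard_normal(x.shape)
        if len(xi):
            vi = c1 * vi + c2 * rng.standard_normal(xi.shape)
        x += 0.5 * dt * v
        if len(xi):
            xi += 0.5 * dt * vi
            xi %= box
        _, F, Fi, qs, eb = total_forces(x, xi)
        if not np.all(np.isfinite(F)):
            raise RuntimeError(f"non-finite forces at step {step}")
        v += 0.5 * dt * F / m
        if len(xi):
            vi += 0.5 * dt * Fi / m
        if step % cfg.save_interval == 0:
            save(step)

    return Trajectory(
        rna=np.array(frames_rna),
        ions=np.array(frames_ion),
        box_edge=box,
        steps=np.array(steps),
        q_smooth=np.array(qss) if bias is not None else None,
        bias_energy=np.array(ebs) if bias is not None else None,
        window_id=bias.window_id if bias is not None else None,
        meta={"seed": cfg.seed, "temperature": cfg.temperature},
    )


def umbrella_run(
    top: Topology,
    cfg: SimConfig,
    win: UmbrellaWindow,
    x0_rna: np.ndarray,
    x0_ions: np.ndarray | None = None,
) -> Trajectory:
    """One umbrella window: Langevin dynamics plus 0.5 k (Q_s - q0)^2 bias.

    Per-frame Q_smooth and bias energy are recorded on the trajectory.
    With k_q = 0 the result is identical to an unbiased run with the same
    seed (the bias adds no force and consumes no randomness).
    """
    return run_langevin(top, cfg, x0_rna=x0_rna, x0_ions=x0_ions, bias=win)


# --------------------------------------------------------------------------
# Morph fixture generator
# --------------------------------------------------------------------------

def morph_ensemble(
    cg: CGStructure,
    n_frames: int,
    unfold_fraction: float = 1.0,
    noise: float = 0.0,
    seed: int = 0,
    n_background_ions: int = 3,
    bridge: BridgeSpec | None = None,
    box_edge: float = 150.0,
) -> Trajectory:
    """Unfolding-path frames with optional scripted ions.

    Frame f unfolds the native structure toward a self-avoiding extended
    chain by progressive unzipping from the 3' end: the unfolding progress
    alpha_f = unfold_fraction * f/(n_frames-1) converts to per-residue
    blend weights (a short ramp window keeps the chain continuous), so the
    fraction of native contacts decays gradually along the path instead of
    collapsing at once.  Isotropic Gaussian coordinate noise is added on
    top.  If ``bridge`` is given, one extra
    ion is placed midway between the phosphates of the two named residues
    in exactly round(fraction * n_frames) randomly chosen frames (elsewhere
    it is parked in the bulk), creating a designed bridging ground truth.
    Background ions are placed in the bulk, away from all phosphates.
    """

    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    native = cg.xyz
    ext = extended_chain(cg)
    # center both conformations in the box so bulk ions can surround them
    shift = box_edge / 2.0
    native = native - native.mean(axis=0) + shift
    ext = ext - ext.mean(axis=0) + shift

    alphas = (
        np.zeros(n_frames)
        if n_frames == 1
        else unfold_fraction * np.arange(n_frames) / (n_frames - 1)
    )
    # 3'-to-5' unzipping: residue r unfolds once the progress front passes
    # it, blended over a ramp window of a few residues for continuity
    n_res = cg.n_residues
    ramp = 4.0
    r_idx = np.arange(1, n_res + 1)
    progress = alphas[:, None] * (n_res + ramp)
    w_res = np.clip((progress - (n_res - r_idx)[None, :]) / ramp, 0.0, 1.0)
    w = np.repeat(w_res, 3, axis=1)[:, :, None]
    rna = (1.0 - w) * native + w * ext
    if noise > 0:
        rna = rna + rng.normal(scale=noise, size=rna.shape)

    n_ions = n_background_ions + (1 if bridge is not None else 0)
    ions = np.zeros((n_frames, n_ions, 3))

    def bulk_position(frame_xyz: np.ndarray) -> np.ndarray:
        for _ in range(1000):
            cand = rng.uniform(0.0, box_edge, size=3)
            p = frame_xyz[0::3]
            if np.min(np.linalg.norm(p - cand, axis=1)) > 20.0:
                return cand
        raise RuntimeError("no bulk position found")

    bridge_mask = np.zeros(n_frames, dtype=bool)
    if bridge is not None:
        k = int(round(bridge.fraction * n_frames))
        bridge_mask[rng.permutation(n_frames)[:k]] = True

    for f in range(n_frames):
        for b in range(n_background_ions):
            ions[f, b] = bulk_position(rna[f])
        if bridge is not None:
            if bridge_mask[f]:
                pi = rna[f, 3 * (bridge.res_i - 1)]
                pj = rna[f, 3 * (bridge.res_j - 1)]
                ions[f, -1] = 0.5 * (pi + pj) + rng.normal(scale=bridge.jitter,
                                                           size=3)
            else:
                ions[f, -1] = bulk_position(rna[f])

    return Trajectory(
        rna=rna,
        ions=ions,
        box_edge=box_edge,
        steps=np.arange(n_frames),
        meta={
            "generator": "morph",
            "unfold_fraction": unfold_fraction,
            "noise": noise,
            "seed": seed,
            "alphas": alphas.tolist(),
            "bridge_frames": np.flatnonzero(bridge_mask).tolist(),
        },
    )
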
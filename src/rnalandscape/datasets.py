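"""Synthetic RNA structures used as programmatic fixtures and demos.

Nothing here is a real molecule: the geometries are idealized hairpin-like
folds built from straight strands, a turn, and flexible tails, with the
three beads of each nucleotide laid out so that paired residues form
bead-bead contacts under the default 7 A contact cutoff.  They exist so
that the whole pipeline — parsing, coarse-graining, simulation, projection,
ion statistics — can be exercised end-to-end without any external input
file, at system sizes (12 and 52 nt) matching a small stem-loop and a
riboswitch-sized chain.
"""

from __future__ import annotations

import numpy as np

from .rna_model import AnnotationList, CGStructure

__all__ = [
    "toy_hairpin",
    "synthetic_riboswitch",
    "extended_chain",
    "synthetic_rna_pdb",
]

_RISE = 5.5          # per-residue rise along a strand, Angstrom
_STRAND_SEP = 14.0   # P-P distance across the duplex groove
_S_OFF = 3.0         # sugar bead offset toward the helix interior
_B_OFF = 4.5         # base bead offset toward the helix interior


def _strand_beads(p_xyz: np.ndarray, inward: np.ndarray) -> list[np.ndarray]:
    """P/S/B beads for one residue given its phosphate position and the
    unit vector pointing toward the duplex interior."""
    return [p_xyz, p_xyz + _S_OFF * inward, p_xyz + _B_OFF * inward]


def _hairpin_fold(
    n: int, stem_start: int, stem_len: int, loop_len: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Bead coordinates for an idealized hairpin embedded in a longer chain.

    Residues (1-based) ``stem_start .. stem_start+stem_len-1`` run up the
    5' strand, ``loop_len`` residues turn, and the next ``stem_len``
    residues run back down the 3' strand directly across the groove.
    Whatever precedes or follows the hairpin is laid out as straight tails.
    Returns (beads array (3n,3), list of across-groove residue pairs).
    """

    x5, x3 = 0.0, _STRAND_SEP
    up_end = stem_start + stem_len - 1          # last residue of 5' strand
    down_start = up_end + loop_len + 1          # first residue of 3' strand
    down_end = down_start + stem_len - 1
    if down_end > n:
        raise ValueError("hairpin does not fit in the chain")

    beads: list[np.ndarray] = []
    right = np.array([1.0, 0.0, 0.0])
    left = -right
    pairs = []
    for i in range(1, n + 1):
        if i < stem_start:                      # 5' tail, heading -y
            p = np.array([x5 - 6.0 - 5.0 * (stem_start - 1 - i), -6.0, 4.0])
            inward = np.array([0.0, 0.0, -1.0])
        elif i <= up_end:                       # 5' strand
            p = np.array([x5, (i - stem_start) * _RISE, 0.0])
            inward = right
        elif i < down_start:                    # loop arc over the top
            k = i - up_end                      # 1..loop_len
            frac = k / (loop_len + 1)
            ang = np.pi * frac
            cx = _STRAND_SEP / 2.0
            top = (stem_len - 1) * _RISE
            p = np.array(
                [cx - cx * np.cos(ang), top + (_STRAND_SEP / 2.0) * np.sin(ang), 0.0]
            )
            inward = np.array([0.0, -1.0, 0.0])
        elif i <= down_end:                     # 3' strand, heading -y
            p = np.array([x3, (down_end - i) * _RISE, 0.0])
            inward = left
            pairs.append((stem_start + (down_end - i), i))
        else:                                   # 3' tail
            p = np.array([x3 + 6.0 + 5.0 * (i - down_end - 1), -6.0, -4.0])
            inward = np.array([0.0, 0.0, 1.0])
        beads.extend(_strand_beads(p, inward))
    return np.array(beads), pairs


def _annotations(pairs: list[tuple[int, int]], n: int) -> AnnotationList:
    bps = [(i, j, "WC") for i, j in pairs]
    stacked = sorted({i for i, _ in pairs} | {j for _, j in pairs})
    stacks = [
        (a, b) for a, b in zip(stacked[:-1], stacked[1:]) if b == a + 1
    ]
    return AnnotationList(base_pairs=bps, stacks=stacks, n_residues=n)


def toy_hairpin() -> tuple[CGStructure, AnnotationList]:
    """A 12-nt stem-loop: 4 base pairs, 4-residue loop.

    The smallest system on which folding/unfolding, umbrella sampling and
    every analysis stage are meaningful; used by the demo pipeline.
    """
    seq = "GGCGUUUUCGCC"
    beads, pairs = _hairpin_fold(12, stem_start=1, stem_len=4, loop_len=4)
    return (
        CGStructure(xyz=beads, sequence=seq, source_id="toy-hairpin-12nt"),
        _annotations(pairs, 12),
    )


def synthetic_riboswitch() -> tuple[CGStructure, AnnotationList]:
    """A 52-nt riboswitch-sized synthetic fold.

    The chain folds into a 9-bp hairpin whose strands place the phosphates
    of residues 28 and 38 directly across the groove (~14 A apart), so a
    single divalent ion midway between them is within the 8 A coordination
    cutoff of both — the geometry needed to exercise ion-bridging
    analytics on a designed ground truth.
    """
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGU"), size=52))
    # 5' strand 24..32, 1-residue apex at 33, 3' strand 34..42: residue 28
    # sits at the same height as residue 38 on the opposite strand.
    beads, pairs = _hairpin_fold(52, stem_start=24, stem_len=9, loop_len=1)
    cg = CGStructure(xyz=beads, sequence=seq, source_id="synthetic-riboswitch-52nt")
    p = cg.phosphate_xyz()
    assert np.linalg.norm(p[27] - p[37]) < 16.0  # designed bridge geometry
    return cg, _annotations(pairs, 52)


def extended_chain(cg: CGStructure, spacing: float | None = None) -> np.ndarray:
    """A self-avoiding fully extended conformation with the same bead count.

    Beads are laid along a straight line at the mean native consecutive-bead
    spacing, which preserves bond lengths approximately while breaking every
    contact separated by three or more residues.
    """
    n = cg.n_beads
    if spacing is None:
        spacing = float(np.mean(np.linalg.norm(np.diff(cg.xyz, axis=0), axis=1)))
    out = np.zeros((n, 3))
    out[:, 0] = spacing * np.arange(n)
    # small deterministic zig-zag keeps consecutive triples non-collinear
    out[:, 1] = 0.3 * spacing * (np.arange(n) % 2)
    return out


# --------------------------------------------------------------------------
# Synthetic atomistic PDB text (for parser / coarse-graining tests)
# --------------------------------------------------------------------------

_PUR = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
_PYR = ("N1", "C2", "N3", "C4", "C5", "C6")
_SUGAR = ("C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'", "O3'")
_PHOS = ("P", "OP1", "OP2", "O5'")

_ELEMENT = {"P": "P", "O": "O", "N": "N", "C": "C"}


def _pdb_atom_line(
    serial: int, name: str, resname: str, chain: str, resseq: int,
    xyz: np.ndarray, altloc: str = " ", record: str = "ATOM",
) -> str:
    el = _ELEMENT[name[0]]
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {pad_name}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"  1.00  0.00          {el:>2s}"
    )


def synthetic_rna_pdb(
    sequence: str = "GCAU",
    chain_id: str = "A",
    with_waters: bool = False,
    with_ions: bool = False,
    altloc_residue: int | None = None,
    second_chain: str | None = None,
) -> str:
    """Generate well-formed PDB text for a synthetic RNA chain.

    Atoms of each residue are scattered deterministically around the three
    bead centers of an idealized fold, so parsing followed by
    coarse-graining recovers a sensible geometry.  Options add HETATM
    waters/ions, a duplicate-altloc atom, or a second (protein-free) chain
    to exercise the parser's filtering rules.
    """
    n = len(sequence)
    stem = max(1, (n - 2) // 2) if n >= 4 else 1
    loop = n - 2 * stem if n >= 4 else max(n - 2 * stem, 0)
    if n < 4:
        beads = np.array(
            [b for i in range(n) for b in _strand_beads(
                np.array([0.0, i * _RISE, 0.0]), np.array([1.0, 0.0, 0.0]))]
        )
    else:
        beads, _ = _hairpin_fold(n, stem_start=1, stem_len=stem, loop_len=loop)

    rng = np.random.default_rng(11)
    lines = []
    serial = 1

    def emit(name: str, resname: str, resseq: int, center: np.ndarray,
             altloc: str = " ", record: str = "ATOM") -> None:
        nonlocal serial
        jitter = rng.normal(scale=0.6, size=3)
        lines.append(
            _pdb_atom_line(serial, name, resname, chain_id if record == "ATOM"
                           else "A", resseq, center + jitter, altloc, record)
        )
        serial += 1

    for i, base in enumerate(sequence, start=1):
        p_c, s_c, b_c = beads[3 * (i - 1)], beads[3 * i - 2], beads[3 * i - 1]
        phos = _PHOS if i > 1 else ("O5'",)   # 5' terminus has no phosphate
        for name in phos:
            emit(name, base, i, p_c)
        for name in _SUGAR:
            emit(name, base, i, s_c)
            if altloc_residue == i and name == "C1'":
                # duplicate atom with a second altloc; parsers must keep one
                emit(name, base, i, s_c, altloc="B")
        ring = _PUR if base in "AG" else _PYR
        for name in ring:
            emit(name, base, i, b_c)

    if second_chain:
        for k in range(3):
            center = np.array([60.0 + 10 * k, 0.0, 0.0])
            for name in ("O5'",) + _SUGAR + _PYR:
                jitter = rng.normal(scale=0.6, size=3)
                lines.append(
                    _pdb_atom_line(serial, name, "U", second_chain, k + 1,
                                   center + jitter)
                )
                serial += 1

    hetseq = len(sequence) + 10
    if with_waters:
        for k in range(3):
            lines.append(
                _pdb_atom_line(serial, "O", "HOH", chain_id, hetseq + k,
                               np.array([40.0, 5.0 * k, 0.0]), record="HETATM")
            )
            serial += 1
    if with_ions:
        lines.append(
            _pdb_atom_line(serial, "O", "MG", chain_id, hetseq + 5,
                           np.array([45.0, 0.0, 0.0]), record="HETATM")
        )
        serial += 1

    lines.append("END")
    return "\n".join(lines) + "\n"
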
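"""RNA structures, three-bead coarse-graining, and native contact maps.

The analysis pipeline works on a reduced representation of RNA in which
every nucleotide is replaced by three beads located at the mass-weighted
centers of its phosphate group, sugar, and base.  Native contacts between
beads of the reference (crystal or model) conformation define the fraction
of native contacts Q and the attractive part of the structure-based
potential used by the surrogate simulator.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser

from .constants import (
    ATOMIC_MASSES,
    BASE_ATOMS,
    BEAD_ROLES,
    PHOSPHATE_ATOMS,
    RNA_RESNAMES,
    SUGAR_ATOMS,
)

__all__ = [
    "Atom",
    "Structure",
    "CGStructure",
    "NativeContactSet",
    "AnnotationList",
    "load_structure",
    "coarse_grain",
    "native_contacts",
    "read_annotations",
    "write_annotations",
]


@dataclass(frozen=True)
class Atom:
    """A single atom record with 1-based residue indexing."""

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    xyz: tuple[float, float, float]


@dataclass
class Structure:
    """An atomistic single-chain RNA structure.

    ``atoms`` holds the nucleotide atoms of one chain; waters, ions and
    other heteroatoms encountered during parsing are kept aside in
    ``het_atoms`` so they never leak into the coarse-graining.
    """

    atoms: list[Atom]
    source_id: str = ""
    het_atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")
        for a in self.atoms:
            if a.residue_index < 1:
                raise ValueError(f"residue index must be >= 1, got {a.residue_index}")
            if not all(np.isfinite(a.xyz)):
                raise ValueError(f"non-finite coordinates on atom {a.name}")

    @property
    def n_residues(self) -> int:
        return len({a.residue_index for a in self.atoms})

    def residues(self) -> dict[int, list[Atom]]:
        """Atoms grouped by residue index, in index order."""
        out: dict[int, list[Atom]] = {}
        for a in sorted(self.atoms, key=lambda a: a.residue_index):
            out.setdefault(a.residue_index, []).append(a)
        return out


@dataclass
class CGStructure:
    """Three-bead-per-nucleotide coarse-grained structure.

    Beads are ordered P, S, B within each residue, so bead ``3*(i-1)+k``
    belongs to residue ``i`` (1-based) with role ``BEAD_ROLES[k]``.
    """

    xyz: np.ndarray                 # (3*n_residues, 3) in Angstrom
    sequence: str                   # one letter per residue
    source_id: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_beads, 3)")
        if self.xyz.shape[0] != 3 * len(self.sequence):
            raise ValueError(
                f"expected {3 * len(self.sequence)} beads for "
                f"{len(self.sequence)} residues, got {self.xyz.shape[0]}"
            )
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite bead coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_beads(self) -> int:
        return self.xyz.shape[0]

    @property
    def bead_roles(self) -> list[str]:
        return list(BEAD_ROLES) * self.n_residues

    @property
    def bead_residues(self) -> np.ndarray:
        """1-based residue index of every bead."""
        return np.repeat(np.arange(1, self.n_residues + 1), 3)

    def phosphate_xyz(self, xyz: np.ndarray | None = None) -> np.ndarray:
        """P-bead coordinates, optionally for an alternative frame."""
        coords = self.xyz if xyz is None else np.asarray(xyz, dtype=float)
        return coords[0::3]

    def to_pdb(self) -> str:
        """Write the beads as a PDB-like CG file (one ATOM per bead)."""
        lines = []
        for b in range(self.n_beads):
            res = int(self.bead_residues[b])
            role = self.bead_roles[b]
            x, y, z = self.xyz[b]
            lines.append(
                f"ATOM  {b + 1:5d} {role:<4s}{self.sequence[res - 1]:>3s} A"
                f"{res:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"


@dataclass
class NativeContactSet:
    """Reference bead-pair contacts with their native distances.

    ``pairs`` is an (N_c, 2) int array of bead indices with i < j;
    ``native_distances`` the corresponding distances in Angstrom.
    """

    pairs: np.ndarray
    native_distances: np.ndarray
    cutoff_used: float
    min_sequence_separation: int
    bead_residues: np.ndarray       # 1-based residue of every bead of the parent

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.native_distances = np.asarray(self.native_distances, dtype=float)
        if len(self.pairs) != len(self.native_distances):
            raise ValueError("pairs and native_distances length mismatch")
        if len(self.pairs):
            if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
                raise ValueError("contact pairs must satisfy i < j")
            if np.any(self.native_distances <= 0):
                raise ValueError("native distances must be positive")
            sep = np.abs(
                self.bead_residues[self.pairs[:, 0]]
                - self.bead_residues[self.pairs[:, 1]]
            )
            if np.any(sep < self.min_sequence_separation):
                raise ValueError("contact violates the minimum sequence separation")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def residue_pairs(self) -> np.ndarray:
        """Deduplicated residue-level view of the contact list (1-based)."""
        rp = np.stack(
            [
                self.bead_residues[self.pairs[:, 0]],
                self.bead_residues[self.pairs[:, 1]],
            ],
            axis=1,
        )
        rp.sort(axis=1)
        return np.unique(rp, axis=0)

    def to_tsv(self) -> str:
        lines = ["i\tj\tres_i\tres_j\tr_native"]
        for (i, j), r in zip(self.pairs, self.native_distances):
            lines.append(
                f"{i}\t{j}\t{self.bead_residues[i]}\t{self.bead_residues[j]}\t{r:.4f}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class AnnotationList:
    """Native base pairs and stacks, by 1-based residue index.

    Base pairs optionally carry a Leontis-Westhof class label which is
    treated as opaque text (never recomputed at CG resolution).
    """

    base_pairs: list[tuple[int, int, str]]
    stacks: list[tuple[int, int]]
    n_residues: int | None = None

    def __post_init__(self) -> None:
        for i, j, _ in self.base_pairs:
            self._check(i, j)
        for i, j in self.stacks:
            self._check(i, j)

    def _check(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError(f"self-pair ({i}, {j}) not allowed")
        for k in (i, j):
            if k < 1 or (self.n_residues is not None and k > self.n_residues):
                raise ValueError(f"residue index {k} out of range")

    @property
    def n_interactions(self) -> int:
        return len(self.base_pairs) + len(self.stacks)

    def labels(self) -> list[str]:
        out = [f"bp:{i}-{j}" for i, j, _ in self.base_pairs]
        out += [f"stack:{i}-{j}" for i, j in self.stacks]
        return out


def load_structure(pdb_text: str, chain_id: str = "A", source_id: str = "") -> Structure:
    """Parse PDB text and return the requested chain's nucleotides.

    Keeps the first alternate location of every atom, drops hydrogens'
    duplicates only through the altloc rule (hydrogens themselves are
    kept), and moves waters, ions and ligands to ``het_atoms``.  Residues
    are renumbered 1..n in chain order.
    """

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure(source_id or "rna", io.StringIO(pdb_text))[0]

    chains = {c.id: c for c in model}
    if chain_id not in chains:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {sorted(chains)}"
        )
    chain = chains[chain_id]

    atoms: list[Atom] = []
    het: list[Atom] = []
    res_counter = 0
    for residue in chain:
        hetflag = residue.id[0].strip()
        resname = residue.get_resname().strip()
        is_nt = not hetflag and resname in RNA_RESNAMES
        if is_nt:
            res_counter += 1
        for atom in residue:
            # Disordered atoms expose altlocs; keep the first one only.
            if atom.is_disordered():
                atom = sorted(atom.disordered_get_list(), key=lambda a: a.get_altloc())[0]
            rec = Atom(
                name=atom.get_name(),
                element=(atom.element or atom.get_name()[0]).upper(),
                residue_index=res_counter if is_nt else max(res_counter, 1),
                residue_name=RNA_RESNAMES.get(resname, resname),
                chain_id=chain_id,
                xyz=tuple(float(v) for v in atom.coord),
            )
            (atoms if is_nt else het).append(rec)

    if res_counter == 0:
        raise ValueError(f"chain {chain_id!r} contains no standard ribonucleotides")
    return Structure(atoms=atoms, source_id=source_id, het_atoms=het)


def _group_com(group: list[Atom]) -> np.ndarray:
    masses = np.array([ATOMIC_MASSES.get(a.element, 12.0) for a in group])
    coords = np.array([a.xyz for a in group])
    return masses @ coords / masses.sum()


def coarse_grain(s: Structure) -> CGStructure:
    """Map an atomistic structure to three beads per nucleotide.

    Each bead is the mass-weighted center of its atom group.  A 5'-terminal
    residue without a phosphate group gets its P bead at the center of mass
    of O5' (plus any attached hydrogens) so every residue carries exactly
    three beads.
    """

    if not isinstance(s, Structure):
        raise TypeError(
            "coarse_grain expects an atomistic Structure; "
            f"got {type(s).__name__} (already coarse-grained input is not valid)"
        )

    beads = []
    sequence = []
    for res_idx, res_atoms in s.residues().items():
        names = {a.name for a in res_atoms}
        p_group = [a for a in res_atoms if a.name in PHOSPHATE_ATOMS]
        s_group = [a for a in res_atoms if a.name in SUGAR_ATOMS]
        b_group = [
            a
            for a in res_atoms
            if a.name in BASE_ATOMS
            or (a.name not in PHOSPHATE_ATOMS and a.name not in SUGAR_ATOMS
                and not a.name.startswith("H"))
        ]
        if "P" not in names:
            # 5' terminus: fall back to the O5' (+ attached hydrogens) center.
            p_group = [a for a in res_atoms if a.name in ("O5'", "HO5'", "H5T")]
        if not p_group:
            raise ValueError(f"residue {res_idx} has no phosphate or O5' atoms")
        if not s_group:
            raise ValueError(f"residue {res_idx} has no sugar atoms")
        if not b_group:
            raise ValueError(f"residue {res_idx} has no base atoms")
        beads.extend([_group_com(p_group), _group_com(s_group), _group_com(b_group)])
        sequence.append(RNA_RESNAMES.get(res_atoms[0].residue_name, "N"))

    return CGStructure(
        xyz=np.array(beads), sequence="".join(sequence), source_id=s.source_id
    )


def native_contacts(
    cg: CGStructure, cutoff: float = 7.0, min_sep: int = 3
) -> NativeContactSet:
    """All bead pairs closer than ``cutoff`` with residue separation >= ``min_sep``.

    The pair list is deterministic (i < j, lexicographic order).  The
    default 7 A / 3-residue choice gives a contact map whose fraction of
    native contacts behaves like the standard structure-based-model Q.
    """

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    xyz = cg.xyz
    res = cg.bead_residues
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    sep = np.abs(res[:, None] - res[None, :])
    ii, jj = np.where(np.triu((dist < cutoff) & (sep >= min_sep), k=1))
    order = np.lexsort((jj, ii))
    ii, jj = ii[order], jj[order]
    return NativeContactSet(
        pairs=np.stack([ii, jj], axis=1),
        native_distances=dist[ii, jj],
        cutoff_used=float(cutoff),
        min_sequence_separation=int(min_sep),
        bead_residues=res,
    )


def read_annotations(text: str, n_residues: int | None = None) -> AnnotationList:
    """Read a base-pair/stack annotation list from TSV text.

    Lines are ``pair <res_i> <res_j> [class]`` or ``stack <res_i> <res_j>``;
    blank lines and ``#`` comments are ignored.
    """

    bps: list[tuple[int, int, str]] = []
    stacks: list[tuple[int, int]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kind = parts[0].lower()
        i, j = int(parts[1]), int(parts[2])
        if kind == "pair":
            bps.append((i, j, parts[3] if len(parts) > 3 else ""))
        elif kind == "stack":
            stacks.append((i, j))
        else:
            raise ValueError(f"unknown annotation record {kind!r}")
    return AnnotationList(base_pairs=bps, stacks=stacks, n_residues=n_residues)


def write_annotations(ann: AnnotationList) -> str:
    lines = [f"pair\t{i}\t{j}\t{cls}".rstrip() for i, j, cls in ann.base_pairs]
    lines += [f"stack\t{i}\t{j}" for i, j in ann.stacks]
    return "\n".join(lines) + "\n"
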
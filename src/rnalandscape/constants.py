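"""Shared physical constants and atom-classification tables.

The three-bead mapping places one bead at the mass-weighted center of the
phosphate group, one at the sugar, and one at the base of every nucleotide.
The assignment of PDB atom names to those groups is fixed here so that the
coarse-graining is stable across PDB dialects.
"""

from __future__ import annotations

# Standard atomic masses (u) for the elements found in nucleic acids.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

# Phosphate group: the phosphorus, its non-bridging oxygens and the 5'
# bridging oxygen.  The O3' of the preceding linkage stays with the sugar
# of its own residue.
PHOSPHATE_ATOMS = frozenset({"P", "OP1", "OP2", "OP3", "O1P", "O2P", "O3P", "O5'"})

# Ribose sugar ring plus the 2'- and 3'-hydroxyl oxygens.
SUGAR_ATOMS = frozenset({"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'", "O3'"})

# Everything heavy that is neither phosphate nor sugar belongs to the base;
# listing the canonical names lets us reject residues with no base atoms.
BASE_ATOMS = frozenset(
    {
        "N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
        "O2", "O4", "O6", "N2", "N4", "N6",
    }
)

# Residue names accepted as standard ribonucleotides.
RNA_RESNAMES: dict[str, str] = {
    "A": "A", "G": "G", "C": "C", "U": "U",
    "RA": "A", "RG": "G", "RC": "C", "RU": "U",
    "ADE": "A", "GUA": "G", "CYT": "C", "URA": "U",
}

BEAD_ROLES = ("P", "S", "B")
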
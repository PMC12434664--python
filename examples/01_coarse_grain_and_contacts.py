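"""Parse an RNA chain, coarse-grain it to three beads per nucleotide, and
derive the native contact map that defines the folding coordinate Q.

Uses a synthetic 52-nt chain generated in memory; point `load_structure`
at a real PDB file (e.g. a riboswitch crystal structure) to analyze
experimental coordinates instead.
"""

import numpy as np

from rnalandscape import coarse_grain, datasets, fraction_native, load_structure, native_contacts

pdb_text = datasets.synthetic_rna_pdb("GCAU" * 13, with_waters=True)
structure = load_structure(pdb_text, chain_id="A")
print(f"parsed {structure.n_residues} nucleotides, "
      f"{len(structure.het_atoms)} heteroatoms set aside")

cg = coarse_grain(structure)
print(f"coarse-grained to {cg.n_beads} beads (3 per residue: P, S, B)")

nc = native_contacts(cg, cutoff=7.0, min_sep=3)
print(f"native contacts: {len(nc)} bead pairs "
      f"({len(nc.residue_pairs)} residue pairs) within 7.0 A, "
      f">=3 residues apart")
print(f"mean native contact distance: {nc.native_distances.mean():.2f} A")

q_native = fraction_native(cg.xyz, nc)
q_swollen = fraction_native(cg.xyz * 1.5, nc)
print(f"Q of the native frame: {q_native:.2f} (folded reference by definition)")
print(f"Q after uniform 1.5x expansion: {q_swollen:.2f} "
      f"(expansion breaks contacts, so Q drops)")
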
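# Methods

## Coarse-grained representation

Each nucleotide is reduced to three beads placed at the mass-weighted
centers (standard atomic masses) of its phosphate, sugar, and base atom
groups. The atom-to-group table is fixed in `constants.py`: the phosphate
group holds P, the non-bridging oxygens, and O5′; the sugar holds
C1′–C5′, O4′, O2′, and O3′ (the O3′ of a linkage stays with its own
residue's sugar); every remaining heavy atom belongs to the base. A
5′-terminal residue without a phosphate gets its P bead at the center of
mass of O5′ (plus attached hydrogens), so every residue carries exactly
three beads. Residue indexing is 1-based throughout; distances are in Å.

Native contacts are all bead pairs of the reference conformation closer
than a cutoff (default 7.0 Å) with sequence separation ≥ 3 residues.
This distance-cutoff map is a deliberate simplification: atomistic
contact-derivation schemes (shadow/occlusion algorithms) need all-atom
geometry that a three-bead model does not retain, and the cutoff map
preserves everything the downstream Q-based analyses rely on. Both cutoff
and separation are configurable.

## Surrogate simulator

The simulator is a desk-scale surrogate for production-grade
structure-based RNA/ion simulations: its purpose is to generate
trajectories with the right phenomenology (two-state folding of small
motifs, ion condensation and bridging, umbrella-confined windows), not to
reproduce any particular production Hamiltonian.

**Potential.** Treating the bead sequence as a linear chain (3N−1 bonds,
3N−2 angles):

- bonds: ½ k_b (r−r₀)², k_b = 100 ε/Å²;
- angles: ½ k_θ (θ−θ₀)², k_θ = 10 ε/rad²;
- native contacts: Gaussian wells with a hard core,
  ε_c [(1+(s/r)¹²)(1−e^{−(r−r₀)²/2w²})−1], ε_c = 2 ε, w = 1 Å,
  s = 0.8 r₀, so the native distance is the exact minimum;
- excluded volume: WCA repulsion between all other bead pairs with a
  per-pair diameter capped at 0.8× the native separation — this makes the
  native structure an exact minimum of the ion-free potential (gradient
  ≈ 0 at the reference coordinates, verified numerically in the tests);
- electrostatics: screened Coulomb C q_i q_j e^{−r/λ_D}/r between charged
  sites — phosphate beads at −1, divalent ions at +2 — with Debye length
  λ_D = 10 Å (≈100 mM monovalent salt) and prefactor C = 7 Å·ε (a
  Bjerrum-length-scale coupling). Implicit monovalent salt enters only
  through λ_D; no dynamic condensation variables are modeled. Ions carry a
  hydrated-ion excluded-volume radius of 3.5 Å (configurable; the value is
  a standard outer-sphere scale, not fitted).

**Units and integration.** Reduced units: ε = k_B = bead mass = 1,
lengths in Å. Langevin dynamics uses the BAOAB splitting with timestep
0.001 τ (tests and demos use 0.01 τ, well inside the stability limit of
the stiffest bond), friction 1 τ⁻¹. Ions are wrapped into the periodic
cubic box (default edge 15 nm; larger production-scale boxes are accepted
via config) and all ion-involving pair interactions use minimum-image
displacements; the RNA itself is kept whole. A (config, seed) pair fully
determines the trajectory, bit for bit. Non-finite forces abort with the
step index.

**Temperature calibration.** The folding temperature of the toy 12-nt
hairpin was located by a temperature scan (median Q over the second half
of 40k-step runs started from the native state): Q ≈ 1.0 at T ≤ 0.5,
midpoint near T ≈ 1.7, fully unfolded by T ≥ 3. The package uses T = 0.2
as the "cold" regime, T = 1.7 for umbrella sampling, and T = 4.0 as the
"hot" regime. These are properties of this surrogate's energy scale only.

**Umbrella biasing.** The hard Q (a count) has no gradient, so biasing
uses a smooth variant Q_s = (1/N_c) Σ 1/(1+e^{β(r_ij−λ r_ij⁰)}) with
β = 5 Å⁻¹ and λ = 1.2; the bias is ½ k_Q (Q_s − Q₀)². Hard Q is used for
all reporting; profiles from umbrella data are reconstructed along Q_s,
the coordinate the bias actually acts on. With k_Q = 0 the biased
integrator reproduces the unbiased trajectory exactly under the same seed.

## Morph-ensemble generator

`morph_ensemble` produces unfolded↔folded fixture trajectories without
dynamics: the chain unzips progressively from the 3′ end toward a
self-avoiding extended conformation (per-residue blend weights with a
4-residue continuity ramp), plus isotropic Gaussian coordinate noise. The
unzipping schedule makes Q decay gradually along the path, so projections
of the path form a connected filament and nativeness measures correlate
with Q. Optionally one scripted ion is placed midway between two chosen
phosphates in exactly ⌈fraction·n⌉ randomly chosen frames (elsewhere it is
parked in the bulk), and background ions are placed in the bulk away from
the backbone.

What the generator emulates: ensembles spanning the folded-to-unfolded
range, designed ion-coordination ground truths, and smooth conformational
paths. What it does not emulate: Boltzmann weighting (frames are evenly
spaced along the path, not sampled from any ensemble), chain
self-entanglement, ion dynamics, or correlated base-pair kinetics. Tests
that pass on morph data therefore validate the *analysis* machinery —
recovery of designed signals, algebraic identities, invariances — not any
thermodynamic statement about real RNA; thermodynamic behavior is
exercised separately through the Langevin simulator.

## ELViM-style projection

Dissimilarity between conformations k and l is δ = 1 − q_w with
q_w = (1/N_p) Σ exp(−(r_ij^k−r_ij^l)²/2σ_ij²) over bead pairs, and
σ_ij = σ₀|n_i−n_j|^ε (σ₀ = 3 Å, ε = 0.15, with n the residue index of a
bead). Intra-residue pairs are excluded from the pair set: their sequence
separation is zero, which would make σ_ij vanish and the Gaussian
singular; N_p is the size of the included set. δ depends only on internal
distances and is invariant under rigid motion of either conformation.

The force scheme starts from seeded uniform-random 2D positions; per
iteration every point serves once as pivot (order reshuffled each
iteration from the run seed) and every other point moves along the
pivot→point direction by step_fraction × (δ_scaled − d_current). Defaults:
100 iterations, step fraction 1/8, δ min-max scaled to [0, 1] with no
nonlinear transform. Normalized stress Σ(δ−d)²/Σδ² is recorded per
iteration; on random 50×50 inputs the final stress never exceeds the
initial one, and an exactly embeddable equilateral triple is recovered to
well under 2%.

Density uses a Gaussian KDE with Scott's rule on the 2D embedding;
degenerate (all-identical) point sets are rejected. Regions are selected
programmatically — a polygon in embedding coordinates (the equivalent of
circling a basin by hand) or a density-quantile threshold. The local
conformational signature of a region is the frame minimizing the mean
dRMSD to the region's other members (ties to the lowest frame index),
reported with its nearest dRMSD neighbors.

## Ion-coordination analytics

- **RDF**: shell-normalized g(r) of ions around phosphate beads against
  the ideal-gas ion density of the box; the first minimum of the smoothed
  g(r) after its first peak is the data-driven coordination cutoff and is
  used as the default occupancy cutoff when none is supplied.
- **Occupancy**: per-frame, per-phosphate count of ions within the cutoff
  (default 8 Å), strict inequality — an ion at exactly the cutoff does not
  count, and an ion near two phosphates counts toward both. Binned along Q
  with bin width 0.05; empty bins are reported missing (NaN), never zero.
- **Bridging map**: P(i,j) is the fraction of frames with ≥1 ion
  simultaneously within the cutoff of phosphates i and j, restricted to
  |i−j| ≥ 4 residues ("nonlocal"; configurable). A per-frame
  at-least-one-ion event count was chosen over an ion-count average so the
  map reads directly as a probability.
- **Excess ions**: mean number of distinct ions within the cutoff of any
  phosphate minus the ideal-bulk expectation (bulk density × union volume
  of the cutoff spheres, estimated by seeded Monte Carlo), reported
  separately for folded (Q ≥ 0.85) and unfolded (Q < 0.4) frames.

## Interaction maps

A native base pair or stack (from the annotation list) is "formed" in a
frame when its base-bead distance is within λ = 1.2 of the native
base-bead distance — a pure distance criterion, because CG beads carry no
hydrogen-bond geometry. Leontis–Westhof class labels are carried as
opaque text. Frequencies are reported per Q bin and as symmetric
residue×residue ensemble maps; increasing λ can only increase
frequencies (verified as a property test).

## WHAM and state classification

Standard self-consistent WHAM on (windows × bins) histograms with bias
energies tabulated at bin centers, iterated until max|Δf_w| < 10⁻⁷
(default grid 50 bins on [0,1], iteration cap 10⁵, failure raises with the
residual). The solution is invariant to adding a constant to any window's
bias; windows whose histograms share no occupied bins are reported as
disconnected components with a warning. F(Q) = −ln P(Q), minimum shifted
to zero; bins with no samples are +∞. On an analytic 1D double well
sampled through 9 harmonic windows the reconstructed barrier matches the
Boltzmann-integral oracle to ≲0.05 k_BT, well inside the 0.3 k_BT bound
asserted in the tests.

States along Q: U below 0.4, PO in [0.4, 0.55), PF in [0.55, 0.85), F at
and above 0.85. Boundary values are assigned to the higher state
(left-closed intervals); the conventional threshold statements use open
inequalities and leave boundaries unspecified, so the tie-break had to be
fixed — it is documented here and in the classifier.

## Synthetic structures

`datasets` provides programmatic fixtures: a 12-nt stem-loop
(4 bp + tetraloop) used by the demo pipeline and simulator tests, and a
52-nt riboswitch-sized fold whose hairpin places the phosphates of
residues 28 and 38 directly across the groove (~14 Å apart), so a single
ion midway between them is within the 8 Å cutoff of both — the designed
geometry behind the ion-bridging recovery tests. Both are idealized
strand/turn constructions, clearly synthetic, and `synthetic_rna_pdb`
emits equivalent atomistic-style PDB text (with optional waters, ions,
altlocs, extra chains) for exercising the parser and coarse-grainer.

## Problem sizes and numerical choices

Test and demo runs use the 12-nt hairpin (36 beads, ~20k Langevin steps),
morph ensembles of 200–1000 frames on the 52-nt fold, 9 umbrella windows
of 3–4k steps, and 50-bin WHAM grids — sizes chosen so the full suite and
the acceptance script each complete in about a minute on one CPU while
every analysis stage still operates in its intended regime. Window count
scales to production values (e.g., 45) by configuration. Degenerate
inputs are handled explicitly throughout: empty contact sets, single-frame
regions, zero-ion trajectories, all-identical embeddings, non-overlapping
windows, and out-of-range Q values all raise or are flagged rather than
silently misbehave.

## Known limitations

The simulator has no explicit water, no inner-sphere ion chemistry, no
all-atom detail, and no replica exchange; its temperatures and energies
are in surrogate reduced units and map to experimental conditions only
qualitatively. The morph generator is not Boltzmann-weighted. Base-pair
detection is distance-only at CG resolution. WHAM is 1D (no MBAR, no 2D
profiles). PDB parsing covers standard ribonucleotides in ATOM/HETATM
records, not modified nucleotides or full mmCIF.
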
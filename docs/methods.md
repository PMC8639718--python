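# Methods

This note records the scientific conventions, default parameters, and
design choices behind `crystalens`, and what its synthetic validation does
and does not establish.

## Analysis model

The package treats a conformational ensemble as an ordered list of
coordinate models sharing one topology (a multi-model PDB), with a frame
interval in ps supplied by the user — it is metadata of how the trajectory
was written, never inferred. Frames before a user-set equilibration start
are discarded; equilibration is never auto-detected.

### Native contacts and fold classification

The reference contact set contains every Cα–Cα pair of the native
structure that is **strictly** closer than the cutoff (default 6.5 Å) and
at least 3 residues apart in sequence; "closer than" is read strictly, so
a pair exactly at the cutoff is not a contact. A frame's native-contact
percentage is the fraction of reference pairs retained under the same
strict rule. Cluster-level percentages are unweighted means over member
frames, and a cluster is folded iff its mean is **greater than or equal
to** 60 % (the boundary is folded). These conventions are asserted in the
tests and exposed as configuration.

### Clustering

Both clusterings consume the same pairwise Cα-RMSD matrix, computed with
reflection-free Kabsch superposition for every frame pair (a batched SVD;
residuals are evaluated directly rather than via the Gram-trace shortcut,
which loses ~7 digits to cancellation for near-identical frames).

*GROMOS*: iteratively take the frame with the most neighbours under the
cutoff (default 5 Å, strict `<`) as a cluster centre, remove it and its
neighbours, repeat. Ties in neighbour count break to the lowest frame
index, making the procedure deterministic.

*Network*: edges join frames with RMSD strictly below the cutoff
(default 3.5 Å; `auto` uses the mean of the strictly-upper-triangle
distribution). Clusters are **connected components** of that graph — the
reproducible reading of a force-directed visual grouping; spring-layout
coordinates are produced only as an optional visualisation export and
never define membership. Cluster labels are 1-based by decreasing size;
centroids are medoids (member minimising mean RMSD to the others, ties to
the lowest frame id). For large ensembles the network stage subsamples
500 frames at a regular stride.

*Convergence*: GROMOS clustering in 20 ns windows advancing by half a
window (the overlap step is unstated upstream; half-window is this
package's choice), reporting per-window cluster counts and the cluster
entropy −Σ Pⱼ ln Pⱼ. Natural log is used throughout; a different base only
rescales the series. A flat trend is the convergence signal — reported,
never auto-judged.

### Surface areas, burial, patches

SASA uses the Shrake–Rupley rolling-ball algorithm with probe 1.4 Å and a
deterministic Fibonacci sphere lattice (default 960 points; single-sphere
quadrature error < 0.5 %). The default van der Waals radii are the classic
united-atom rolling-ball set — C 2.00, N 1.70, O 1.40, S 1.85, H 1.20 Å —
appropriate for structures without explicit hydrogens, where the carbon
radius absorbs its hydrogens; the table is config-overridable. Under this
set the extended Ala-X-Ala references reproduce the published tripeptide
scale (Ala 105.0 vs 102.7 Å², Trp 249.0 vs 251.8 Å²; six of seven residues
within ±5 Å², Pro +5.9 Å²) and the full ordering
Trp > Phe > Leu > Ile > Val > Pro > Ala exactly. A bare-element radii set
(C 1.70 Å) was rejected because it underestimates that scale by up to
22 Å².

rhSASA is the whole-residue area (backbone + side chain) of the seven
hydrophobic residues Ala, Leu, Val, Ile, Phe, Pro, Trp — consistent with
the whole-residue Ala-X-Ala reference convention; a side-chain-only switch
exists. A residue is *buried* iff rhSASA < 50 Å² (strict). Hydrophobic
patches are connected components over exposed (rhSASA ≥ 50 Å²) hydrophobic
residues, with an edge when any inter-residue atom pair is within
r_i + r_j + 0.5 Å; the 0.5 Å tolerance is the reproducible reading of
"van der Waals contact" and is exposed as a parameter. Patch area is the
sum of member rhSASA. In folded/unfolded group comparisons a residue is an
exposure *hotspot* when its unfolded-group mean rhSASA exceeds the
folded-group mean by more than 3 Å² — a threshold matched to the exposure
contrast of the pseudo-atomic toy (group-mean sampling noise is an order
of magnitude smaller); for all-atom ensembles, where meaningful exposure
changes are tens of Å², users should raise it.

### Tripeptide builder

Extended (φ = ψ = ω = 180°) peptides are built from ideal internal
coordinates (Engh–Huber-style backbone; per-residue side-chain templates
with extended χ angles and planar rings) via natural-extension (NeRF)
placement. Leucine uses the mt rotamer (χ1 = −60°, χ2 = 180°), its most
exposed ideal rotamer, fitting the maximally-exposed-reference purpose.
Proline keeps the extended backbone with an approximate ring template; the
slight strain is irrelevant at surface-area resolution.

### Descriptors, PCA, entropy

RMSF and PCA superpose frames onto an iteratively refined mean (superpose →
mean → re-superpose, 5 iterations; the reference structure for fluctuation
analysis is otherwise arbitrary). PCA diagonalises the 3N Cα covariance;
the reported "concerted-motion magnitude" is defined here as the square
root of the first eigenvalue (Å) — the RMS amplitude of the dominant
collective mode — and the raw spectrum is returned so other definitions
can be applied. The Schlitter entropy

S = (k_B/2) · ln det(1 + k_B T e²/ħ² · M σ)

uses the mass-weighted positional covariance σ (Å² → m²), uniform carbon
mass for all-Cα covariances, and is reported per mole (multiplied by
Avogadro's number), in J·mol⁻¹·K⁻¹. It is an upper bound and is monotone
in the covariance scale. Free-energy surfaces are −k_B T ln(P/P_max) on a
2-D histogram, minimum-shifted to zero; empty bins are NaN, never a
sentinel.

### Interactions

Ionic interactions follow the six-distance rule: between a positive
residue's charged side-chain atoms (Arg NE/NH1/NH2; Lys NZ) and a negative
residue's (Asp OD1/OD2; Glu OE1/OE2), the interaction is present in a
frame iff the minimum cross distance is strictly below 4 Å. Lys/Glu extend
the rule beyond the Arg/Asp case for generality. Hydrogen bonds use
donor–acceptor ≤ 3.0 Å and, when hydrogens are present, a D–H···A angle
within 20° of linear (the cited visualisation tool's defaults); without
hydrogens the criterion degrades to distance-only with a logged notice.
Block errors cut a series into consecutive 10 ns blocks (trailing partial
block discarded, ≥ 2 blocks required) and report the mean and *sample*
standard deviation of block means.

### REMD bookkeeping

"Exponentially distributed" replica temperatures are implemented as the
geometric ladder T_k = T_min·(T_max/T_min)^((k−1)/(n−1)); with endpoints
281.85/339.88 K and 16 replicas this reproduces the published ladder to
two decimals at 14 of 16 positions (the other two differ by one unit in
the last digit) with 300.00 K sixth and 319.32 K eleventh. Linear spacing
reproduces none beyond the endpoints, which fixes the interpretation.
Exchange acceptance is p = min(1, exp[(β_i−β_j)(E_i−E_j)]) with k_B in
kcal·mol⁻¹·K⁻¹ by default; attempts alternate even/odd neighbour pairs
(the standard schedule; the attempt pairing is unstated upstream). The
exchange simulator draws per-replica Gaussian energies — a diagnostic
device, not molecular dynamics.

## The synthetic toy and what it shows

The generator caricatures a two-sheet β-sandwich at pseudo-atomic
resolution: two rigid straight strands of Cα + one side-chain sphere per
residue (3.8 Å spacing), stacked face to face across a wedge-shaped gap
(3.4 Å at the tight end widening to 5.2 Å). Interior tight-end positions
carry hydrophobic residues whose side chains point into the gap; flanking
polar side chains lean over the run so its outer face is shielded, as
flanking residues do in a real sheet. By construction the native state has
≥ 10 inter-block native contacts and every interface hydrophobe below the
50 Å² burial threshold.

Unfolding is a rigid-body separation of the second block scaled by a
coordinate λ (1 Å per unit). Because the wedge puts the wide-end contacts
near the 6.5 Å cutoff, contacts peel progressively from the wide end
inward — the contact fraction is non-increasing in λ — while every
interface residue's exposure rises together (non-decreasing in λ). Planted
ensembles mix such states with known weights and add isotropic Gaussian
coordinate noise (default σ = 0.1 Å, chosen so that the two planted states
remain resolvable by RMSD clustering at toy scale); state draws and noise
use separate child streams of one root seed, so adding one kind of draw
never perturbs the other.

Passing the planted-recovery suite shows the *operators* are correct:
clustering recovers planted populations, the 60 % rule recovers planted
fold labels, grouped rhSASA flags the planted interface, and patch area
grows with unfolding. It does **not** show that the pipeline's biological
conclusions transfer to all-atom ensembles: the toy has no real side-chain
chemistry, its exposure contrasts are a few Å² rather than hundreds, its
states are rigid rather than locally flexible, and absolute Schlitter
entropies or RMSF values on it are not comparable to protein values.
Reproducing any published trajectory-dependent number (cluster
populations, entropies, patch areas of a specific protein) is explicitly
out of scope — those require the original trajectories, which were not
deposited.

## Numerical and scale choices

- Strict inequalities at every printed threshold (6.5, 4.0, 50 Å²; the
  60 % fold rule alone is inclusive, "60 % or greater").
- All tie-breaks (GROMOS centres, medoids, label order) resolve to the
  lowest frame index; all stochastic components are seeded.
- The demo/recovery study uses 500 frames of a 16-residue toy with weights
  0.9/0.1 and states at ~75 %/~45 % native contacts; at these sizes the
  full pipeline runs in seconds on one core, and the pairwise-RMSD stage
  subsamples nothing. The demo maps its 500 frames onto a 130 ns span so
  the 10 ns block and 20 ns window machinery is exercised end to end.
- PDB I/O is delegated to biotite (coordinates to 3 decimals, hence 1e-3 Å
  round-trip tolerance); an independent biotite SASA call serves as a
  cross-check oracle in the tests, never as the implementation.

## Known limitations

- Multi-chain inputs are carried through but the toy, and therefore the
  planted validation, is single-chain.
- Hydrogen-bond typing is an N/O heuristic, not a force-field topology;
  His tautomers and unusual donors are approximated.
- The hotspot threshold default (3 Å²) is toy-scaled, as discussed above.
- Binary trajectory formats and mmCIF are out of scope; convert to
  multi-model PDB first.
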
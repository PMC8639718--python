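# crystalens

Conformational-ensemble analysis for crystallin-like β-sandwich proteins.

Eye-lens and microbial βγ-crystallins are built from interlocked Greek-key
motifs; destabilising point mutations shift their conformational ensembles
toward partially unfolded states that expose continuous hydrophobic surface
patches — candidate self-association sites on the path to aggregation (and,
in lens crystallins, cataract). Replica-exchange molecular dynamics (REMD)
samples such ensembles, but turning a raw trajectory into the statements a
structural biologist cares about — *which conformational states exist, how
populated they are, which are still folded, and how much aggregation-prone
surface they expose* — requires a reproducible analysis chain. `crystalens`
implements that chain as a tested library plus a thin CLI, together with a
synthetic toy-protein generator so every stage can be validated against
planted ground truth without the original trajectories.

## What it computes

Given a native reference structure and a multi-model PDB ensemble:

- **Native-contact fraction.** The reference set is all Cα–Cα pairs closer
  than 6.5 Å and at least 3 residues apart in the native structure; a
  frame's foldedness is `Q(t) = 100 · |retained contacts| / |reference|`.
  A cluster with mean Q ≥ 60 % is classified **folded (F)**, otherwise
  **unfolded (U)**.
- **Conformational clustering** of the pairwise Kabsch-minimised Cα-RMSD
  matrix, two ways: GROMOS max-neighbour peeling (5 Å cutoff, used for
  convergence diagnostics in 20 ns windows together with the cluster
  entropy −Σ Pⱼ ln Pⱼ), and network clustering (edges below 3.5 Å or the
  distribution mean; clusters = connected components, with populations,
  medoid centroids, and an exportable edge list).
- **Hydrophobic exposure.** Rolling-ball (Shrake–Rupley) SASA with a 1.4 Å
  probe on a deterministic Fibonacci lattice; per-residue hydrophobic SASA
  (rhSASA) for Ala/Leu/Val/Ile/Phe/Pro/Trp; residues below 50 Å² are
  *buried*; connected exposed hydrophobic residues form surface patches
  whose combined area is the aggregation-propensity readout. Extended
  Ala-X-Ala tripeptides built from ideal geometry provide the
  maximally-exposed reference scale.
- **Descriptors and thermodynamic summaries.** Rg, RMSD to the reference,
  per-residue RMSF about an iteratively refined mean, Cα-covariance PCA,
  two-coordinate free-energy surfaces −k_BT ln(P/P_max), Schlitter
  upper-bound configurational entropy, ionic interactions (any of the
  positive/negative side-chain atom distances < 4 Å), VMD-style hydrogen
  bonds, and 10 ns block-averaged error bars.
- **REMD bookkeeping.** Geometric (exponential) temperature ladders
  `T_k = T_min (T_max/T_min)^{(k−1)/(n−1)}`, Metropolis exchange
  probabilities `p = min(1, exp[(β_i − β_j)(E_i − E_j)])`, synthetic
  exchange-rate diagnostics and replica-walk demultiplexing.

## Worked example

The built-in demo plants a two-state toy ensemble — 90 % of frames from a
mostly folded state (~75 % native contacts), 10 % from a partially unfolded
state (~45 %) in which the toy's buried hydrophobic interface becomes
exposed — and then recovers that truth with the full pipeline:

```bash
crystalens demo --seed 1 --out demo_output
```

prints the recovered cluster table:

```
 cluster  population_pct  native_contacts_mean_pct  native_contacts_sd_pct fold_label  centroid_frame
       1            92.6                      81.9                     4.6          F             310
       2             7.4                      49.1                     4.1          U              93
```

Cluster 1 (92.6 % of frames, mean 81.9 % native contacts) is labelled
folded; cluster 2 (7.4 %, 49.1 %) is unfolded — matching the planted 90/10
mixture within sampling noise. The accompanying report
(`demo_output/report/`) contains the per-residue RMSF, the grouped
folded-vs-unfolded rhSASA with exposure hotspots (here exactly the four
planted interface hydrophobes, residues 2, 3, 10 and 11), per-centroid
hydrophobic patches, the convergence series, and a summary with the
Schlitter entropy and cluster entropy of the run. The demo exits non-zero
if any planted quantity is not recovered.

Library use mirrors the CLI:

```python
from crystalens import (read_pdb_ensemble, assign_radii, select_atoms,
                        reference_contacts, contact_fraction_series,
                        pairwise_rmsd_matrix, network_cluster)

native = assign_radii(read_pdb_ensemble("native.pdb"))
ens = assign_radii(read_pdb_ensemble("ensemble.pdb", frame_interval=2.0))
ref = reference_contacts(native.models[0])          # 6.5 Å, ≥3 separation
q = contact_fraction_series(ens, ref)               # % per frame
ca = select_atoms(ens.models[0], "CA")
clusters = network_cluster(pairwise_rmsd_matrix(ens, ca), "auto")
```

Reference surface areas come from the tripeptide builder: under the
package's united-atom radii the extended Ala-Ala-Ala central residue gives
105.0 Å² and Ala-Trp-Ala gives 249.0 Å², with the full hydrophobic ordering
Trp > Phe > Leu > Ile > Val > Pro > Ala.

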
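# scanpsn

Structure-network and mutational-scan analysis of protein conformational
ensembles, built around the dimeric SCAN domain of zinc-finger
transcription factors.

A SCAN domain is an ~80-residue five-helix protein-protein interaction
module that functions as a (often domain-swapped) dimer. Studying how
cancer-associated substitutions perturb such a domain requires combining
several desk-scale computations around a conformational ensemble — an NMR
conformer bundle or a trajectory sample. `scanpsn` implements those
computations as a tested, reusable library:

- **Ensembles** (`scanpsn.ensemble`) — multi-model PDB (and plain tabular)
  I/O into a uniform frame stack (coordinates in nm), mass-weighted
  side-chain centers of mass, and equally spaced frame subsampling.
- **Protein structure networks** (`scanpsn.psn`) — nodes are the
  non-glycine residues; an edge joins residues whose side-chain centers of
  mass lie within a cutoff (default 0.5 nm) in a frame, and survives only
  when the contact occurs in at least a fraction *p*<sub>crit</sub>
  (default 20%) of frames. On top: hub detection (degree ≥ 3 by default),
  connected components with zero-degree "orphans", *all* minimal-hop
  communication paths annotated with occurrence-weight sums and averages,
  cutoff-sensitivity diagnostics (flagging collapsed networks), and
  jack-knife convergence under leave-10%-out frame blocks.
- **Saturation-mutagenesis ΔΔG** (`scanpsn.ddg`) — pooling of per-mutation,
  per-conformer, per-run ΔΔG records into position × 19-substitution scan
  matrices; the empirical linear correction
  ΔΔG<sub>exp</sub> = m·ΔΔG<sub>pred</sub> + b with m = 1/1.14 ≈ 0.877 and
  b = 0.078/1.14 ≈ 0.068 (from inverting the published calibration
  ΔΔG<sub>pred</sub> = −0.078 + 1.14·ΔΔG<sub>exp</sub>); mutant unfolding
  free energies ΔG<sub>u</sub> = ΔG<sub>u,WT</sub> + m·ΔΔG + b; neutral /
  deleterious classification at 1.6 kcal/mol (twice the 0.8 kcal/mol
  typical prediction error); stability-vs-binding categories and hotspot
  detection.
- **NMR validation** (`scanpsn.nmr`) — the chi-square-like shift statistic
  χ² = 1/(s−1) · Σ<sub>j</sub> (mean<sub>i</sub> δ<sub>ij</sub> −
  δ<sub>exp,j</sub>)² / δ<sub>exp,j</sub> per atom type and pooled, its
  running (cumulative-frame) curve, NOE distance differences under linear
  or r⁻⁶ averaging with short/long/intermolecular categorization
  (long = same chain, > 4 residues apart), RMSIP overlap of the leading
  Cα-fluctuation principal subspaces of two ensembles, and the histidine
  tautomer call from the CD2 shift (< 122 ppm → Nε2-H).
- **Annotation** (`scanpsn.annotate`) — consensus over seven
  variant-effect predictors at their published cutoffs, the −2.39 kcal/mol
  docking-energy filter, and paired tumor/normal expression network values
  (node = |Δ median log2(count+1)|, edge = Pearson r of per-patient log2
  changes).
- **Synthetic data** (`scanpsn.synthetic`) — seeded generators for every
  input with planted ground truth: toy dimer ensembles with exact contact
  persistences, scan records with planted hotspots, shifts/NOEs as
  truth-plus-noise, predictor tables with planted consensus classes, and
  negative-binomial paired count matrices with planted fold changes and
  change correlations.

## Worked example

```python
from scanpsn import synthetic as syn
from scanpsn.psn import PsnConfig, build_psn, find_hubs, shortest_paths

specs = [
    syn.ContactSpec(("A", 1), ("B", 1), persistence=1.0),
    syn.ContactSpec(("A", 2), ("B", 2), persistence=0.5),
    syn.ContactSpec(("A", 3), ("B", 3), persistence=0.15),
]
ens = syn.make_dimer_ensemble(20, 5, specs, seed=7)
net = build_psn(ens, PsnConfig(distance_cutoff=0.5, p_crit=0.20))
for a, b, occ in net.edges:
    print(a, b, f"occurrence={occ:.2f}")
```

prints

```
ALA1:A ALA1:B occurrence=1.00
ALA2:A ALA2:B occurrence=0.50
```

The pair planted at 15% persistence is filtered out by the 20%
*p*<sub>crit</sub> rule; the other two edges carry their exact planted
occurrence fractions as weights. `shortest_paths(net, source, target)`
then reports every minimal-hop route between two residues with the sum and
average of its edge weights on the percent scale (a 7-node path with
weight sum 411.6 averages 411.6/6 = 68.6), and `find_hubs(net)` lists
residues with degree ≥ 3.

The same pipeline is scriptable from the shell:

```sh
scanpsn simulate ensemble --n-frames 20 --residues-per-chain 5 --out ens.pdb
scanpsn psn build ens.pdb --out edges.tsv --graphml net.graphml
scanpsn psn cutoff-scan ens.pdb --cutoffs 0.5,0.55
```

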
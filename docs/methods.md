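# Methods

This note documents the models, conventions and numerical choices behind
`scanpsn`, and what the synthetic-data generators do and do not emulate.

## Ensemble representation

An ensemble is an ordered stack of frames over one fixed atom/residue
composition. Coordinates are converted from PDB Ångström to nanometres on
load and kept in nm throughout, so all contact cutoffs are stated in nm.
Author residue numbering from the input file is preserved verbatim
(1-based, no renumbering). Every model of a multi-model file must list the
same atoms in the same order; the first offending model is named in the
load error, and residue names outside the twenty standard amino acids are
rejected.

Side-chain centers of mass are mass-weighted means over the residue's
atoms excluding the backbone N, CA, C, O (and OXT) and backbone-attached
hydrogens. Heavy atoms only by default — whether side-chain hydrogens
should contribute is a genuinely open convention, so a flag
(`include_hydrogens=True`) offers the alternative. Masses come from a
standard element table with per-atom-name overrides for force-field mass
redefinitions. Glycine has no side chain and is excluded explicitly, both
from center-of-mass computation and as a network node.

Frame subsampling keeps `k` equally spaced frames including both
endpoints, with index `i → round(i·(N−1)/(k−1))`; `k = 1` returns the
first frame by convention. The canonical use is thinning a long trajectory
to ~500 frames before shift/NOE back-calculation comparisons.

## Protein structure network

Two non-glycine residues are in contact in a frame when their side-chain
centers of mass are within the distance cutoff; the boundary is inclusive
(`d ≤ cutoff`), configurable. The edge weight is the occurrence: the
fraction of frames containing the contact. Edges below the critical
persistence `p_crit` (default 0.20) are removed. Default cutoff is 0.5 nm;
0.55 nm is the natural comparison point, and the cutoff diagnostic flags a
value as "collapsed" when the largest connected component holds more than
a configurable fraction (default 80%) of the nodes — the signature of a
cutoff too generous to resolve network structure.

Hubs are nodes whose degree meets the threshold. Two conventions circulate
("at least three" vs "more than three" edges); the default is degree ≥ 3
with `strict=True` selecting the exclusive comparison. Connected
components are the standard undirected components restricted to nodes with
at least one edge, sorted by descending size then smallest residue;
zero-degree nodes are reported separately as orphans.

Communication paths between two residues are *all* paths of minimal hop
count (every directly connected pair is at distance one); ties are never
broken silently, and paths are ordered lexicographically by node sequence.
Each path carries its per-edge weights, their sum and their average. The
reporting scale for these weights is the occurrence percentage (0–100) by
default — the literature does not pin down an absolute scale for such path
weights, so the factor is configurable (`weight_scale`); the arithmetic
identity avg = sum / edge-count holds on any scale.

Jack-knife convergence splits the frame axis into `round(1/drop_fraction)`
contiguous blocks (boundaries rounded down), discards each block in turn,
rebuilds the network, and reports per-block edge-set Jaccard similarity,
hub-set Jaccard and top-5 component sizes against the full-ensemble
network. `drop_fraction = 0` degenerates to a single self-comparison with
similarity 1. Two empty sets have Jaccard 1 by convention.

Graph algorithms (components, all shortest paths) are delegated to
networkx; the test suite verifies both against independent brute-force
oracles (union-find; exhaustive breadth-first path enumeration) on
a thousand random graphs of up to 12 nodes.

## ΔΔG scan aggregation and correction

Raw records are one predicted ΔΔG (kcal/mol, positive = destabilizing) per
mutation × conformer × run — e.g. 20 conformers × 5 runs per mutation. A
cell (position, substitution; plus mutated chain for dimer scans) is
aggregated as the arithmetic mean over all pooled records with the sample
standard deviation; runs within conformers are *not* averaged
hierarchically first, which is identical for balanced designs and simpler
otherwise. Completeness is enforced: each scanned position must carry all
19 substitutions of its wild type, so a monomer scan over the 94 domain
positions 35–128 yields exactly 94 × 19 = 1786 cells and a two-chain dimer
scan 3572.

The correction to experimental scale inverts the published calibration of
the predictor against experimental unfolding data,
ΔΔG_pred = −0.078 + 1.14·ΔΔG_exp, giving m = 1/1.14 = 0.877 and
b = 0.078/1.14 = 0.068. (Quoting the forward relation's intercept, 0.078,
as the corrected-scale intercept is a common slip; the algebraically
consistent value is 0.068, which is the default here.)

Mutant unfolding free energies use the additive form
ΔG_u,mut = ΔG_u,WT + m·ΔΔG + b with ΔG_u,WT defaulting to 5 kcal/mol, a
mid-range reference for small helical domains when no experimental value
exists. Thermodynamic convention would subtract a destabilizing ΔΔG; the
subtractive form is available behind an explicit flag
(`subtractive=True`) and never substituted silently.

Classification is deleterious iff mean ΔΔG strictly exceeds 1.6 kcal/mol
(twice the predictor's typical 0.8 kcal/mol error); the boundary falls on
the neutral side, with an `inclusive` option. Stability and binding means
combine into four categories (neutral / stability-only / binding-only /
both). Hotspots are positions where at least a minimum fraction (default
one half) of the 19 substitutions classify deleterious, sorted by that
fraction.

## NMR cross-validation

The shift statistic for a group of s shifts over n frames is

    chi2 = 1/(s−1) · Σ_j ( (1/n Σ_i δ_ij − δ_exp,j)² / δ_exp,j )

with the frame mean taken first. The per-shift experimental value appears
in both the squared deviation and the denominator — the only reading under
which the sum is well formed — which is why experimental shifts of exactly
zero are rejected at construction. The statistic is reported per atom name
(the backbone atom types of the usual convergence panels) and pooled; a
group needs s ≥ 2. The running variant recomputes the pooled statistic
over growing frame windows; for predictions with a stationary systematic
offset the curve converges to the offset's bias term, while for unbiased
noise it decays like 1/n by construction.

NOE differences are signed: (ensemble-average distance − target distance),
per restraint, grouped into short (same chain, ≤ 4 residues apart), long
(same chain, > 4 apart) and intermolecular categories. Averaging is linear
(arithmetic mean over frames) by default, matching the straightforward
back-calculation procedure; the spectroscopic convention
(mean d⁻⁶)^(−1/6) is available as `averaging="r6"` and never exceeds the
linear mean (power-mean inequality, property-tested). Target distances are
treated as targets, not upper bounds, so bound-style analyses remain
possible downstream. Restraints are taken at face value per atom pair; no
pseudo-atom corrections or r⁻⁶ summation over equivalent protons is
applied.

RMSIP superposes each ensemble's frames onto its mean Cα structure
(two-pass least-squares fit: first to frame 0, then to the resulting mean),
diagonalizes the 3N×3N covariance matrix of Cα fluctuations, and computes
√(1/n_modes · Σ_ij (v_i·w_j)²) over the first n_modes (default 20)
eigenvectors of each ensemble. The value is 1 for identical subspaces and
0 for orthogonal ones; both ensembles must share the Cα set and have at
least n_modes frames. The alignment reference (ensemble mean) is a
documented choice — the literature rarely states it.

The histidine tautomer rule maps a CD2 carbon shift strictly below 122 ppm
to Nε2-H and anything else (including exactly 122) to Nδ1-H.

## Annotation computations

Predictor consensus applies each method's published cutoff: Provean
< −2.5, Mutation Assessor > 2, PolyPhen-2 and PON-P2 > 0.5, SNAP2 < 0,
MutPred > 0.75, and Align-GVGD classes C45/C55/C65 damaging. The SNAP2
rule is implemented as printed even though that tool's native convention
is the opposite (positive score = effect); the direction is configurable.
Missing scores are excluded from the consensus denominator rather than
counted as neutral; a complete consensus means every *scored* method votes
deleterious.

The docking filter retains complexes with energy strictly below
−2.39 kcal/mol ("lower than" is strict; the boundary value is dropped).

Expression network values operate on a gene × sample count matrix with
tumor/normal condition and patient labels. Node value:
|median log2(tumor+1) − median log2(normal+1)|. Edge value: Pearson r of
per-patient log2(tumor+1) − log2(normal+1) change vectors (only patients
with exactly one sample per condition participate) — the correlation of
expression *changes*, which matches the paired-sample reading of such
network annotations; a `tumor_only` mode correlating log2 counts across
tumor samples covers the alternative reading. Zero-variance inputs yield
NaN with a warning, never a silent 0. The annotated graph exports to
GraphML with `abs_log2_median_diff` node and `pearson_r` edge attributes.

## Synthetic generators

All generators are pure functions of their arguments and a seed
(bit-identical reruns), and at zero noise every downstream statistic hits
its planted truth exactly.

*Ensembles.* Residues are minimal rigid bodies (backbone N/CA/C/O plus a
single CB pseudo-atom that *is* the side-chain center of mass), spread on
a far-apart grid (2 nm spacing, chains 6 nm apart) so only planted pairs
can touch. Each planted pair sits at its contact distance (default
0.45 nm) in a prefix of a seeded frame permutation of length
round(persistence · n_frames) — exact persistence even for tiny ensembles
— and at its separated distance (0.65 nm) otherwise, before isotropic
Gaussian coordinate noise. This exercises center-of-mass, contact and
persistence logic but contains no rotamer realism, secondary structure or
correlated dynamics: passing recovery tests shows the bookkeeping is
right, not that real trajectories are well behaved.

*Scans.* Neutral cells draw true means uniformly in [−0.5, 0.9] kcal/mol
and hotspot cells in [2.2, 4.0], leaving ≥ 0.5 kcal/mol margin on each
side of the 1.6 threshold; records add Gaussian noise (default sd
0.2 kcal/mol, 100 records per cell, so cell-mean standard errors are
~0.02).

*Shifts/NOEs.* Experimental values equal the truth table; predictions add
per-frame Gaussian noise, so E[chi2] = (s/(s−1))·mean(σ²/(n·δ_exp)) —
verified against simulation. NOE targets are the true linear
ensemble-average distances plus jitter, with per-category counts met
exactly.

*Predictor tables.* Scores are drawn uniformly on the planted side of each
method's cutoff; "mixed" mutations get at least one vote on each side.

*Paired counts.* Counts are negative binomial (variance μ + φμ², default
dispersion φ = 0.01) around baseline means (default 1000). The
per-patient tumor log2 change of gene g is
fc_g + sd_g·(√ρ_g·z_p + √(1−ρ_g)·ε), with z a shared per-patient latent
factor, so two genes with loadings ρ_g, ρ_h have change correlation
≈ √(ρ_g·ρ_h). At these defaults the count noise contributes ~0.2 log2
units per paired change: fold-change recovery uses the default change sd
of 0.3 (median standard errors well under 0.1 at 100 patients), while
correlation-recovery checks use change sd 1.5, where the noise attenuates
a planted correlation of 0.9 by only ~2%. Real tumor/normal data differ in
every distributional respect; only the paired structure, median shifts and
change correlations are emulated.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data at
deliberately small sizes — 500-frame ensembles for persistence recovery,
200 frames for jack-knife stability, 100 records per scan cell, 500
replicates for chi-square expectations, 100 patients for count recovery,
and 1000 random graphs for the oracle-equivalence suites — chosen so each
check is statistically decisive at its stated tolerance. All randomness
flows through explicit integer seeds.

## Known limitations

- The PDB reader takes the first altloc only and performs no structure
  repair; hetero residues and solvent are rejected rather than skipped.
- Path weights beyond occurrence (interaction energies, typed contacts)
  and centrality measures beyond degree are out of scope.
- The chi-square statistic is undefined for shifts near zero by
  construction; callers with sign-alternating shift types should group
  them per atom type (the default) so denominators stay homogeneous.
- The empirical ΔΔG correction is a global linear map; it does not model
  mutation-class-specific biases.
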
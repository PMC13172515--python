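# Methods

## Soft contact counting

The interface statistic between chains A and B is

    AB_cnts = Σ_{i∈A} Σ_{j∈B} σ(|r_ij|),   σ(r) = 0.5 − 0.5 · tanh((r − a)/b)

with the sums over selected atom pairs. σ is the unique smooth step that
equals 0.5 exactly at the cutoff `a`, tends to 1 well below it and to 0
well above it, with the transition width set by `b`; it counts
interactions below the cutoff (`r ≤ a`) without a hard discontinuity.
Defaults: `a = 5 Å, b = 0.5 Å` over heavy (non-hydrogen) atoms for
all-atom structures; `a = 10 Å, b = 1.0 Å` over one designated bead per
residue (name "BB", configurable) for coarse-grained models, whose larger
beads justify the looser cutoff.

Residue-pair weights are the *sum* of σ over the residues' atom pairs,
not a maximum or a binarized count — so a residue pair with many close
atoms weighs more than a grazing one. A binarized view (threshold 0.5)
is available for plotting. Distance maps report the minimum selected-atom
Euclidean distance per residue pair.

Numerical notes: in float64, σ underflows to exactly 0 for
`r ≳ a + 19b`; strict monotonicity therefore holds only within the
resolvable range, which the tests respect. No periodic-boundary
minimum-image convention is applied: inputs must be whole molecules,
which is the normal state of post-processed simulation output and of
predicted models. Trajectory frames are scored independently; no
smoothing across frames.

## LIR scanning and LDS binding-mode classification

The LIR core consensus is the 4-residue window `[W/F/Y]-x-x-[L/I/V]`.
Scanning is core-only — no upstream acidic-residue weighting or PSSM
scoring — and reports all windows, overlapping ones included.

The LDS of an ATG8 protein is described by two disjoint pocket residue
sets (HP1, which receives the aromatic core position, and HP2, which
receives the hydrophobic one). Pocket residue sets are configuration;
shipped defaults for GABARAPL2 and LC3B are curated from conserved
hydrophobic-pocket annotations and should be overridden when an analysis
has structure-specific definitions.

A candidate occupant is either a LIR motif (atoms of the 4 core residues
plus a flank of 2 on each side, configurable) or a whole chain. For each
candidate the classifier computes soft-contact weight against HP1 and
HP2 separately, then applies three explicit thresholds:

- `min_weight = 1.0`: minimum total (HP1+HP2) weight for any engagement.
  One fully formed atom contact contributes ~1, so this demands roughly
  one buried contact overall.
- `min_pocket_weight = 0.25`: each pocket individually must be engaged —
  a genuine LIR docking buries residues in both pockets.
- `margin = 0.10` (relative): if the top two eligible candidates are
  within 10% of each other the call is "ambiguous"; ties break toward
  the lowest motif start. Models with no eligible candidate are
  "unoccupied".

These thresholds are design choices, not published constants; every
occupancy summary echoes the thresholds it used. Ensemble occupancy
classifies each model independently and reports counts and percentages
per mode label. The synthetic binding-mode generator guarantees a
planted occupant's total pocket weight around 12 and rival weights near
0, so classification margins exceed the thresholds by an order of
magnitude and label recovery is exact by construction.

## Interactor calling

Input LFQ matrices are linear-scale; preprocessing converts zeros to
missing, takes log2, and drops proteins that fail a minimum-valid-values
rule (default 2) in every tested condition. Optional imputation draws
missing values per sample from a downshifted normal,
`Normal(mean − 1.8·sd, (0.3·sd)²)` of the sample's observed
distribution — the convention popularised by Perseus for
left-censored proteomics missingness; whether it ran is recorded.

Per protein, a two-sample Student t-test with pooled variance (Welch by
flag) compares bait vs control; `difference` is the log2 mean difference.
The interactor rule is the conjunction: one-sided (bait > control)
p-value passing a 5% FDR correction AND linear enrichment factor
`2^difference ≥ 2`. Benjamini–Hochberg step-up is the default FDR method
and is implemented directly (the canonical `q_(i) = min_{j≥i} p_(j)·m/j`
with step-up monotonicity) so that it is bit-for-bit the textbook
formula; a group-label permutation FDR (null-exceedance ratio of the t
statistic, monotone in the observed ranking) is available because
different analysis platforms default to it. Untestable proteins (fewer
than two valid values in a group) are excluded from the FDR denominator.
Volcano coordinates use the two-sided p-value by default while the call
stays one-sided; both are reported.

Fold-change gates between two conditions use linear-scale means with an
inclusive threshold (`ratio ≥ 2`); heatmap values are z-scores of
per-condition average log2 intensity across conditions (sample sd,
ddof 1), with constant rows set to 0 and flagged.

## Flux statistics

Flux readouts are per-cell ratios (marker-in-lysosome / marker-total,
surface / total); cells with non-positive or missing denominators are
excluded and counted. Normalization divides by the mean of a reference
group (e.g. untreated wild type) within each stratum (experiment or
replicate), making the reference mean exactly 1 per stratum; both
per-well-then-normalize and per-cell-normalize paths are supported and
must be selected explicitly because published panels differ in which
they use.

Group tests: two-sided one-sample t against 1 for normalized grouped
conditions (sd = 0 samples are flagged untestable rather than tested);
two-sided Wilcoxon rank-sum between groups — exact enumeration when the
combined sample is tie-free and n ≤ 25, otherwise the normal
approximation with tie correction and continuity correction —
with Benjamini–Hochberg correction across each planned-comparison
family. Box summaries use linear-interpolation percentiles and Tukey
whiskers (most extreme points within 1.5×IQR of the box). FACS tandem
reporter analysis computes the per-sample mCherry/GFP MFI ratio
(orientation configurable) divided by the cell line's untreated mean.
Significance stars follow the p < 0.05 / 0.01 / 0.001 / 0.0001
convention.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (config, seed):

- **Two-chain complexes**: single-heavy-atom residues, chain A on a
  25 Å-spaced line, planted pairs at exact requested distances, all
  other inter-chain distances > 3 cutoffs. Isolates the σ arithmetic
  from geometry bookkeeping; two-atom residues behind a flag exercise
  the residue-pair summation.
- **Binding-mode ensembles**: per-mode counts by largest-remainder
  rounding (so fraction recovery is exact at any n); model order
  shuffled with the seeded generator.
- **Decay trajectories**: one chain rigidly translated by a fixed step
  per frame, so the contact series is non-increasing by construction.
- **LFQ matrices**: per-protein baseline log2 abundance
  Normal(25, 2), spike shifts in the bait group, replicate noise
  Normal(0, sd²), missingness completely at random.
  Intensity-dependent (left-censored) missingness is deliberately not
  modelled: it would change the imputation-calibration claims.
- **Cell tables**: per-group normal features truncated at zero, wells
  assigned round-robin (2 wells/group by default, mirroring typical
  technical duplicates).
- **FACS tables**: reporter ratio = base × condition effect ×
  (1 + noise), GFP MFI around 10⁴.

None of the generators emulate model-confidence scores, force-field
energetics, spectral noise, ragged segmentation artefacts, or batch
effects. Passing tests therefore demonstrate correctness of the
statistics and the geometry under clean, known-truth conditions — not
robustness to the failure modes of real instruments.

## Calibration and recovery suite sizes

The false-discovery calibration of the interactor rule uses 200 null
matrices of 2,000 proteins (3 vs 3, sd 0.3, no missingness); with no
true enrichment every call is false, so the per-replicate
false-discovery proportion is 1 when anything is called and 0 otherwise,
and its mean estimates the realised FDR. The conjunction with the
enrichment-factor gate makes the realised rate far below the nominal 5%.

The spike-recovery suite uses 100 matrices with 100 spiked proteins of
2,000 (5% true interactors, a typical pulldown yield) at log2 effect 3
and sd 0.3. With 3 replicates the noncentral-t signal
(ncp = 3/(0.3·√(2/3)) ≈ 12.2, df 4) puts per-protein recovery above
99.5% at the BH threshold implied by ~100 discoveries among 2,000 tests;
with only a handful of spiked proteins the BH threshold is much stricter
and that recovery level is not attainable — the suite's spike count is
part of its stated conditions.

The planted-effect recovery suite uses 100 cell tables with 500
cells/group and a +50% surface/total ratio shift; the rank-sum q-value
is below 0.05 in every replicate at this effect size.

## Known limitations

- The PDB reader implements fixed-column v3.3 ATOM/HETATM/MODEL records
  (altloc resolved to highest occupancy, tie to first encountered;
  insertion codes kept; numbering source-verbatim). mmCIF and binary
  trajectory formats are not supported.
- Exact Wilcoxon p-values are only used for tie-free samples; with ties
  the asymptotic tie-corrected path is taken regardless of n.
- The LDS classifier assumes the pocket definition and candidate list
  are correct; it measures geometry only and knows nothing about
  affinities or competition kinetics.
- Permutation FDR with 3-vs-3 groups has only 20 distinct label
  permutations; its resolution is correspondingly coarse.
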
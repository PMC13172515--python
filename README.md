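# hubscope

Analysis toolkit for studies of selective-autophagy hub complexes that
combine structural modelling, interaction proteomics and high-content
imaging. It covers four computational layers that such studies share:

1. **Soft-contact interface analysis** of two-chain protein complexes,
   model ensembles and trajectories (`hubscope.contacts`). The chain-pair
   contact count is
   `AB_cnts = Σ_{i∈A} Σ_{j∈B} σ(|r_ij|)` with the smooth switch
   `σ(r) = 0.5 − 0.5·tanh((r − a)/b)`, summed over heavy atoms
   (`a = 5 Å, b = 0.5 Å`) or one bead per residue for coarse-grained
   structures (`a = 10 Å, b = 1.0 Å`). Residue-pair contact and
   minimum-distance maps come from the same machinery.
2. **LIR/LDS binding-mode classification** (`hubscope.lirlds`). LIR cores
   `[W/F/Y]-x-x-[L/I/V]` are scanned from sequence; for each model of an
   ensemble the classifier measures soft-contact weight between candidate
   occupants (a LIR motif or a whole partner chain) and the two
   hydrophobic pockets (HP1/HP2) of an ATG8 LIR-docking site, and
   aggregates per-mode occupancy percentages over the ensemble.
3. **Label-free interactome calling** (`hubscope.interactome`). Per
   protein, a pooled-variance Student t-test of log2 bait vs control LFQ
   intensities; interactors must pass a 5% FDR-corrected one-sided test
   with a linear enrichment factor ≥ 2. Volcano coordinates, pairwise
   fold-change gates and per-condition z-scores are provided alongside.
4. **High-content flux statistics** (`hubscope.fluxquant`). Ratio metrics
   per cell, normalization to an untreated reference (reference mean = 1
   per stratum), per-well aggregation, one-sample t-tests against 1,
   two-sided Wilcoxon rank-sum tests with Benjamini–Hochberg correction,
   Tukey box summaries, and tandem mCherry/GFP reporter MFI fold changes.

Every stage has a seeded synthetic-data generator with recorded ground
truth (`hubscope.synthdata`), so the whole pipeline is testable against
planted answers: planted interfaces, planted binding-mode fractions,
dissolving interfaces, spiked LFQ matrices, shifted cell populations.

## Worked example

Classify binding modes over a synthetic 25-model ensemble built with 72%
of models docking the LIR1 core into the LDS and 28% docking an
alternative partner:

```python
from hubscope import synthdata, lirlds

ens, lds, cands, truth = synthdata.gen_mode_ensemble(
    25, {"LIR1-LDS": 0.72, "ATG7-LDS": 0.28}, seed=42)
occ, calls = lirlds.ensemble_occupancy(ens, lds, cands)
print(occ.counts)        # {'LIR1-LDS': 18, 'ATG7-LDS': 7}
print(occ.percentages)   # {'LIR1-LDS': 72.0, 'ATG7-LDS': 28.0}
```

The classifier is purely geometric — it never sees the planted labels.
For the first model it reports pocket weights
`{'LIR1': (6.32, 5.65), 'ATG7': (0.0, 0.0)}`: the LIR1 core engages both
hydrophobic pockets with a total soft-contact weight of ~12 while the
alternative candidate is out of range, so the call is `LIR1-LDS` with a
margin of 11.96 over the runner-up.

Call interactors from a spiked LFQ matrix (100 enriched proteins of
2,000; log2 effect 3, replicate noise sd 0.3, 3 vs 3):

```python
from hubscope import synthdata, interactome

lfq, truth = synthdata.gen_lfq(2000, 100, 3.0, 0.3, 0.0, 3, seed=1)
log2, dropped = interactome.preprocess_lfq(lfq, ["bait", "control"])
enr = interactome.test_enrichment(log2, lfq, "bait", "control")
q = interactome.adjust_fdr(enr["p_one_sided"])          # Benjamini-Hochberg
res = interactome.call_interactors(enr, q)              # q<=0.05 AND factor>=2
print(res["interactor"].sum())   # 100  (all spiked, no false positives here)
```

The same operations are exposed on the command line (`hubscope simulate`,
`hubscope contacts`, `hubscope classify`, `hubscope interactome`,
`hubscope flux`, `hubscope facs`, `hubscope scan-lir`,
`hubscope validate`); see `hubscope --help`.

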
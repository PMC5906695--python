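# mutrec

Statistical discovery of positively selected non-coding somatic mutation
hotspots in tumor cohorts.

Tumor genomes accumulate passenger mutations at rates that vary strongly
along the genome — with replication timing, chromatin state, sequence
context, and per-patient burden. A focal region (for example a CTCF binding
site, CBS) recurrently mutated across patients is only evidence of positive
selection if the recurrence exceeds what that local background predicts.
`mutrec` implements the full chain for whole-genome cohorts of somatic
calls: artifact post-filters and sample QC, a covariate-aware per-patient
background mutation model, an exact Poisson-binomial recurrence test over
focal windows / gene non-coding regions / CBSs, and the downstream statistics
(functional-region enrichment, CBS rate profiles, motif spectra, SCNA
breakpoint coupling, VAF clonality, TAD-scoped expression association). A
synthetic-cohort generator with known ground truth makes every stage testable
without any external data.

## Model

Per-base, per-tumor background mutation probability:

    q_ij = logit^-1( b0 + b_pid(i) + Σ_c β_c x_c(j) )

fit as a binomial GLM on the frequency table of mutated/non-mutated site
counts per covariate combination and patient, after LASSO bootstrap stability
selection of the covariates (features selected in >95% of 100 half-sample
bootstraps, penalty per fit by 10-fold CV at the one-SE point).

For a region of length l, tumor i is mutated with probability
`p_i = 1 − Π_j (1 − q_ij)`, and the number of mutated tumors K follows the
Poisson-binomial distribution. A region with k mutated samples gets the exact
tail p-value Pr(K ≥ k) by dynamic-programming convolution (a refined normal
approximation with skewness correction serves as a fast prefilter only),
Bonferroni-corrected over the analyzable-genome base count (focal windows),
the gene count, or the CBS count. The CBS-specific model additionally
conditions on tumor subtype, loop-boundary status, and per-tumor signature-1
and signature-17 fractions, so a CBS can be called selected *beyond* the
genome-wide CBS rate elevation.

## Worked example

Simulate a 2 Mb, 50-patient cohort with a background of 1e-6 mutations per
base per patient and one planted 21 bp hotspot mutated in ~20% of patients,
then fit the background model and scan:

```python
from mutrec.simulate import SimulationConfig, HotspotPlan, simulate_cohort
from mutrec.pipeline import fit_patient_background
from mutrec.recurrence import scan_hotspots

cfg = SimulationConfig(
    seed=11, chrom_lengths={"chr1": 2_000_000}, n_patients=50, base_rate=1e-6,
    hotspots=[HotspotPlan("chr1", 1_000_000, 1_000_021, per_patient_prob=0.2)],
)
cohort = simulate_cohort(cfg)
rate_model = fit_patient_background(cohort.mutations, cohort.masked, cohort.patients)
results, hotspots = scan_hotspots(cohort.mutations, rate_model, cohort.masked)
for h in hotspots:
    print(f"{h['chrom']}:{h['start']}-{h['end']}  k={h['k']}"
          f"  p={h['p_value']:.3g}  p_adj={h['p_adjusted']:.3g}")
```

Output:

```
chr1:999991-1000031  k=7  p=9.79e-26  p_adj=1.96e-19
```

The cohort carries 83 mutations in total; the scan recovers exactly one
hotspot — the planted locus (windows around the 7 mutated samples' positions
merged into one interval). `p` is the exact Poisson-binomial tail for 7 of 50
patients mutated in a 21 bp window under the fitted per-patient background;
`p_adj` multiplies it by the 2,000,000 analyzable bases (the hypothesis
count), and stays far below the 0.01 significance cutoff. A null cohort
(drop the `hotspots` plan) reports no hotspots.

The same objects drive the other scans (`scan_genes_indel`, `scan_cbs`) and
the downstream statistics in `mutrec.downstream`. A thin CLI mirrors the
library: `mutrec simulate --preset cbs-rates --seed 1 --out DIR`,
`mutrec run-all --bundle DIR --out OUT`.

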
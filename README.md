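# txdrift

Transcriptional drift-variance analysis of aging transcriptomes.

As animals age, genes within the same pathway change expression in opposing
directions, eroding the co-expression ratios that characterize young adults.
`txdrift` quantifies this with two statistics. **Transcriptional drift** of
gene *g* at age *t* is its log-fold change relative to a young reference
profile,

```
td_g(t) = log2( (cpm_g(t) + c) / (cpm_g(young ref) + c) )
```

(*c* a small pseudocount), and **drift-variance** of a group of *n* genes is
the sample variance of their drift values,

```
dv = 1/(n-1) * Σ (td_i - mean(td))²
```

A young transcriptome has dv ≈ 0; dv grows monotonically with age and is a
transcriptome-intrinsic metric of physiological age. Treatments that slow
aging *attenuate* drift — treated animals' transcriptomes stay closer to
the young state than age-matched controls.

The package is aimed at researchers analyzing bulk RNA-seq (or microarray)
time courses across age, and provides:

- **io**: count/CPM matrices (TSV/CSV/MatrixMarket), GMT gene sets, sample
  annotations, life tables — validated readers and writers.
- **drift**: young-reference construction (pooled-mean or holdout, with
  circular-reference guards), drift matrices, per-group drift-variance with
  Tukey box-plot summaries, age binning, gene sub-sampling, leading
  log-fold-change MDS.
- **stats**: robust Levene (Brown–Forsythe family, 10% trimmed-mean center)
  dispersion tests, Welch/pooled t-tests, exact log-space binomial tests,
  per-gene attenuation calls, Spearman age correlation, Benjamini–Hochberg
  FDR.
- **mortality**: empirical hazard curves, Gompertz (h(t) = A·e^{Gt}) maximum-
  likelihood fitting, cohort simulation, Mantel–Haenszel log-rank tests, and
  Monte-Carlo power analysis for lifespan experiments.
- **simulate**: synthetic aging transcriptomes and lifespan cohorts with
  known ground truth (drift directions/rates, attenuation factor, hazard
  parameters) so every stage is testable without external downloads.
- a `drift` command-line tool orchestrating all of the above.

## Worked example

Simulate a two-arm aging experiment (3,000 genes, harvests at days 1/3/5/10
in triplicate, treatment attenuating drift rates by 60%), compute drift
against the pooled day-1 reference, and compare arms:

```python
from txdrift import (SyntheticConfig, generate_transcriptome, cpm_normalize,
                     build_young_reference, compute_drift, drift_variance,
                     robust_levene, GompertzModel, power_of_detection)

cfg = SyntheticConfig(n_genes=3000, ages=(1, 3, 5, 10), n_replicates=3,
                      attenuation=0.6, seed=42)
counts, annotations, truth = generate_transcriptome(cfg)
cpm = cpm_normalize(counts)
ref = build_young_reference(cpm, annotations, ref_age=1)
d = compute_drift(cpm, ref)

groups = {a.sample_id: f"{a.treatment} d{a.age:g}" for a in annotations}
for r in drift_variance(d, groups):
    flag = "  (reference age: not testable)" if r.self_referential else ""
    print(f"{r.group_label:<12} dv = {r.variance:.3f}{flag}")

frame = d.to_frame()
day10 = lambda arm: frame[[s for s in d.sample_ids
                           if s.startswith(f"{arm}_d10")]].to_numpy().ravel()
lev = robust_levene([day10("water"), day10("treated")])
print(f"robust Levene, water vs treated day 10: W = {lev.W:.1f}, p = {lev.p_value:.3g}")

model = GompertzModel.from_mean_lifespan(19.8, G=0.35)
res = power_of_detection(model, n_per_arm=1500, effect_days=1.0,
                         alpha=0.01, n_reps=200, seed=7)
print(f"power to detect a 1-day extension (n=1500/arm, alpha=0.01): {res.power:.2f}")
```

Output:

```
water d1     dv = 0.078  (reference age: not testable)
water d3     dv = 0.204
water d5     dv = 0.360
water d10    dv = 1.182
treated d3   dv = 0.165
treated d5   dv = 0.185
treated d10  dv = 0.316
robust Levene, water vs treated day 10: W = 5281.8, p = 1e-300
power to detect a 1-day extension (n=1500/arm, alpha=0.01): 1.00
```

Drift-variance of the untreated arm grows ~15-fold between day 1 and
day 10, while the treated arm at day 10 stays near the untreated day-3
level — the treatment has attenuated drift, and the robust Levene test
separates the two dispersions decisively (the day-1 group is flagged
because a pooled-mean reference makes its variance circular and unusable
for testing). The final line shows a lifespan experiment with 1,500
animals per arm detects a 1-day extension essentially always at α = 0.01.

The same analyses are available from the shell:

```
drift simulate --config sim.yaml --out-dir sim/
drift run --counts sim/counts.tsv --annotations sim/annotations.tsv --out-dir out/
drift power --mean-lifespan 19.8 --g 0.35 --n 1500 --effect-days 1 --alpha 0.01 --reps 500 --seed 7
```

`drift reproduce <recipe> --data-dir ...` runs the analysis presets for the
published external data sets (worm RNA-seq time course, dose response,
delayed treatment, two-channel microarray time course, mouse tissue panel,
human brain series); the data themselves are not bundled and the command
lists exactly which files it needs.

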
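# herbdna

DNA in herbarium and other historical specimens degrades in two measurable,
time-dependent ways: the backbone fragments (preferentially just 3′ of
purines, the footprint of depurination), and cytosines near fragment ends
deaminate, showing up as C→T substitutions at the 5′ read termini. `herbdna`
turns aligned, merged shotgun reads into the standard damage statistics of
that process and fits its kinetics across a collection-year-spanning cohort.
It is aimed at people working with historical collections — herbaria,
museum material, archival tissue — who need to quantify degradation,
authenticate historical DNA, or predict what older specimens will yield.

## The model

Fragment survival under i.i.d. per-bond breakage is exponential in length:

```
F(L) = F0 · e^(−λL)        ⇒   log F(L) = log F0 − λL
```

so the per-bond damage fraction λ of one library is the (negated) slope of
log fragment-frequency over the exponential tail of its length
distribution. If damage accrues at a constant per-site per-year rate *k*,

```
λ = k · age
```

and *k* is the slope of the through-origin regression of λ̂ on sample age.
The package also computes the lognormal length summary (log-mean, with
median = e^log-mean), the position −1 purine fold enrichment relative to
position −5 (break-point composition), the position-wise misincorporation
profile with the first-base C→T percentage (the deamination clock), and an
R-`aov`-style ANCOVA (`y ~ covariate × factor`, sequential sums of squares,
full-vs-additive model comparison) for contrasts such as nuclear vs
organellar reads or extraction protocols.

Because real historical cohorts are not reproducible at desk scale, the
package ships a ground-truth simulator (`herbdna.simdata`) that generates
damaged reads from exactly this model — geometric lengths, logistic
length-dependent recovery, purine-biased break points, geometrically
declining terminal deamination, uniform sequencing error — so every
estimator is validated by parameter recovery (`herbdna.validation`).

## Worked example

Simulate a five-sample cohort (ages 60–278 years, one nuclear and one
organellar contig), profile it, and fit the kinetics:

```yaml
# cfg.yaml
reference_year: 2015
outdir: demo_out
fasta: demo_out/reference.fa
sample_table: demo_out/samples.tsv
simulation:
  ages: [60, 120, 180, 240, 278]
  n_reads: 20000
  reference_length: 50000
  contig_compartments: {nuc: nuclear, chl: organelle}
  seed: 7
```

```
herbdna simulate --config cfg.yaml
herbdna profile  --config cfg.yaml
herbdna cohort   --config cfg.yaml
```

`demo_out/metrics.tsv` then holds one row per sample × compartment, e.g.
for the first sample (S01, age 60; truth λ = 1.66×10⁻⁴ × 60 ≈ 0.0100):

```
sample_id  compartment  n_reads  log_mean  log_sd  median   lambda_hat
S01        all          19996    4.6556    0.6475  105.17   0.010446
S01        nuclear       9970    4.6569    0.6495  105.30   0.010503
S01        organelle    10026    4.6544    0.6454  105.05   0.010677
```

and `demo_out/regressions.tsv` / `cohort_report.json` give the cohort fits:

```
k_per_site_per_year   1.676e-04     # truth 1.66e-04, recovered within ~1%
k_free_intercept      1.659e-04     # sensitivity fit; intercept 3.6e-04 ≈ 0
ct_first_pct_vs_collection_year  slope -0.0208  R²=0.98  p=1.4e-03
fold_A_vs_collection_year        slope -6.4e-05 R²=0.08  p=0.65
```

Read: the damage fraction λ̂ grows linearly with age at the simulated decay
rate; first-base C→T falls by ~0.021 percentage points per calendar year of
collection (i.e. rises with age); purine enrichment is flat through time,
as expected when depurination-driven breakage is constant. The ANCOVA block
in `cohort_report.json` compares nuclear and organellar deamination
(`conclusion: "no difference" / "intercepts differ" / "slopes differ"`).

The same machinery is callable as a library (`herbdna.fit_decay`,
`herbdna.estimate_decay_rate`, `herbdna.ancova`, ...) on any SAM/BAM +
FASTA + sample-table inputs; see `docs/methods.md` for conventions,
defaults and the simulator's scope.

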
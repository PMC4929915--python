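# Methods

## The degradation model

Herbarium (and more generally historical/ancient) DNA carries two
time-dependent chemical signatures. First, the sugar–phosphate backbone
breaks at random positions, predominantly following depurination; if every
internucleotide bond fails independently with the same per-bond probability
λ, the frequency of surviving fragments of length L is exponential,

    F(L) = F0 · exp(−λ L),        log F(L) = log F0 − λ L,

so the log length-frequency is linear in L with slope −λ. λ is the per-bond
breakage (damage) fraction of one library. (Some descriptions gloss λ as a
*survival* fraction; we fix the convention that λ is the breakage fraction —
the magnitude of the log-linear slope — which is the quantity the fit
actually measures.) If breakage accrues at a constant per-site per-year rate
k, then across samples of known age

    λ = k · age,

and k is the slope of the (age, λ) regression. Because the model has no
intercept, the headline k comes from a through-origin fit; a free-intercept
fit is reported alongside, since a nonzero intercept is the signature of
age-independent fragmentation (e.g. specimen preparation by drying/pressing).

Second, cytosine deamination near single-stranded fragment ends converts C
to U, read as T: the C→T frequency is maximal at the 5′-terminal base and
declines toward the interior. The percentage of C→T at the first base is the
standard deamination proxy; it grows essentially linearly with sample age
and is absent (at the sequencing-error floor) in freshly collected material.

Break points also carry a compositional signature of depurination: the
reference base immediately 5′ of a read start (position −1) is enriched for
purines. The statistic used is the fold ratio of a purine's frequency at −1
over its frequency at −5 (a position far enough upstream to be background).

## Estimators

* **Length summary** — closed-form lognormal MLE on the length histogram:
  `log_mean` and `log_sd` are the count-weighted mean and uncorrected SD of
  ln L; `median = exp(log_mean)` exactly.
* **λ (per sample)** — unweighted OLS of ln(count) on L over a tail window.
  The window starts at the histogram mode + 5 bp (past the recovery-shaped
  body) and ends at the last length bin with ≥ 10 reads; zero-count bins are
  dropped (log undefined) and reported. A count-weighted fit and a
  truncated-geometric MLE are available as sensitivity checks. A
  non-decaying tail is flagged and excluded from cohort regressions. Note
  the geometric tail has log-slope ln(1−λ) ≈ −λ; for λ ≤ 0.05 the
  difference (≤ 2.5%) is below the estimator's sampling error at the
  simulated depths.
* **k (cohort)** — OLS of λ̂ on age, through the origin (headline) and with
  free intercept (sensitivity). P-values are F-tests; through-origin R² is
  uncentered, matching R's `lm` convention for intercept-free models.
* **ANCOVA** — `response ~ covariate * factor` with sequential (Type I) sums
  of squares, exactly what R's `aov` prints, then an F-test of the full
  against the additive model. Decision rule at α = 0.05: interaction
  significant → slopes differ; otherwise factor significant in the additive
  model → intercepts differ. Implemented on statsmodels OLS/anova_lm; the
  test suite checks the sequential decomposition against an explicit
  projection oracle to 1e-10.

## Alignment handling

Internally all coordinates are 0-based half-open; SAM's 1-based convention
is confined to the pysam boundary. Reads are reported in read orientation:
minus-strand read/reference bases are reverse-complemented, and position −1
for a minus-strand read is the complement of the reference base immediately
3′ of the mapped interval. Unmapped, secondary, supplementary, sub-MAPQ
(default min_mapq 25 — no published filter exists for this analysis, so it
is configurable) and indel/clipped records are dropped with counts logged,
because positionally indexed damage statistics assume end-anchored
match-only alignments. PCR duplicates are collapsed by (contig, start, end,
strand) to a majority-rule consensus (ties → N); damage statistics are
computed after this consensus. Reads too close to a contig edge to supply
ten upstream bases are flagged and excluded from break-point profiling only.

## The simulator

`simdata` generates data from exactly the process the estimators assume,
so every pipeline stage is testable by parameter recovery:

1. **Reference** — i.i.d. bases at a configurable GC content per contig,
   each contig labelled nuclear or organelle.
2. **Lengths** — geometric(λ) (the discrete analogue of the exponential
   survival model, equivalent to i.i.d. per-bond breakage), conditioned on
   [min_len, max_len] by inverse-CDF truncation.
3. **Recovery filter** — a fragment of length L is retained with logistic
   probability 1/(1 + e^−(L−L50)/s). This emulates the empirical fact that
   very short fragments are lost to extraction, library preparation and
   mapping, producing the moded, lognormal-looking body of real length
   distributions while leaving the informative right tail exponential. The
   mechanism behind the lognormal body is not established; the logistic
   filter is a modelling choice, which is why the λ fit deliberately starts
   past the mode.
4. **Break-point bias** — candidate fragments are accepted with probability
   proportional to the product of the break weights of the two flanking
   bases (purine w_pur, pyrimidine 1), the 3′ flank being assessed on the
   complementary strand; this reproduces the purine excess at −1 on both
   ends symmetrically without modelling nick chemistry.
5. **Deamination** — each C at 0-based 5′ distance i mutates to T with
   probability d1·r^i, each G at 3′ distance j to A with d1·r^j, where
   d1 = age × deam_rate_per_year (+ an additive organelle offset on
   organellar contigs). The mirrored 3′ G→A signal emulates double-stranded
   libraries; the analysis itself uses only the 5′ side.
6. **Sequencing error** — uniform per-base miscalls at rate ε, applied last.
7. **Strand** — uniform; coordinates and bases recorded accordingly, SAM SEQ
   stored in reference orientation with match-only CIGARs.

All randomness comes from one seeded generator; each sample draws from a
substream keyed by (seed, CRC32 of sample id), so cohorts are reproducible
read-for-read independent of simulation order.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| gc_content | 0.36 | Arabidopsis-like nuclear GC |
| k_true | 1.66e-4 /site/yr | herbarium-scale decay rate |
| deam_rate_per_year | 2e-4 /yr | first-base C→T ≈ 5.6% at 278 yr, the observed scale |
| deam_decline r | 0.5 | interior C→T falls to noise within ~10 bp, as in real profiles |
| deam_offset_organelle | −0.005 | organellar reads show a lower deamination intercept |
| purine_break_weight | 2.0 | clear but not caricatured −1 purine excess (fold ≈ 4/3 on a uniform genome) |
| seq_error | 1e-3 | merged-read Illumina error scale |
| min_len, max_len | 25, 500 | mappable merged-read range |
| recovery L50, scale | 35 bp, 5 bp | mode of retained lengths near 40 bp, matching historic libraries |
| reference_year | 2015 | "today" for age = reference_year − collection year; explicit, never implicit |

What the simulator deliberately omits: indels, mappability/repeat
artifacts, contamination, unmerged pairs, base-quality structure, species
mixtures. Passing recovery tests therefore demonstrates the estimators are
correct *under the stated degradation model*, not that real herbarium data
are free of those additional effects.

## Recovery experiments (`herbdna.validation`)

Problem sizes were chosen to make sampling error comfortably smaller than
the recovery tolerances while keeping a full run in minutes on one CPU:

* λ recovery: one sample, λ_true = 0.01, 2×10⁵ reads on 200 kb.
* k recovery: 30 samples, ages 20–278 yr, k_true = 1.66e-4, 5×10⁴ reads
  each on 100 kb; through-origin k̂ and the free-intercept check, plus the
  deamination-slope regression from the same cohort.
* Modern baseline: age-1 sample, 6×10⁴ reads; expected first-base C→T is
  d1(1−ε) + (1−d1)ε/3.
* Purine enrichment: w_pur = 2 on a 50% GC genome (expected fold 4/3),
  checked against a rejection-sampling oracle written independently of the
  simulator; plus 100 constant-weight cohorts for the fold-vs-year null.
* ANCOVA calibration: 200 replicates of two 15-point groups on the age
  range 20–278; type-I error of the interaction test under a shared line,
  and detection of a 5-residual-SD intercept shift under a shared slope.
  With the factor effect detected essentially always, the joint
  "factor significant, interaction not" rate is bounded above by one minus
  the interaction type-I error, so its expectation is ~95% by construction.

## Numerical notes and limitations

* Tail-window selection assumes a unimodal histogram; tied modes warn and
  use the smallest. Degenerate windows raise instructive errors rather than
  fitting silently.
* OLS log-count fitting ignores the Poisson heteroscedasticity of bin
  counts; at the default min_count of 10 the induced slope bias is well
  under 1% of λ, and the count-weighted option is available.
* Through-origin k on data with a genuine intercept is biased upward; the
  free-intercept fit recovers both parameters and is always reported.
* Chance coordinate collisions between genuinely independent fragments are
  collapsed by deduplication; on the simulated depths this affects well
  under 1% of reads and is ignored.
* No species covariate is modelled in cohort regressions; samples enter as
  exchangeable libraries.
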
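# Methods

## The drift model

A CpG-island locus is characterized by a base methylation fraction
`m_base ∈ [0,1]`, a fixed direction sign `s ∈ {−1,+1}` and a plasticity
status: *invariant*, *baseline-plastic* (stochastically variable even in
unexposed animals) or *diet-recruited* (variable only once the lineage has
been exposed for at least `g` generations, `g` the locus's recruitment
generation).  One generation of transmission is

```
m_child = clamp( m_base + h · (m_parent − m_base) + δ , 0, 1 )
```

with heritability `h ∈ [0,1]` and perturbation `δ = s·|Z|`,
`Z ~ N(0, σ²)` — a half-normal magnitude with a locus-fixed sign, the
simplest law under which inter-individual differences at a locus always
occur in the same direction while their amplitude varies.  At active loci
`σ = baseline_sd` without exposure and `baseline_sd·sqrt(diet_inflation)`
under the supplemented diet; at inactive loci `δ = 0`.

The deviation variance follows the recursion `Var_g = h²·Var_{g−1} +
Var(δ)`, approaching `Var(δ)/(1−h²)` for `h < 1`; this closed form is the
Monte-Carlo oracle for the transmission tests.  Because the signed
perturbation also has a nonzero mean, exposed lineages drift in the locus
direction while spreading apart — both the increase in variance and the
direction consistency seen on arrays.

**Exchangeable null by construction.**  Every lineage (control, F1, F6 and
the 10-animal reference pool) is propagated for the same total number of
generations: `burn_in_generations` (30, enough for the variance recursion
to reach stationarity at any `h ≤ 0.95`) plus `n_generations_long` (6)
further generations, of which the final one (F1) or all six (F6) are under
the diet.  With `diet_inflation = 1` and no recruitment the three groups
are then draws from *exactly* the same law, so null-calibration checks test
the pipeline and not an artifact of unequal lineage lengths.

## Rendering arrays

Arrays enrich the *unmethylated* DNA fraction, so the noiseless probe
log-ratio is `log2((1 − m_test + ε)/(1 − m_ref + ε))` with `ε = 0.01`
bounding the ratio at fully methylated loci; `m_ref` is the mean fraction
over the 10-control reference pool (pool members are distinct from the five
assayed controls).  Probes within an island share the island's methylation
state; everything else is per-probe, per-array: Gaussian technical noise
(`technical_sd`, log-ratio scale), a lognormal raw intensity with a
near-background low-signal subset (2% of features) for exercising the QC
filter, a linear-in-log-intensity dye bias (amplitude 0.15) and a small
random per-array median offset.  The latter two exist to be removed by
LOESS normalization and median centering.  A reference-channel matrix (same
pooled sample on every array, independent technical noise) supports the
reference-pool SD diagnostic.  GC content is drawn independently of
everything, so the GC-vs-SD diagnostic has nothing real to find.

## Parameter defaults and why

| parameter | default | rationale |
|---|---|---|
| `n_islands` / `probes_per_island` | 16000 / 4–9 | full-array scale: ≈16k islands, ≈105k probes |
| `n_mice_per_group` / `n_reference_mice` | 5 / 10 | study design: five animals per group, ten-control pool |
| `baseline_plastic_fraction` | 0.10 | a minority of islands is metastable even in controls |
| `diet_extra_plastic_fraction_per_gen` | 0.10/6 | recruitment totals 10% of islands over six generations |
| `baseline_sd` | 0.08 | per-generation perturbation SD on the methylation scale; keeps induced changes small (under ~10% methylation per generation) |
| `diet_inflation` | 3.0 | exposure triples perturbation variance at affected loci |
| `heritability_h` | 0.7 | partial transmission: F6 visibly exceeds F1 without fixation |
| `technical_sd` | 0.10 | typical replicate log-ratio noise for two-color arrays |
| `m_base` windows | gain 0.10–0.45, loss 0.55–0.90 | plastic loci are intermediately methylated metastable epialleles with headroom to drift in their direction; invariant loci uniform 0.05–0.95 |

No quantitative heritability, effect-size or noise estimates are available
to fit these to; they were fixed once by an a priori power analysis so that
the injected effect is detectable at the five-animals-per-group design
(biological SD at plastic loci ≈ 2× technical SD on the log-ratio scale),
and they stay fixed across all tests.  The test suite and the acceptance
script run the generator at 250–3,080 islands (tests) and 2,000–3,080
islands (acceptance) rather than full array scale; island count only sets
Monte-Carlo resolution, not the per-locus statistics.

## Pipeline numerics

* **Low-signal filter**: a feature is removed when its raw intensity is
  `≤ background_mean + k·background_sd`, `k = 2.6`, applied per array
  (configurable to a per-probe mean rule); the boundary is inclusive.
  Probes with no retained value are dropped; a probe enters a group's
  variance analysis only with ≥ 3 retained arrays (sample SD is too
  unstable below that).
* **LOESS**: statsmodels LOWESS of log-ratio on log10 intensity,
  span 0.3 (default), evaluated at the observed covariate with the
  interpolation shortcut (`delta` = 1% of the covariate range) for
  linear-time fitting; residuals are then median-centered per array to
  exactly 0.  A constant covariate skips trend removal with a warning.
* **Bartlett per probe** is vectorized from the classical formula
  (pooled-variance log contrast over k groups, `C` correction, χ² with
  k−1 df); scipy's scalar implementation is the independent oracle in the
  tests.  Zero-variance or undersized groups yield a flagged (NaN) probe.
* **Welch test** on SD distributions uses scipy with
  Welch–Satterthwaite df; box-plot summaries report the 10th/25th/50th/
  75th/90th percentiles.
* **Percentile threshold**: linear interpolation at rank `q/100·(n−1)`;
  calling is strictly greater-than, so the control group calls ≈ 5% of its
  own probes at q = 95.
* **Region merging**: within an island (probes ordered by genomic start),
  maximal runs of called probes allowing up to `max_gap` uncalled probes
  inside a run; defaults `min_probes = 1`, `max_gap = 0` — no region rule
  is externally specified, so the most permissive deterministic choice is
  the default and both knobs are echoed in output headers.
* **Direction**: sign of the group-mean log-ratio over region probes;
  positive = hypomethylation = "loss" (unmethylated-fraction enrichment),
  exact zero = "ambiguous".
* **Overlap null**: expected triple overlap `N·(n1/N)(n2/N)(n3/N)`
  conditions on `N` = islands retained after QC, not the nominal array
  size.  The permutation null is sampled exactly by the nested
  hypergeometric equivalence `|A∩B| ~ HG(N, n1, n2)`,
  `|A∩B∩C| ~ HG(N, |A∩B|, n3)`, which is what label-shuffling preserving
  the three set sizes induces; the p-value uses the +1 correction.  The
  secondary chi-square mode tests the 2×2×2 membership table against full
  independence of the three margins with df = 2³ − 1 − 3 = 4 (a published
  6-df construction for this comparison is not reconstructable from first
  principles; the permutation mode is therefore primary).
* **PCA**: probe-wise mean-centering, no scaling (log-ratios share a
  scale); per-group dispersion is the SD of array scores on the first
  three components, their product an ellipsoid-volume proxy.  All-equal
  arrays return zero dispersion rather than an error.
* **Promoters**: 0-based half-open coordinates throughout; a minus-strand
  TSS window is `[tss − 500, tss + 1000)`.  Nearest-TSS assignment breaks
  ties by smallest gene id for determinism.  GC content excludes N from
  the denominator and is invariant to case and reverse complement.

## Design choices that were genuinely open

* **Null-calibration configuration**: "no diet effect" sets both
  `diet_inflation = 1` *and* recruitment to 0 — recruited loci perturb
  (at baseline variance) only under exposure, so leaving recruitment on
  would not be a null.
* **Recovery bookkeeping**: sensitivity is measured over diet-recruited
  loci; a called locus counts as a false discovery only if the truth table
  marks it invariant — baseline-plastic loci are genuinely variable and
  calling them is correct.
* **Null calibration tolerance**: the check compares the *mean* call
  fraction over 10 replicate simulations against the binomial 99% interval
  for one 20,000-probe replicate; per-replicate fractions are
  overdispersed relative to binomial because probes within an island share
  their biological deviation and all calls share one estimated threshold.
* **ANOVA candidate calling** is a documented stub that raises: with high
  within-group variance the between-group test is underpowered by
  construction, which is the motivation for the variance-first approach.

## What the simulator does and does not emulate

It reproduces the study's *statistical* structure: group sizes, pooled
reference, island/probe hierarchy, direction-consistent stochastic drift,
variance inflation accumulating over generations, background-level
features, dye bias and technical noise.  It does not model the enzymatic
enrichment chemistry (HpaII/McrBC digestion efficiency, fragment-length
effects), probe-sequence-specific hybridization, spatial array artifacts,
cellular heterogeneity of tissue samples, or bisulphite conversion error.
Passing tests therefore demonstrate that the pipeline recovers
variance-structured signals of realistic magnitude under idealized array
physics — not that any particular biological dataset would yield the same
counts.

## Known limitations

* The signed half-normal drift couples the mean shift to the variance
  (mean ≈ 3× the stationary SD after many generations); loci near the
  clamp boundary saturate and lose across-individual variance, which is
  biologically plausible for bistable epialleles but means extreme
  `baseline_sd` values degrade detection nonmonotonically.
* Detection power is not exactly symmetric between gain and loss loci (the
  log-ratio transform compresses deviations at low methylation), only
  approximately balanced by the direction-aware base-level windows.
* Bartlett's test assumes normality per group; the Shapiro–Wilk helper is
  provided to check this, but no robust (e.g. Levene) alternative is
  implemented.
* The chi-square overlap mode treats loci as exchangeable Bernoulli draws;
  islands with more probes are in reality more likely to be called when
  `min_probes = 1`.
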
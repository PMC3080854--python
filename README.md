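# methvar

Variance-based detection of stochastic DNA methylation variability on
two-color CpG-island arrays, with a built-in simulator of multigenerational,
partially heritable epiallele drift.

## The problem

Isogenic mice raised in a common environment still differ epigenetically:
DNA methylation at some CpG-island loci varies between individuals for no
genetic or environmental reason, and an environmental exposure such as
dietary methyl-donor supplementation can *increase* that variability — more
strongly after multigenerational exposure.  Because the changes are
stochastic (different loci in different animals, small amplitudes, high
within-group variance), the usual between-group mean tests (ANOVA) find
almost nothing.  The productive question is instead *where methylation is
variable*, and whether exposure enlarges that set.

`methvar` implements this variance-first analysis for unmethylated-fraction
enrichment arrays, where each array measures log2(test / pooled-reference)
per probe and an increase in signal means relative **hypo**methylation:

1. **QC + normalization** — features within *k* = 2.6 SD of background are
   removed; the intensity-dependent dye bias is removed by LOESS and each
   array is median-scaled to zero.
2. **Variability statistics** — per-probe within-group SD `s_g`; Bartlett's
   chi-square test of variance heterogeneity per probe (pairwise and
   3-group); Welch's unequal-variance t-test on SD distributions; PCA score
   dispersion per group; Pearson diagnostics of SD against reference-pool SD
   and probe GC content.
3. **Calling** — probes with `s_g > Q95(s_control)` (the 95th percentile of
   the control group's SDs) are methylation-variable; called probes merge
   into regions within their CpG island and islands become variable loci.
   Region direction comes from the sign of the group-mean signal.
4. **Overlap statistics** — 7-cell Venn partition of the three groups'
   locus sets; expected triple overlap under independence
   `N·(n1/N)(n2/N)(n3/N)` with a permutation test (and a secondary
   chi-square mode on the 2×2×2 membership table).
5. **Sequence context** — promoter windows (−1000 bp to +500 bp of the TSS,
   strand-aware), GC content, repeat-element frequency (chi-square) and
   TSS-to-element distance (t-test) for variable vs invariant promoters;
   percent-methylation summaries of bisulphite clone matrices.

The simulator renders the generative model behind these observations: at a
*plastic* locus each generation adds a signed half-normal perturbation to
the methylation fraction, a fraction `h ∈ [0,1]` of the parent's deviation
is inherited (`m' = clamp(m_base + h·(m_parent − m_base) + δ, 0, 1)`),
dietary exposure multiplies the perturbation variance by `diet_inflation`
and recruits additional loci each exposed generation.  Ground truth is
emitted for every locus, so recovery of injected variability is measurable
end to end.

## Worked example

```python
import methvar as mv
from methvar import preprocess as pp, variability as vb, vmr

cfg = mv.SimulationConfig(n_islands=2000, seed=42)   # 5 mice x 3 groups
ds = mv.simulate_dataset(cfg)

sm = pp.SignalMatrix(ds.signals, ds.design)
norm, report = pp.normalize_signal_matrix(
    sm, ds.intensity, cfg.background_mean, cfg.background_sd)

sds = vb.group_sd(norm)                  # per-probe SD per group
vmrset = vmr.call_vmr(sds, norm, ds.annotation)
print(vmrset.locus_counts())
rec = vmr.recovery_metrics(vmrset.loci["F6"], ds.truth)
print(round(rec["sensitivity"], 3), round(rec["fdp"], 3))
```

prints

```
{'control': 210, 'F1': 264, 'F6': 395}
0.93 0.114
```

The locus counts rise with exposure (controls ≈ the nominal 5% call rate;
one diet generation recruits a first cohort of loci; six generations
accumulate all of them), and 93% of the truly recruited loci are recovered
in the F6 group at an 11% false-discovery proportion.  Testing the overlap
of the three locus sets against chance:

```python
import numpy as np
res = vmr.overlap_test_from_sets(
    vmrset.loci["control"], vmrset.loci["F1"], vmrset.loci["F6"],
    n_total=2000, rng=np.random.default_rng(0))
print(res.observed_triple, round(res.expected_triple, 1), res.pvalue)
# 145 5.5 9.999e-05
```

— far more loci are variable in all three groups than expected if
variability struck loci at random, i.e. some loci are intrinsically
epigenetically plastic.

The same pipeline is scriptable from the shell:

```bash
methvar all --outdir run1 --seed 42
methvar report --outdir run1            # regenerate from intermediates
```

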
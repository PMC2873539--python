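# Methods

## Generative model

The synthetic generator draws probe-level intensities under the
multiplicative model `PM_ij = t_i f_j e_ij + BKG_ij`. Per gene *g* with
exons *e* and groups/conditions *c*, the linear target response of a probe
in exon *e* and sample *s* is

```
t = 2 ^ ( b_g + o_e + [fc_{e,g} + d_e] · 1{s in target group} + a_{g,pair(s)} )
```

* `b_g ~ N(baseline_log2_mean, baseline_log2_sd)` — gene baseline (log2;
  defaults 7 ± 1, i.e. linear signals of order a few hundred, typical of
  bright core probesets over a background of a few tens of units).
* `o_e ~ N(0, exon_baseline_sd)` — per-exon baseline offset (default 1.5
  log2 units), the heterogeneity of exon-level signal within a gene that the
  PS/PD diagnostics need.
* `fc_{e,g}` — realized exon-level fold change of a differentially expressed
  gene. A fraction `frac_de_genes` (default 0.3) of genes receive a gene
  fold change `fc_g ~ N(de_log2fc_mean, de_log2fc_sd)` (defaults 0, 1.5).
  The exon-level magnitude is coupled to the exon's standardized baseline
  offset `z_e`:

  ```
  fc_{e,g} = fc_g · max(0, 1 + intensity_effect_coupling · z_e)
  ```

  so with coupling > 0 bright exons change more than dim ones — the
  empirical pattern (right-skewed per-gene correlation between exon level
  and |effect|) that links the "bright probes dominate" weighting of PLIER
  to gene-level change over-estimation. Coupling 0 (the default) makes all
  exons of a DE gene change exactly proportionally.
* `d_e` — alternative-splicing delta: a fraction `frac_as_exons` of exons
  get ±`as_delta_ni` log2 units of inclusion change in the target group
  (sign: skipped = negative).
* `a_{g,p}` — optional per-pair gene effect for the paired design
  (`pair_effect_sd`, default 0 so the noiseless-null example is exact).
* `f_j = exp(N(0, affinity_sd_log))` with mean log 0 (default sd 0.7 — real
  probe affinities span well over an order of magnitude), so probeset-level
  expected signals equal `t` on average, matching the geometric-mean-one
  identifiability convention of the fits.
* `e_ij = exp(N(0, noise_sd_log))` (default 0.25, a ~25–30% multiplicative
  CV typical of probe-level intensities).
* `BKG_ij` — the per-probe deterministic background level of the probe's GC
  bin. Five bins by default, with per-bin means `background_mean ·
  linspace(0.7, 1.3, n_bins)` (GC-richer probes hybridize background more
  brightly); the separately simulated *background probe* matrix adds
  Gaussian spread `background_sd` (floored at 0.5) and feeds the DABG
  surrogate.

All draws come from a single `numpy` Generator seeded by `config.seed` in a
fixed order, so identical configurations are bit-identical. Counts of DE
genes and AS exons are exact (`round(frac · n)`), not binomial.

What the generator does **not** emulate: probe-sequence affinity models,
mismatch probes, spatial artifacts, cross-hybridization signal (the
`crosshyb_type` label only exercises the filter), saturation, or
correlated probe noise. Passing tests therefore show that the analysis
behaves correctly *under the multiplicative model the summarizers assume*,
not that either summarizer is well calibrated on any particular real array.

## Summarization

**RMA track.** Optional quantile normalization across all probes jointly
(column sorted values replaced by the mean order statistics; ties get
average ranks interpolated into the target), log2 transform, then Tukey
median polish per unit (probeset for exon level, transcript cluster for
gene level), capped at 10 full sweeps. The signal is `overall +
sample_effect`. The full RMA convolution background model is not
implemented; the optional `pm-gcbg` subtraction (below) is available for
both tracks, since the comparison's object is summarization, not background
modelling.

**PLIER track.** The exact published loss of PLIER is not public; we use a
Huber-type loss on `r_ij = log e_ij`: `G(r) = r²/2` for `|r| ≤ z`, else
`z|r| − z²/2` (default `z = 5`), which has the required down-weighting of
outlier probes and keeps the loss convex in each coordinate block. After
background adjustment (`pm`: none; `pm-gcbg`: subtract the per-sample
median of the probe's GC bin's background probes) and flooring at
`min(PM, 0.5)` — the floor only binds where subtraction drives a value to
zero — the model is additive in logs and is fit by alternating damped
Newton updates of `log t` (given `f`) and `log f` (given `t`). Steps are
halved until the loss is non-increasing; coordinates whose curvature
vanishes (every residual beyond `z`) take a damped gradient step, counted
and logged, which is the instability mode that background-anomaly flagging
looks for downstream. Convergence: relative loss change ≤ 1e-8 (default),
100 sweeps cap. Identifiability: geometric mean of `f` fixed to 1, so `t`
carries the intensity scale and "gene signal > 70" thresholds are
meaningful on `t` directly. Reported signals are `log2(t + 16)`.

**iterPLIER.** Gene-level only: after a full fit, probes are ranked by
Pearson correlation between their log adjusted intensity and `log t` across
samples, the top `keep_fraction` (default 0.5, never fewer than 8 probes,
ties at the cutoff all kept — so a perfectly concordant probe set is never
trimmed) are retained and the model re-fit; two rounds by default. Probe
selection is purely correlation-ranked; the "consecutive exons" aspect of
the original heuristic is not enforced because synthetic probes have no
genomic coordinates. Exon-level signals in the PLIER track always come from
plain per-probeset PLIER fits.

## Presence calls and filtering

DABG is a documented surrogate, not the vendor formula: probe
`p = (1 + #{background ≥ PM}) / (1 + n_background)` within the probe's GC
bin, combined per probeset by Fisher's method (`χ² = −2Σ ln p`, 2k df).
Any calibrated surrogate preserves the filter semantics, which is all the
cascades consume.

Paired cascade (in order): transcript present in both groups; probeset
present in either group; cross-hybridization type 1 only; mean linear
gene-level signal > 70 (mean over samples — the per-sample alternative is
not distinguishable from the source description; mean was chosen and is
flagged here). Tissue cascade: probeset present in the test tissue or ≥ 5
others; gene present in the test tissue and ≥ 5 others ("five of the other
tissues" read as inclusive ≥ 5); cross-hybridization type 1; gene mean log2
expression in the top 50% for *every* supplied summarization method.
Gene presence in a tissue reuses the ≥ 50%-of-probesets rule, which the
source filtering description defines only for the paired design. The top-50%
threshold is computed over the full summarized gene set (a fixed input), and
boundary ties are kept — both choices make the cascade idempotent and
order-independent. Attrition is recorded per rule and always balances.

## Splicing statistics and diagnostics

NI, SI (per-pair differences for paired designs; difference of group means
for one-vs-rest), paired and Welch t-tests (Satterthwaite df) on NI and on
gene signals. Zero-variance units return p = 1 with a degenerate flag
rather than erroring, keeping vectorized pipelines total. No
multiple-testing correction anywhere: raw p-values are thresholded at 0.001
and 0.05, matching the analysis being reproduced. PS and PD use strict
inequalities (ties count against skew). Enrichment tables fix gene-level
significance at p < 0.05 and vary only the splicing alpha; "mean NI
difference" sign is sign(SI), identical by the mean-of-differences =
difference-of-means identity for paired designs. SI strata use the
inclusive middle interval −1 ≤ ΔG ≤ 1. The 1:1 skipped:included test is the
standard 1-df goodness-of-fit chi-square `(a−b)²/(a+b)`; published p-values
for some count pairs do not match this standard form (e.g. 877/867 gives
p = 0.811) and the discrepancy is documented rather than imitated.

## Problem sizes and numerical choices

The canned bias study uses 500 genes × 8 exons × 10 matched pairs with
coupling 0.5 and no true splicing (~4,000 probesets, ~16,000 probes); the
null calibration uses 400 genes × 6 exons (2,400 NI tests, binomial 3σ band
0.05 ± 0.013). These sizes give stable correlation and enrichment estimates
(the bias contrast is reproducible to ±0.02 in Pearson r across seeds)
while keeping a full run to seconds. Degenerate inputs: all-equal matrices
polish to zero effects; single-column matrices skip quantile normalization
with a logged notice; empty GC bins and empty groups raise named errors.

## Known limitations

* The Huber loss stands in for the unpublished PLIER loss; `z` is pluggable
  but the default is a convention, not a calibration against vendor output.
* The iterPLIER retained-count schedule (fraction 0.5, floor 8, 2 rounds)
  is a documented guess at an unspecified schedule.
* Quantile normalization assumes comparable intensity distributions across
  samples; on very small simulated panels with many DE genes it leaks
  between-group differences into null genes, so calibration studies either
  use a global null or disable it.
* RMA background correction is limited to the shared `pm-gcbg` option; the
  convolution model is out of scope.
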
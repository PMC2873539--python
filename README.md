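# exonbias

Probe-level exon-array simulation and a head-to-head comparison of PLIER- and
RMA-style probe summarization, focused on how gene-level estimation bias
distorts normalized-index (NI) based alternative-splicing detection.

## The problem

Exon arrays measure every exon of a gene with a small probeset (four
perfect-match probes here), enabling both gene-level expression analysis and
splicing detection. Both summarizers assume a multiplicative probe model

```
PM_ij = t_i · f_j · e_ij + BKG_ij
```

with target response `t_i` (mRNA abundance in array *i*), feature response
`f_j` (probe affinity), log-normal error `e_ij` and GC-specific background
`BKG_ij`. RMA fits the log-additive form with Tukey median polish; PLIER
minimizes a robust loss on `r_ij = log e_ij` (here a Huber-type loss with
tuning constant `z`) by damped Newton steps, and iterPLIER re-fits the
gene-level model on the subset of probes that best track the fitted target
response.

Splicing detection works on the normalized index and splicing index

```
NI = E_exon − G_gene          (log2)
SI = NI_test − NI_reference = ΔE − ΔG
```

so any summarizer that over-estimates gene-level changes relative to
exon-level changes (|ΔG| > |ΔE| for most exons) forces SI to correlate
negatively with ΔG — skipped calls pile up on up-regulated genes and included
calls on down-regulated genes, a technical artifact rather than biology.
This package reproduces that mechanism end to end on synthetic data with
known ground truth: a generator for paired two-group and multi-tissue
designs, both summarization tracks, DABG presence-call filtering cascades,
and the full set of diagnostics (PS, PD, SI–ΔG correlations, enrichment
tables, per-gene intensity–effect correlations, 1:1 chi-square tests,
background-anomaly flags).

## Worked example

```python
from exonbias.pipeline import bias_study
out = bias_study(seed=1)  # 500 genes x 8 exons, 10 matched pairs,
                          # no true splicing, intensity_effect_coupling=0.5
print(out["plier"])
print(out["rma"])
```

prints (seed 1):

```
{'pearson_si_dg': -0.755, 'spearman_si_dg': -0.723, 'up_skipped_pct': 92.9,
 'down_included_pct': 93.5, 'n_up': 519, 'n_down': 1001,
 'ps_mean': 0.682, 'pd_mean': 0.755}
{'pearson_si_dg': 0.054, 'spearman_si_dg': 0.001, 'up_skipped_pct': 49.8,
 'down_included_pct': 48.9, 'n_up': 426, 'n_down': 571,
 'ps_mean': 0.496, 'pd_mean': 0.355}
```

Read: with **no true splicing** in the data, the iterPLIER track shows a
strong negative SI–ΔG correlation (−0.76) and calls 93% of its significant
probesets on up-regulated genes "skipped", while the RMA track is essentially
uncorrelated and balanced. The PS mean (fraction of a gene's probesets lying
below the gene signal) is right-skewed for PLIER (0.68) and centred for RMA
(0.50): PLIER's gene estimate is dominated by bright probesets, whose effect
sizes are larger when expression level and effect magnitude are coupled,
hence the over-estimated ΔG.

A YAML-driven CLI wraps the same stages:

```
exonbias --config cfg.yaml --seed 1 --out run1 run       # full pipeline
exonbias --out run1 simulate                             # or stage by stage
exonbias --out run1 summarize --method iterplier --dataset-dir run1/dataset
```

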
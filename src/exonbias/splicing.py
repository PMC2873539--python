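"""Normalized-index splicing statistics and summarization-bias diagnostics.

The normalized index (NI) of an exon is its log2 exon-level signal minus the
log2 gene-level signal of its parent transcript, a proxy for the log exon
inclusion rate.  The splicing index (SI) is the difference in NI between
conditions (per matched pair for paired designs, or as a difference of group
means for one-vs-rest comparisons); dG is the corresponding gene-level log2
expression difference.  Since SI = (exon-level change) - (gene-level change),
a systematic negative correlation between SI and dG is the signature of a
summarizer over-estimating gene-level changes relative to exon-level changes.

Diagnostics implemented here:

* PS: per transcript and sample, the fraction of its probesets whose signal
  lies strictly below the gene-level signal (0.5 ~ a median-like gene
  estimate; right-skew means bright probesets dominate the gene signal).
* PD: per transcript, the fraction of probesets whose absolute mean
  between-group difference is strictly smaller than the gene-level absolute
  difference (large PD = gene-level change over-estimation).
* SI-dG Pearson/Spearman correlations, SI distributions stratified by dG,
  skipped/included enrichment tables on differentially expressed genes, the
  per-gene correlation between exon expression level and effect size, a
  1-df chi-square test of skipped:included = 1:1, and a flag for transcripts
  whose background-corrected signal is anomalously larger than the
  uncorrected one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "NIMatrix",
    "EnrichmentTable",
    "normalized_index",
    "splicing_index_paired",
    "splicing_index_unpaired",
    "test_splicing",
    "test_gene_expression",
    "splice_test_table",
    "ps_statistic",
    "pd_statistic",
    "si_dg_correlation",
    "intensity_effect_correlation",
    "enrichment_table",
    "si_strata_summary",
    "chi_square_one_to_one",
    "exclude_inconsistent",
    "flag_background_anomalies",
    "percent",
]


@dataclass
class NIMatrix:
    ni: pd.DataFrame  # probeset x sample, log2
    parent: pd.Series  # probeset -> transcript


@dataclass
class EnrichmentTable:
    """Counts of significant probesets on differentially expressed genes,
    split by the sign of the gene change and of the mean NI difference."""

    alpha_splice: float
    alpha_gene: float
    n_significant: int
    n_on_de_genes: int
    up_included: int
    up_skipped: int
    down_included: int
    down_skipped: int

    @property
    def up_skipped_pct(self) -> float:
        return percent(self.up_skipped, self.up_included + self.up_skipped)

    @property
    def up_included_pct(self) -> float:
        return percent(self.up_included, self.up_included + self.up_skipped)

    @property
    def down_included_pct(self) -> float:
        return percent(self.down_included, self.down_included + self.down_skipped)

    @property
    def down_skipped_pct(self) -> float:
        return percent(self.down_skipped, self.down_included + self.down_skipped)

    def to_dict(self) -> dict:
        return {
            "alpha_splice": self.alpha_splice,
            "alpha_gene": self.alpha_gene,
            "n_significant": self.n_significant,
            "n_on_de_genes": self.n_on_de_genes,
            "up": {
                "included": self.up_included,
                "skipped": self.up_skipped,
                "included_pct": self.up_included_pct,
                "skipped_pct": self.up_skipped_pct,
            },
            "down": {
                "included": self.down_included,
                "skipped": self.down_skipped,
                "included_pct": self.down_included_pct,
                "skipped_pct": self.down_skipped_pct,
            },
        }


def percent(part: float, whole: float) -> float:
    """``100 * part / whole`` (NaN for an empty cell)."""
    return float("nan") if whole == 0 else 100.0 * part / whole


# ---------------------------------------------------------------------------
# NI and SI
# ---------------------------------------------------------------------------

def normalized_index(exon_signal: pd.DataFrame, gene_signal: pd.DataFrame, parent: pd.Series) -> NIMatrix:
    """NI = exon log2 signal - parent gene log2 signal, per sample."""
    parent = parent.reindex(exon_signal.index)
    have = parent.isin(gene_signal.index)
    if (~have).any():
        log.warning("%d probeset(s) lack a parent gene signal; omitted", int((~have).sum()))
    exon = exon_signal.loc[have.to_numpy()]
    parent = parent.loc[have.to_numpy()]
    gene = gene_signal.loc[parent.to_numpy()]
    ni = pd.DataFrame(exon.values - gene.values, index=exon.index, columns=exon.columns)
    return NIMatrix(ni=ni, parent=parent)


def _paired_columns(design: pd.DataFrame, test_group: str):
    """Matched (reference, test) sample columns ordered by pair id."""
    groups = list(dict.fromkeys(design["group"]))
    if len(groups) != 2:
        raise ValueError("paired analysis expects exactly two groups")
    ref_group = next(g for g in groups if g != test_group)
    pairs = {}
    for sid, row in design.iterrows():
        pairs.setdefault(row["pair_id"], {})[row["group"]] = sid
    ref_cols, test_cols, pair_ids = [], [], []
    for pid in sorted(pairs):
        members = pairs[pid]
        if test_group not in members or ref_group not in members:
            log.warning("incomplete pair %r skipped", pid)
            continue
        ref_cols.append(members[ref_group])
        test_cols.append(members[test_group])
        pair_ids.append(pid)
    if len(pair_ids) < 2:
        raise ValueError("paired analysis needs at least two complete pairs")
    return ref_cols, test_cols, pair_ids


def splicing_index_paired(
    ni: NIMatrix, gene_signal: pd.DataFrame, design: pd.DataFrame, test_group: str
) -> pd.DataFrame:
    """Per-(probeset, pair) SI and the parent gene's per-pair dG.

    SI_ijk = NI(test member of pair k) - NI(reference member); dG_jk is the
    analogous difference of gene-level signals.
    """
    ref_cols, test_cols, pair_ids = _paired_columns(design, test_group)
    si = ni.ni[test_cols].values - ni.ni[ref_cols].values
    dg_tx = gene_signal[test_cols].values - gene_signal[ref_cols].values
    dg = pd.DataFrame(dg_tx, index=gene_signal.index, columns=pair_ids)
    dg_rows = dg.loc[ni.parent.to_numpy()].values
    records = pd.DataFrame(
        {
            "probeset_id": np.repeat(ni.ni.index.to_numpy(), len(pair_ids)),
            "transcript_id": np.repeat(ni.parent.to_numpy(), len(pair_ids)),
            "pair_id": np.tile(np.array(pair_ids, dtype=object), len(ni.ni)),
            "si": si.ravel(),
            "dg": dg_rows.ravel(),
        }
    )
    return records


def splicing_index_unpaired(
    ni: NIMatrix, gene_signal: pd.DataFrame, design: pd.DataFrame, test_group: str
) -> pd.DataFrame:
    """Per-probeset SI (mean NI in test group minus mean NI in the rest) and dG."""
    test_cols = design.index[design["group"] == test_group]
    rest_cols = design.index[design["group"] != test_group]
    if len(test_cols) == 0 or len(rest_cols) == 0:
        raise ValueError("test group and complement must both be non-empty")
    si = ni.ni[test_cols].mean(axis=1) - ni.ni[rest_cols].mean(axis=1)
    dg_tx = gene_signal[test_cols].mean(axis=1) - gene_signal[rest_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "probeset_id": ni.ni.index,
            "transcript_id": ni.parent.to_numpy(),
            "si": si.to_numpy(),
            "dg": dg_tx.loc[ni.parent.to_numpy()].to_numpy(),
        }
    ).set_index("probeset_id")


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def _paired_t(values: pd.DataFrame, design: pd.DataFrame, test_group: str):
    ref_cols, test_cols, _ = _paired_columns(design, test_group)
    d = values[test_cols].values - values[ref_cols].values
    n = d.shape[1]
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p = np.where(degenerate, 1.0, p)
    if degenerate.any():
        log.info("%d unit(s) with zero-variance differences; p set to 1", int(degenerate.sum()))
    return mean, p, degenerate


def _welch_t(values: pd.DataFrame, design: pd.DataFrame, test_group: str):
    a = values[design.index[design["group"] == test_group]].values
    b = values[design.index[design["group"] != test_group]].values
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test needs >= 2 samples per side")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    degenerate = se2 == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2 ** 2 / (v1 ** 2 / (n1 ** 2 * (n1 - 1)) + v2 ** 2 / (n2 ** 2 * (n2 - 1)))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.where(degenerate, 1.0, p)
    if degenerate.any():
        log.info("%d unit(s) with zero variance on both sides; p set to 1", int(degenerate.sum()))
    return m1 - m2, p, degenerate


def test_splicing(
    ni: NIMatrix, design: pd.DataFrame, mode: str = "paired_t", test_group: str | None = None
) -> pd.DataFrame:
    """Two-sided t-test on NI per probeset.

    ``mode='paired_t'`` tests per-pair NI differences; ``mode='welch_t'``
    compares the test group against all other samples with Satterthwaite
    degrees of freedom.  Zero-variance units get p = 1 and a degenerate flag.
    """
    if mode == "paired_t":
        test_group = test_group or _infer_test_group(design)
        diff, p, flag = _paired_t(ni.ni, design, test_group)
    elif mode == "welch_t":
        if test_group is None:
            raise ValueError("welch_t requires a test_group")
        diff, p, flag = _welch_t(ni.ni, design, test_group)
    else:
        raise ValueError("mode must be 'paired_t' or 'welch_t'")
    return pd.DataFrame(
        {"mean_diff": diff, "p": p, "degenerate": flag}, index=ni.ni.index
    )


def test_gene_expression(
    gene_signal: pd.DataFrame, design: pd.DataFrame, mode: str = "paired_t",
    test_group: str | None = None,
) -> pd.DataFrame:
    """Per-transcript dG and differential-expression p-value (same modes)."""
    if mode == "paired_t":
        test_group = test_group or _infer_test_group(design)
        dg, p, flag = _paired_t(gene_signal, design, test_group)
    elif mode == "welch_t":
        if test_group is None:
            raise ValueError("welch_t requires a test_group")
        dg, p, flag = _welch_t(gene_signal, design, test_group)
    else:
        raise ValueError("mode must be 'paired_t' or 'welch_t'")
    return pd.DataFrame({"dg": dg, "p": p, "degenerate": flag}, index=gene_signal.index)


def _infer_test_group(design: pd.DataFrame) -> str:
    groups = list(dict.fromkeys(design["group"]))
    if len(groups) != 2:
        raise ValueError("cannot infer test group from a non-two-group design")
    return groups[1]


def splice_test_table(
    exon_signal: pd.DataFrame,
    gene_signal: pd.DataFrame,
    parent: pd.Series,
    design: pd.DataFrame,
    mode: str = "paired_t",
    test_group: str | None = None,
) -> pd.DataFrame:
    """One row per probeset: si, p_splice, delta_g, p_gene, si sign.

    ``si`` is the mean per-pair NI difference (paired) or the difference of
    group means (Welch); for paired designs the two coincide.
    """
    ni = normalized_index(exon_signal, gene_signal, parent)
    splice = test_splicing(ni, design, mode=mode, test_group=test_group)
    gene = test_gene_expression(gene_signal, design, mode=mode, test_group=test_group)
    tx = ni.parent
    out = pd.DataFrame(
        {
            "transcript_id": tx.to_numpy(),
            "si": splice["mean_diff"],
            "p_splice": splice["p"],
            "delta_g": gene["dg"].reindex(tx).to_numpy(),
            "p_gene": gene["p"].reindex(tx).to_numpy(),
        },
        index=ni.ni.index,
    )
    out["si_sign"] = np.sign(out["si"]).astype(int)
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def ps_statistic(exon_signal: pd.DataFrame, gene_signal: pd.DataFrame, parent: pd.Series) -> pd.DataFrame:
    """Per (transcript, sample): fraction of probesets strictly below the gene signal."""
    parent = parent.reindex(exon_signal.index)
    gene_rows = gene_signal.loc[parent.to_numpy()].values
    below = exon_signal.values < gene_rows
    return (
        pd.DataFrame(below, index=parent.to_numpy(), columns=exon_signal.columns)
        .groupby(level=0)
        .mean()
        .rename_axis("transcript_id")
    )


def pd_statistic(
    exon_signal: pd.DataFrame,
    gene_signal: pd.DataFrame,
    parent: pd.Series,
    design: pd.DataFrame,
    test_group: str,
) -> pd.Series:
    """Per transcript: fraction of probesets with |mean exon diff| < |mean gene diff|."""
    test_cols = design.index[design["group"] == test_group]
    rest_cols = design.index[design["group"] != test_group]
    exon_diff = exon_signal[test_cols].mean(axis=1) - exon_signal[rest_cols].mean(axis=1)
    gene_diff = gene_signal[test_cols].mean(axis=1) - gene_signal[rest_cols].mean(axis=1)
    parent = parent.reindex(exon_signal.index)
    smaller = exon_diff.abs().to_numpy() < gene_diff.abs().loc[parent.to_numpy()].to_numpy()
    return (
        pd.Series(smaller, index=parent.to_numpy())
        .groupby(level=0)
        .mean()
        .rename_axis("transcript_id")
        .rename("pd")
    )


def si_dg_correlation(si, dg) -> tuple[float, float]:
    """(Pearson, Spearman) correlation between SI and dG records."""
    si = np.asarray(si, dtype=float)
    dg = np.asarray(dg, dtype=float)
    ok = np.isfinite(si) & np.isfinite(dg)
    si, dg = si[ok], dg[ok]
    if len(si) < 3:
        raise ValueError("need at least 3 finite (SI, dG) records")
    if si.std() == 0 or dg.std() == 0:
        log.warning("zero variance in SI or dG; correlation undefined")
        return float("nan"), float("nan")
    pearson = stats.pearsonr(si, dg).statistic
    spearman = stats.spearmanr(si, dg).statistic
    return float(pearson), float(spearman)


def intensity_effect_correlation(
    exon_signal: pd.DataFrame,
    parent: pd.Series,
    design: pd.DataFrame,
    test_group: str,
    min_probesets: int = 3,
) -> pd.Series:
    """Per gene: Pearson r between mean exon level and |between-group diff|."""
    test_cols = design.index[design["group"] == test_group]
    rest_cols = design.index[design["group"] != test_group]
    level = exon_signal.mean(axis=1)
    effect = (
        exon_signal[test_cols].mean(axis=1) - exon_signal[rest_cols].mean(axis=1)
    ).abs()
    parent = parent.reindex(exon_signal.index)
    out = {}
    for tx, idx in level.groupby(parent.to_numpy()).groups.items():
        if len(idx) < min_probesets:
            continue
        x, y = level.loc[idx].to_numpy(), effect.loc[idx].to_numpy()
        if x.std() == 0 or y.std() == 0:
            log.debug("gene %s has constant level or effect; skipped", tx)
            continue
        out[tx] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(out, name="intensity_effect_r").rename_axis("transcript_id")


def enrichment_table(
    results: pd.DataFrame,
    alpha_splice: float = 0.001,
    alpha_gene: float = 0.05,
    dg_threshold: float = 0.0,
) -> EnrichmentTable:
    """Tally significant probesets on DE genes by sign(dG) and sign(SI).

    ``results`` must carry columns si, p_splice, delta_g, p_gene.  Probesets
    with SI exactly 0 are counted in neither the skipped nor the included
    cell; percentages are within each dG-sign stratum.
    """
    sig = results[results["p_splice"] < alpha_splice]
    on_de = sig[sig["p_gene"] < alpha_gene]
    up = on_de[on_de["delta_g"] > dg_threshold]
    down = on_de[on_de["delta_g"] < -dg_threshold]
    return EnrichmentTable(
        alpha_splice=alpha_splice,
        alpha_gene=alpha_gene,
        n_significant=len(sig),
        n_on_de_genes=len(on_de),
        up_included=int((up["si"] > 0).sum()),
        up_skipped=int((up["si"] < 0).sum()),
        down_included=int((down["si"] > 0).sum()),
        down_skipped=int((down["si"] < 0).sum()),
    )


def si_strata_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Summaries of SI in the strata dG > 1, -1 <= dG <= 1 and dG < -1."""
    dg = results["delta_g"]
    strata = {
        "dg_gt_1": results[dg > 1]["si"],
        "dg_between": results[(dg >= -1) & (dg <= 1)]["si"],
        "dg_lt_minus1": results[dg < -1]["si"],
    }
    rows = []
    for name, si in strata.items():
        if len(si):
            rows.append(
                (name, len(si), si.mean(), si.median(), si.quantile(0.25), si.quantile(0.75))
            )
        else:
            rows.append((name, 0, np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows, columns=["stratum", "n", "mean", "median", "q1", "q3"]
    ).set_index("stratum")


def chi_square_one_to_one(n_included: int, n_skipped: int) -> tuple[float, float]:
    """1-df goodness-of-fit test of skipped:included = 1:1.

    Statistic ``sum (obs - exp)^2 / exp`` with ``exp = total / 2``; upper-tail
    p-value from the chi-square distribution with 1 degree of freedom.
    """
    if n_included < 0 or n_skipped < 0:
        raise ValueError("counts must be >= 0")
    total = n_included + n_skipped
    if total == 0:
        raise ValueError("at least one exon is required")
    statistic = (n_included - n_skipped) ** 2 / total
    return float(statistic), float(stats.chi2.sf(statistic, df=1))


def exclude_inconsistent(n_total: int, n_inconsistent: int) -> int:
    """Exons retained after removing those with inconsistent tissue specificity."""
    if n_inconsistent < 0 or n_total < 0 or n_inconsistent > n_total:
        raise ValueError("need 0 <= n_inconsistent <= n_total")
    return n_total - n_inconsistent


def flag_background_anomalies(
    signal_pm: pd.DataFrame, signal_pmgcbg: pd.DataFrame, fold: float = 7.0
) -> pd.DataFrame:
    """Transcripts whose background-corrected mean signal is >= fold x uncorrected.

    Background subtraction should shrink signals slightly, so a large
    pm-gcbg / pm ratio marks a numerically unstable fit.  Both inputs are
    linear-scale; a zero pm mean is flagged with an infinite ratio.
    """
    common = signal_pm.index.intersection(signal_pmgcbg.index)
    mean_pm = signal_pm.loc[common].mean(axis=1)
    mean_gcbg = signal_pmgcbg.loc[common].mean(axis=1)
    with np.errstate(divide="ignore"):
        ratio = np.where(mean_pm > 0, mean_gcbg / mean_pm, np.inf)
    flagged = ratio >= fold
    return pd.DataFrame(
        {"mean_pm": mean_pm, "mean_pmgcbg": mean_gcbg, "ratio": ratio, "flagged": flagged},
        index=common,
    )
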
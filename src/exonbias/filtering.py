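"""Presence calls and probeset/transcript filtering cascades.

Detection above background (DABG) is computed empirically: each PM probe is
ranked against the background probes of its GC bin in the same sample,
``p = (1 + #{background >= PM}) / (1 + n_background)``, and probe p-values are
combined per probeset with Fisher's method.  Presence flags per group follow
either a fraction rule (present in >= 50% of the group's samples) or a count
rule (present in >= 2 samples), and a transcript is present in a group when at
least half of its probesets are.

Two cascades mirror the two experimental designs:

* paired two-group: transcript present in both groups, probeset present in
  either group, cross-hybridization type 1 only, and mean linear gene-level
  signal above a threshold (70 by default);
* multi-group tissue panel: probeset present in the test tissue or in at
  least five other tissues, gene present in the test tissue and at least five
  others, cross-hybridization type 1, and gene mean log2 expression in the
  top 50% for every summarization method supplied (ties at the boundary are
  kept).

Every cascade records an ordered attrition ledger (rule name, probesets
removed) whose counts always balance against the kept set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .synthetic import ProbeLevelDataset

log = logging.getLogger(__name__)

__all__ = [
    "PresenceCalls",
    "FilterReport",
    "dabg_pvalues",
    "probe_dabg_pvalues",
    "presence_by_group",
    "filter_colon_design",
    "filter_tissue_design",
]


@dataclass
class PresenceCalls:
    probeset_present: pd.DataFrame  # probeset x group, bool
    transcript_present: pd.DataFrame  # transcript x group, bool
    dabg_p: pd.DataFrame  # probeset x sample


@dataclass
class FilterReport:
    kept_probesets: tuple
    kept_transcripts: tuple
    attrition: list  # ordered [(rule_name, n_probesets_removed), ...]

    @property
    def n_initial(self) -> int:
        return len(self.kept_probesets) + sum(n for _, n in self.attrition)

    def to_dict(self) -> dict:
        return {
            "kept_probesets": len(self.kept_probesets),
            "kept_transcripts": len(self.kept_transcripts),
            "attrition": [{"rule": r, "removed": int(n)} for r, n in self.attrition],
        }


# ---------------------------------------------------------------------------
# DABG surrogate
# ---------------------------------------------------------------------------

def probe_dabg_pvalues(dataset: ProbeLevelDataset) -> pd.DataFrame:
    """Per-probe empirical detection p-values against GC-matched background."""
    bg = dataset.background_intensities
    if bg is None or bg.empty:
        raise ValueError("dataset has no background intensities")
    samples = dataset.intensities.columns
    bg_bins = bg["gc_bin"]
    pm = dataset.intensities.values
    probe_bins = dataset.annotation["gc_bin"].reindex(dataset.intensities.index).to_numpy()
    out = np.empty_like(pm)
    for b in np.unique(probe_bins):
        rows = np.flatnonzero(probe_bins == b)
        bvals = bg.loc[bg_bins == b, samples].to_numpy()
        if bvals.shape[0] == 0:
            raise ValueError(f"no background probes for gc bin {b}")
        n_bg = bvals.shape[0]
        for j, s in enumerate(samples):
            col = np.sort(bvals[:, j])
            # #{background >= PM} via position of PM in the sorted background
            n_ge = n_bg - np.searchsorted(col, pm[rows, j], side="left")
            out[rows, j] = (1.0 + n_ge) / (1.0 + n_bg)
    return pd.DataFrame(out, index=dataset.intensities.index, columns=samples)


def dabg_pvalues(dataset: ProbeLevelDataset) -> pd.DataFrame:
    """Probeset-level DABG p-values (Fisher combination of probe p-values)."""
    probe_p = probe_dabg_pvalues(dataset)
    logs = np.log(probe_p.values)
    ps_ids = dataset.annotation["probeset_id"].reindex(probe_p.index)
    codes, uniques = pd.factorize(ps_ids, sort=False)
    n_units = len(uniques)
    stat = np.zeros((n_units, probe_p.shape[1]))
    counts = np.zeros(n_units)
    np.add.at(stat, codes, -2.0 * logs)
    np.add.at(counts, codes, 1.0)
    p = chi2.sf(stat, 2.0 * counts[:, None])
    return pd.DataFrame(
        np.clip(p, 0.0, 1.0),
        index=pd.Index(uniques, name="probeset_id"),
        columns=probe_p.columns,
    )


def presence_by_group(
    dabg_p: pd.DataFrame,
    design: pd.DataFrame,
    parent: pd.Series,
    alpha: float = 0.05,
    rule: tuple = ("fraction", 0.5),
) -> PresenceCalls:
    """Per-group presence flags from probeset DABG p-values.

    ``rule`` is ``('fraction', q)`` (detected in >= q of the group's samples,
    inclusive) or ``('count', k)`` (detected in >= k samples).  A transcript
    is present in a group when >= 50% of its probesets are present there.
    """
    kind, threshold = rule
    if kind not in ("fraction", "count"):
        raise ValueError("rule must be ('fraction', q) or ('count', k)")
    detected = dabg_p < alpha
    groups = list(dict.fromkeys(design["group"]))
    cols = {}
    for g in groups:
        members = design.index[design["group"] == g]
        if len(members) == 0:
            raise ValueError(f"group {g!r} has no samples")
        hits = detected[members].sum(axis=1)
        need = threshold * len(members) if kind == "fraction" else threshold
        cols[g] = hits >= need
    probeset_present = pd.DataFrame(cols)
    tx = parent.reindex(probeset_present.index)
    frac = probeset_present.groupby(tx).mean()
    transcript_present = frac >= 0.5
    transcript_present.index.name = "transcript_id"
    return PresenceCalls(probeset_present, transcript_present, dabg_p)


# ---------------------------------------------------------------------------
# cascades
# ---------------------------------------------------------------------------

def _apply_rules(probesets: pd.Index, rules) -> tuple[pd.Index, list]:
    attrition = []
    current = probesets
    for name, keep_mask_fn in rules:
        mask = keep_mask_fn(current)
        removed = int(len(current) - int(mask.sum()))
        attrition.append((name, removed))
        current = current[np.asarray(mask, dtype=bool)]
    return current, attrition


def filter_colon_design(
    calls: PresenceCalls,
    dataset: ProbeLevelDataset,
    gene_signal_linear: pd.DataFrame,
    min_gene_signal: float = 70.0,
) -> FilterReport:
    """Paired two-group cascade.

    Rules in order: (1) transcript present in BOTH groups; (2) probeset
    present in EITHER group; (3) cross-hybridization type 1 only; (4) parent
    gene's mean linear signal strictly greater than ``min_gene_signal``.
    """
    groups = dataset.groups
    if len(groups) != 2:
        raise ValueError("paired cascade expects exactly two groups")
    parent = dataset.transcript_of_probeset
    ps_all = calls.probeset_present.index
    tx_both = calls.transcript_present[groups].all(axis=1)
    ps_either = calls.probeset_present[groups].any(axis=1)
    crosshyb = (
        dataset.annotation.groupby("probeset_id")["crosshyb_type"].first()
    )
    gene_mean = gene_signal_linear.mean(axis=1)

    rules = [
        (
            "transcript_present_both_groups",
            lambda idx: tx_both.reindex(parent.reindex(idx)).fillna(False).to_numpy(),
        ),
        (
            "probeset_present_either_group",
            lambda idx: ps_either.reindex(idx).fillna(False).to_numpy(),
        ),
        (
            "crosshyb_type_1",
            lambda idx: (crosshyb.reindex(idx) == 1).to_numpy(),
        ),
        (
            "gene_signal_above_threshold",
            lambda idx: (
                gene_mean.reindex(parent.reindex(idx)).to_numpy() > min_gene_signal
            ),
        ),
    ]
    kept, attrition = _apply_rules(ps_all, rules)
    kept_tx = tuple(sorted(set(parent.reindex(kept))))
    report = FilterReport(tuple(kept), kept_tx, attrition)
    log.info("paired cascade: %s", report.to_dict())
    return report


def filter_tissue_design(
    calls: PresenceCalls,
    dataset: ProbeLevelDataset,
    gene_signals_by_method: dict,
    test_tissue: str,
    min_other_tissues: int = 5,
) -> FilterReport:
    """Multi-group tissue cascade.

    Rules in order: (1) probeset present in the test tissue or in at least
    ``min_other_tissues`` other tissues; (2) gene present in the test tissue
    and in at least ``min_other_tissues`` others; (3) cross-hybridization
    type 1; (4) gene mean log2 expression in the top 50% for every method in
    ``gene_signals_by_method`` (ties at the boundary kept).
    """
    groups = dataset.groups
    if test_tissue not in groups:
        raise ValueError(f"test tissue {test_tissue!r} not in design")
    if len(groups) < min_other_tissues + 1:
        raise ValueError("tissue cascade expects more tissues than the presence bound")
    parent = dataset.transcript_of_probeset
    others = [g for g in groups if g != test_tissue]
    ps_all = calls.probeset_present.index

    ps_ok = calls.probeset_present[test_tissue] | (
        calls.probeset_present[others].sum(axis=1) >= min_other_tissues
    )
    tx_ok = calls.transcript_present[test_tissue] & (
        calls.transcript_present[others].sum(axis=1) >= min_other_tissues
    )
    crosshyb = dataset.annotation.groupby("probeset_id")["crosshyb_type"].first()

    # the 50% rank is taken over the full summarized gene set (a fixed input),
    # which also makes the cascade idempotent
    tx_top = None
    for method, sig in gene_signals_by_method.items():
        means = sig.mean(axis=1)
        thr = np.sort(means.to_numpy())[::-1][ceil(len(means) / 2) - 1]
        ok = means >= thr
        tx_top = ok if tx_top is None else (tx_top & ok)

    def _top_half_ok(idx):
        return tx_top.reindex(parent.reindex(idx)).fillna(False).to_numpy()

    rules = [
        (
            "probeset_present_test_or_5_other_tissues",
            lambda idx: ps_ok.reindex(idx).fillna(False).to_numpy(),
        ),
        (
            "gene_present_test_and_5_other_tissues",
            lambda idx: tx_ok.reindex(parent.reindex(idx)).fillna(False).to_numpy(),
        ),
        ("crosshyb_type_1", lambda idx: (crosshyb.reindex(idx) == 1).to_numpy()),
        ("gene_mean_expression_top_half_all_methods", _top_half_ok),
    ]
    kept, attrition = _apply_rules(ps_all, rules)
    kept_tx = tuple(sorted(set(parent.reindex(kept))))
    report = FilterReport(tuple(kept), kept_tx, attrition)
    log.info("tissue cascade: %s", report.to_dict())
    return report
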
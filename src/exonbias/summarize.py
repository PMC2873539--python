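"""Probe summarization: RMA-style median polish and PLIER-style robust fits.

Both summarizers estimate one expression value per unit (probeset = exon, or
transcript cluster = gene) per sample from that unit's perfect-match probes.

* RMA track: optional quantile normalization across all probes, log2
  transform, then Tukey median polish of the probes x samples block; the
  sample effects (plus the overall term) are the log2 signal.
* PLIER track: fit the multiplicative model ``PM = t_i * f_j * e_ij + BKG_ij``
  by minimizing a robust (Huber-type) loss on ``r_ij = log(e_ij)`` with
  damped coordinate-wise Newton steps.  Gene-level signals can additionally
  use iterative probe selection ("iterPLIER"): after an initial fit, probes
  whose log intensity tracks the fitted log target response best are
  retained and the model re-fit, which concentrates the gene estimate on
  bright, concordant probes.

Identifiability of the multiplicative fit is resolved by constraining the
geometric mean of the feature responses ``f`` to 1, so the target response
``t`` carries the intensity scale.  PLIER-track signals are reported as
``log2(signal + offset)`` with a linear offset of 16 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic import ConfigError, ProbeLevelDataset

log = logging.getLogger(__name__)

__all__ = [
    "SummarizationOptions",
    "MultiplicativeFit",
    "SummarizedExpression",
    "quantile_normalize",
    "median_polish",
    "rma_summarize",
    "plier_fit",
    "iterplier_fit",
    "iterplier_summarize",
    "apply_gcbg_background",
    "to_log2",
    "summarize",
]

#: linear floor applied to background-subtracted intensities before taking logs
PM_FLOOR = 0.5


def _background_adjust(pm: np.ndarray, bkg) -> np.ndarray:
    """``pm - bkg`` floored at min(pm, PM_FLOOR) so logs stay defined.

    The floor only binds when subtraction drives a value to ~0; raw PM
    (``bkg == 0``) passes through untouched.
    """
    if bkg is None:
        return pm
    return np.maximum(pm - bkg, np.minimum(pm, PM_FLOOR))


@dataclass(frozen=True)
class SummarizationOptions:
    method: str = "rma"  # rma | plier | iterplier
    background: str = "pm"  # pm | pm-gcbg
    plier_offset: float = 16.0
    z: float = 5.0
    newton_max_iter: int = 100
    newton_tol: float = 1e-8
    iterplier_keep_fraction: float = 0.5
    iterplier_min_probes: int = 8
    iterplier_rounds: int = 2
    quantile_normalize: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("rma", "plier", "iterplier"):
            raise ConfigError("field 'method' must be rma, plier or iterplier")
        if self.background not in ("pm", "pm-gcbg"):
            raise ConfigError("field 'background' must be 'pm' or 'pm-gcbg'")
        if self.z <= 0:
            raise ConfigError("field 'z' must be > 0")
        if not 0 < self.iterplier_keep_fraction <= 1:
            raise ConfigError("field 'iterplier_keep_fraction' must be in (0, 1]")
        if self.plier_offset < 0:
            raise ConfigError("field 'plier_offset' must be >= 0")
        if self.newton_max_iter < 1 or self.iterplier_rounds < 0:
            raise ConfigError("iteration counts must be positive")


@dataclass
class MultiplicativeFit:
    """Result of one robust multiplicative fit on a probes x samples block."""

    t: np.ndarray  # target response per sample (linear)
    f: np.ndarray  # feature response per probe (linear, geometric mean 1)
    residuals: np.ndarray  # r_ij = log(e_ij), probes x samples
    loss: float
    converged: bool
    n_iter: int
    probes_used: tuple
    n_gradient_fallbacks: int = 0


@dataclass
class SummarizedExpression:
    """Log2-scale exon- and gene-level signal matrices with provenance."""

    exon_signal: pd.DataFrame
    gene_signal: pd.DataFrame
    options: SummarizationOptions
    scale_note: dict = field(default_factory=dict)
    exon_signal_linear: pd.DataFrame | None = None
    gene_signal_linear: pd.DataFrame | None = None
    probes_used: dict | None = None


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(intensities):
    """Force every column onto the mean empirical distribution.

    Each column's sorted values are replaced by the row-wise mean of all
    columns' sorted values; tied entries receive the mean of their tied
    positions (average ranks, linearly interpolated into the target
    quantiles).  A single-column matrix is returned unchanged.
    """
    is_df = isinstance(intensities, pd.DataFrame)
    X = np.asarray(intensities, dtype=float)
    if X.ndim != 2:
        raise ValueError("quantile_normalize expects a 2-D matrix")
    n, m = X.shape
    if m < 2:
        log.info("quantile_normalize: single column, returned unchanged")
        return intensities
    if (X <= 0).any():
        raise ValueError("quantile_normalize expects strictly positive intensities")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, target)
    if is_df:
        return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)
    return out


# ---------------------------------------------------------------------------
# median polish (RMA)
# ---------------------------------------------------------------------------

def median_polish(x, max_iter: int = 10, tol: float = 1e-9):
    """Tukey two-way median polish of a probes x samples matrix.

    Returns ``(overall, sample_effects, probe_effects, residuals)`` with
    ``x ~ overall + probe_effects[:, None] + sample_effects[None, :] +
    residuals``.  Row and column medians of the residuals are ~0 at
    convergence; iteration is capped at ``max_iter`` full sweeps.
    """
    z = np.array(x, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish expects a non-empty 2-D matrix")
    if not np.isfinite(z).all():
        raise ValueError("median_polish expects finite entries")
    nr, nc = z.shape
    overall = 0.0
    row = np.zeros(nr)
    col = np.zeros(nc)
    oldsum = 0.0
    for _ in range(max_iter):
        rdelta = np.median(z, axis=1)
        z -= rdelta[:, None]
        row += rdelta
        delta = np.median(col)
        col -= delta
        overall += delta
        cdelta = np.median(z, axis=0)
        z -= cdelta[None, :]
        col += cdelta
        delta = np.median(row)
        row -= delta
        overall += delta
        newsum = np.abs(z).sum()
        if newsum == 0 or abs(newsum - oldsum) < tol * max(1.0, newsum):
            break
        oldsum = newsum
    return overall, col, row, z


def rma_summarize(
    dataset: ProbeLevelDataset,
    level: str = "both",
    options: SummarizationOptions | None = None,
) -> SummarizedExpression:
    """RMA-style summarization: per-unit median polish of log2 intensities.

    ``level`` selects 'probeset', 'transcript' or 'both'.  Per unit, the log2
    signal for sample *i* is ``overall + sample_effect_i`` from the median
    polish of that unit's probes.
    """
    opts = options or SummarizationOptions(method="rma")
    X = _prepare_intensities(dataset, opts)
    L = np.log2(X.values)
    want = {"probeset", "transcript"} if level == "both" else {level}
    if not want <= {"probeset", "transcript"}:
        raise ValueError("level must be 'probeset', 'transcript' or 'both'")
    signals = {}
    for lev in sorted(want):
        key = "probeset_id" if lev == "probeset" else "transcript_id"
        rows = []
        ids = []
        for unit, idx in _unit_indices(dataset, key, X.index):
            if len(idx) == 0:
                log.warning("unit %s has no probes after filtering; omitted", unit)
                continue
            overall, col, _, _ = median_polish(L[idx])
            rows.append(overall + col)
            ids.append(unit)
        signals[lev] = pd.DataFrame(
            np.vstack(rows), index=pd.Index(ids, name=key), columns=X.columns
        )
    exon = signals.get("probeset", pd.DataFrame())
    gene = signals.get("transcript", pd.DataFrame())
    return SummarizedExpression(
        exon_signal=exon,
        gene_signal=gene,
        options=opts,
        scale_note={"scale": "log2", "offset": 0.0, "method": "rma"},
        exon_signal_linear=2.0 ** exon if len(exon) else None,
        gene_signal_linear=2.0 ** gene if len(gene) else None,
    )


# ---------------------------------------------------------------------------
# PLIER-style robust multiplicative fit
# ---------------------------------------------------------------------------

def _huber_loss(r: np.ndarray, z: float) -> float:
    a = np.abs(r)
    return float(np.where(a <= z, 0.5 * r * r, z * a - 0.5 * z * z).sum())


def plier_fit(
    pm,
    bkg=None,
    z: float = 5.0,
    max_iter: int = 100,
    tol: float = 1e-8,
    probe_ids=None,
) -> MultiplicativeFit:
    """Fit ``PM = t_i f_j e_ij + BKG_ij`` by robust loss minimization.

    Background-adjusted intensities are floored at ``PM_FLOOR`` and
    log-transformed; the residual ``r_ij = log(e_ij)`` is then an additive
    two-way term and the Huber-type loss ``G(r) = r^2/2`` (``|r| <= z``) /
    ``z|r| - z^2/2`` is minimized by alternating damped Newton updates of
    ``log t`` and ``log f`` (each block is separable given the other).  Steps
    are halved until the loss does not increase; coordinates whose local
    curvature vanishes (all residuals beyond ``z``) fall back to a damped
    gradient step, counted in ``n_gradient_fallbacks``.  The geometric mean of
    ``f`` is constrained to 1.
    """
    pm = np.asarray(pm, dtype=float)
    if pm.ndim != 2 or pm.size == 0:
        raise ValueError("plier_fit expects a non-empty probes x samples matrix")
    if (pm <= 0).any():
        raise ValueError("plier_fit expects strictly positive PM intensities")
    if bkg is not None:
        bkg = np.asarray(bkg, dtype=float)
        if bkg.shape not in ((), pm.shape):
            raise ValueError("bkg must be scalar or match pm's shape")
        if (bkg < 0).any():
            raise ValueError("bkg must be >= 0")
    y = np.log(_background_adjust(pm, bkg))
    J, I = y.shape

    mu = np.median(y, axis=0)  # log t per sample
    phi = np.median(y - mu[None, :], axis=1)  # log f per probe
    shift = phi.mean()
    phi -= shift
    mu += shift
    loss = _huber_loss(y - phi[:, None] - mu[None, :], z)
    converged = False
    n_fallback = 0
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        loss_start = loss
        for axis in (0, 1):  # 0: update mu (samples), 1: update phi (probes)
            r = y - phi[:, None] - mu[None, :]
            psi = np.clip(r, -z, z)
            inlier = np.abs(r) <= z
            num = psi.sum(axis=axis)
            den = inlier.sum(axis=axis).astype(float)
            bad = den == 0
            if bad.any():
                n_fallback += int(bad.sum())
                log.debug("plier_fit: %d coordinate(s) lost curvature; gradient step", bad.sum())
                den = np.where(bad, 1.0, den)
            step = num / den
            s = 1.0
            for _ in range(40):
                if axis == 0:
                    cand_mu, cand_phi = mu + s * step, phi
                else:
                    cand_mu, cand_phi = mu, phi + s * step
                new_loss = _huber_loss(y - cand_phi[:, None] - cand_mu[None, :], z)
                if new_loss <= loss + 1e-12:
                    break
                s *= 0.5
            else:
                cand_mu, cand_phi, new_loss = mu, phi, loss
            mu, phi, loss = cand_mu, cand_phi, new_loss
        shift = phi.mean()
        phi -= shift
        mu += shift
        if abs(loss_start - loss) <= tol * max(1.0, abs(loss_start)):
            converged = True
            break
    residuals = y - phi[:, None] - mu[None, :]
    if probe_ids is None:
        probe_ids = tuple(range(J))
    return MultiplicativeFit(
        t=np.exp(mu),
        f=np.exp(phi),
        residuals=residuals,
        loss=loss,
        converged=converged,
        n_iter=n_iter,
        probes_used=tuple(probe_ids),
        n_gradient_fallbacks=n_fallback,
    )


def iterplier_fit(
    pm,
    bkg=None,
    options: SummarizationOptions | None = None,
    probe_ids=None,
) -> MultiplicativeFit:
    """PLIER fit with iterative probe selection.

    After each fit, probes are ranked by the Pearson correlation between
    their log background-adjusted intensity and the fitted ``log t`` across
    samples; the top ``iterplier_keep_fraction`` (never fewer than
    ``iterplier_min_probes``) are retained and the model re-fit.  Iteration
    stops early once the retained set cannot shrink further.
    """
    opts = options or SummarizationOptions(method="iterplier")
    pm = np.asarray(pm, dtype=float)
    J = pm.shape[0]
    if probe_ids is None:
        probe_ids = tuple(range(J))
    probe_ids = np.asarray(probe_ids, dtype=object)
    bkg_arr = None if bkg is None else np.asarray(bkg, dtype=float)

    keep = np.arange(J)
    fit = plier_fit(
        pm, bkg_arr, z=opts.z, max_iter=opts.newton_max_iter,
        tol=opts.newton_tol, probe_ids=probe_ids,
    )
    for _ in range(opts.iterplier_rounds):
        n = len(keep)
        if n <= opts.iterplier_min_probes:
            log.debug("iterplier: %d probes at floor; stopping", n)
            break
        k = max(opts.iterplier_min_probes, ceil(opts.iterplier_keep_fraction * n))
        if k >= n:
            break
        sub_pm = pm[keep]
        sub_bkg = bkg_arr[keep] if isinstance(bkg_arr, np.ndarray) and bkg_arr.ndim == 2 else bkg_arr
        y = np.log(_background_adjust(sub_pm, sub_bkg))
        target = np.log(fit.t)
        yc = y - y.mean(axis=1, keepdims=True)
        tc = target - target.mean()
        denom = np.sqrt((yc ** 2).sum(axis=1) * (tc ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (yc @ tc) / denom
        corr = np.where(np.isfinite(corr), corr, -np.inf)
        order = np.argsort(-corr, kind="stable")
        # probes tied with the k-th ranked correlation are all retained, so a
        # perfectly concordant probe set is never trimmed
        cutoff = corr[order[k - 1]]
        selected = np.flatnonzero(corr >= cutoff - 1e-12)
        if len(selected) >= n:
            break
        keep = keep[np.sort(selected)]
        sub_pm = pm[keep]
        sub_bkg = bkg_arr[keep] if isinstance(bkg_arr, np.ndarray) and bkg_arr.ndim == 2 else bkg_arr
        fit = plier_fit(
            sub_pm, sub_bkg, z=opts.z, max_iter=opts.newton_max_iter,
            tol=opts.newton_tol, probe_ids=probe_ids[keep],
        )
    return fit


def iterplier_summarize(
    dataset: ProbeLevelDataset,
    options: SummarizationOptions | None = None,
) -> SummarizedExpression:
    """Full PLIER-track summarization of a dataset.

    Gene-level signals come from :func:`iterplier_fit` (or a plain
    :func:`plier_fit` when ``options.method == 'plier'``) per transcript;
    exon-level signals from a plain PLIER fit per probeset.  Linear target
    responses are shifted by ``plier_offset`` and log2-transformed.
    """
    opts = options or SummarizationOptions(method="iterplier")
    X = _prepare_intensities(dataset, opts, subtract_background=False)
    bkg_full = _background_matrix(dataset, opts, X)

    exon_rows, exon_ids = [], []
    for unit, idx in _unit_indices(dataset, "probeset_id", X.index):
        fit = plier_fit(
            X.values[idx],
            None if bkg_full is None else bkg_full[idx],
            z=opts.z, max_iter=opts.newton_max_iter, tol=opts.newton_tol,
        )
        exon_rows.append(fit.t)
        exon_ids.append(unit)
    exon_linear = pd.DataFrame(
        np.vstack(exon_rows), index=pd.Index(exon_ids, name="probeset_id"), columns=X.columns
    )

    gene_rows, gene_ids, used = [], [], {}
    probe_index = np.asarray(X.index, dtype=object)
    for unit, idx in _unit_indices(dataset, "transcript_id", X.index):
        sub_bkg = None if bkg_full is None else bkg_full[idx]
        if opts.method == "iterplier":
            fit = iterplier_fit(X.values[idx], sub_bkg, opts, probe_ids=probe_index[idx])
        else:
            fit = plier_fit(
                X.values[idx], sub_bkg, z=opts.z,
                max_iter=opts.newton_max_iter, tol=opts.newton_tol,
                probe_ids=probe_index[idx],
            )
        gene_rows.append(fit.t)
        gene_ids.append(unit)
        used[unit] = tuple(fit.probes_used)
    gene_linear = pd.DataFrame(
        np.vstack(gene_rows), index=pd.Index(gene_ids, name="transcript_id"), columns=X.columns
    )

    return SummarizedExpression(
        exon_signal=to_log2(exon_linear, opts.plier_offset),
        gene_signal=to_log2(gene_linear, opts.plier_offset),
        options=opts,
        scale_note={
            "scale": "log2",
            "offset": opts.plier_offset,
            "method": opts.method,
            "background": opts.background,
        },
        exon_signal_linear=exon_linear,
        gene_signal_linear=gene_linear,
        probes_used=used,
    )


# ---------------------------------------------------------------------------
# background and scale helpers
# ---------------------------------------------------------------------------

def apply_gcbg_background(pm: pd.DataFrame, background_intensities: pd.DataFrame, gc_bins: pd.Series) -> np.ndarray:
    """GC-binned background matrix aligned to ``pm``'s probes.

    ``bkg_ij`` is the median intensity of the background probes in probe
    *j*'s GC bin, per sample *i*.
    """
    bg_bins = background_intensities["gc_bin"]
    bg_vals = background_intensities[pm.columns]
    medians = bg_vals.groupby(bg_bins).median()  # bin x sample
    probe_bins = gc_bins.reindex(pm.index)
    missing = sorted(set(probe_bins.unique()) - set(medians.index))
    if missing:
        raise ValueError(f"no background probes for gc bin(s): {missing}")
    return medians.loc[probe_bins].to_numpy()


def to_log2(signal, offset: float = 0.0):
    """``log2(signal + offset)`` with positivity checking."""
    vals = np.asarray(signal, dtype=float) + offset
    if (vals <= 0).any():
        bad = np.argwhere(vals <= 0)[:10]
        raise ValueError(f"non-positive signal+offset at positions {bad.tolist()}")
    out = np.log2(vals)
    if isinstance(signal, pd.DataFrame):
        return pd.DataFrame(out, index=signal.index, columns=signal.columns)
    return out


def _prepare_intensities(
    dataset: ProbeLevelDataset,
    opts: SummarizationOptions,
    subtract_background: bool = True,
) -> pd.DataFrame:
    """Optionally quantile-normalize; for RMA also subtract gc background."""
    X = dataset.intensities
    if opts.quantile_normalize and X.shape[1] >= 2:
        X = quantile_normalize(X)
    if subtract_background and opts.background == "pm-gcbg":
        bkg = apply_gcbg_background(
            X, dataset.background_intensities, dataset.annotation["gc_bin"]
        )
        X = pd.DataFrame(
            _background_adjust(X.values, bkg), index=X.index, columns=X.columns
        )
    return X


def _background_matrix(dataset, opts, X) -> np.ndarray | None:
    if opts.background == "pm":
        return None
    return apply_gcbg_background(X, dataset.background_intensities, dataset.annotation["gc_bin"])


def _unit_indices(dataset: ProbeLevelDataset, key: str, probe_index):
    """Yield (unit_id, row-index array) in stable annotation order."""
    ann = dataset.annotation.reindex(probe_index)
    codes, uniques = pd.factorize(ann[key], sort=False)
    for u_i, unit in enumerate(uniques):
        yield unit, np.flatnonzero(codes == u_i)


def summarize(dataset: ProbeLevelDataset, options: SummarizationOptions) -> SummarizedExpression:
    """Dispatch to the RMA or PLIER track based on ``options.method``."""
    if options.method == "rma":
        return rma_summarize(dataset, "both", options)
    return iterplier_summarize(dataset, options)
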
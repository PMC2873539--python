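"""Synthetic probe-level exon-array data with known expression and splicing truth.

Data are generated under the multiplicative probe model

    PM_ij = t_i * f_j * e_ij + BKG_ij

where ``t_i`` is the target response (linear-scale abundance of the targeted
exon in array *i*), ``f_j`` the feature response (probe affinity), ``e_ij`` a
log-normal multiplicative error, and ``BKG_ij`` a GC-content-specific additive
background.  Each gene (transcript cluster) carries several probesets (exons),
each probeset four perfect-match probes by default.  Ground truth -- gene-level
log2 expression per group, exon-level log2 inclusion per group, and the set of
skipped/included exons -- is recorded alongside the intensities so downstream
summarization and splicing statistics can be scored against it.

The generator supports the two experimental designs exercised downstream: a
paired two-group comparison (tumour vs. matched normal) and a multi-group
tissue panel with a small number of replicates per tissue.  An optional
``intensity_effect_coupling`` makes the magnitude of an exon's fold change grow
with its baseline expression, the data feature that drives the gene-level
over-estimation bias probed by the analysis layer.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "PairedTwoGroup",
    "MultiGroup",
    "SimulationConfig",
    "GroundTruth",
    "ProbeLevelDataset",
    "simulate_dataset",
    "simulate_background",
    "inject_splicing",
    "write_dataset",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


# ---------------------------------------------------------------------------
# experimental designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTwoGroup:
    """Paired two-group design: ``n_pairs`` matched (reference, test) samples."""

    n_pairs: int = 10
    reference_group: str = "normal"
    test_group: str = "cancer"

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ConfigError("design.n_pairs must be >= 2")
        if self.reference_group == self.test_group:
            raise ConfigError("design group labels must differ")

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for k in range(1, self.n_pairs + 1):
            for g in (self.reference_group, self.test_group):
                rows.append((f"{g}_{k:02d}", g, f"pair{k:02d}"))
        return pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"]).set_index(
            "sample_id"
        )

    @property
    def groups(self) -> list[str]:
        return [self.reference_group, self.test_group]


@dataclass(frozen=True)
class MultiGroup:
    """Multi-group design: ``n_groups`` tissues, ``n_replicates`` each."""

    n_groups: int = 11
    n_replicates: int = 3

    def validate(self) -> None:
        if self.n_groups < 2:
            raise ConfigError("design.n_groups must be >= 2")
        if self.n_replicates < 2:
            raise ConfigError("design.n_replicates must be >= 2")

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for g in range(1, self.n_groups + 1):
            for r in range(1, self.n_replicates + 1):
                rows.append((f"tissue{g:02d}_r{r}", f"tissue{g:02d}", ""))
        return pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"]).set_index(
            "sample_id"
        )

    @property
    def test_group(self) -> str:
        return "tissue01"

    @property
    def groups(self) -> list[str]:
        return [f"tissue{g:02d}" for g in range(1, self.n_groups + 1)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the probe-level generator.

    Log-scale noise and affinity spreads (``noise_sd_log``,
    ``affinity_sd_log``) are natural-log standard deviations of the
    log-normal factors ``e_ij`` and ``f_j``.  Expression quantities
    (baselines, fold changes, inclusion deltas) are on the log2 scale.
    """

    n_genes: int = 500
    exons_per_gene: int | tuple[int, int] = 8
    probes_per_exon: int = 4
    design: PairedTwoGroup | MultiGroup = field(default_factory=PairedTwoGroup)
    frac_de_genes: float = 0.3
    de_log2fc_mean: float = 0.0
    de_log2fc_sd: float = 1.5
    frac_as_exons: float = 0.0
    as_delta_ni: float = 1.0
    noise_sd_log: float = 0.25
    affinity_sd_log: float = 0.7
    exon_baseline_sd: float = 1.5
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    pair_effect_sd: float = 0.0
    intensity_effect_coupling: float = 0.0
    background_mean: float = 40.0
    background_sd: float = 8.0
    n_gc_bins: int = 5
    crosshyb_type1_prob: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "probes_per_exon": self.probes_per_exon,
            "n_gc_bins": self.n_gc_bins,
        }
        for name, val in counts.items():
            if not isinstance(val, (int, np.integer)) or val < 1:
                raise ConfigError(f"field '{name}' must be an integer >= 1")
        epg = self.exons_per_gene
        if isinstance(epg, (int, np.integer)):
            if epg < 1:
                raise ConfigError("field 'exons_per_gene' must be >= 1")
        else:
            try:
                lo, hi = epg
            except (TypeError, ValueError):
                raise ConfigError(
                    "field 'exons_per_gene' must be an int or a (lo, hi) pair"
                ) from None
            if lo < 1 or hi < lo:
                raise ConfigError("field 'exons_per_gene' range must satisfy 1 <= lo <= hi")
        fractions = {
            "frac_de_genes": self.frac_de_genes,
            "frac_as_exons": self.frac_as_exons,
            "crosshyb_type1_prob": self.crosshyb_type1_prob,
        }
        for name, val in fractions.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"field '{name}' must lie in [0, 1]")
        nonneg = {
            "de_log2fc_sd": self.de_log2fc_sd,
            "as_delta_ni": self.as_delta_ni,
            "noise_sd_log": self.noise_sd_log,
            "affinity_sd_log": self.affinity_sd_log,
            "exon_baseline_sd": self.exon_baseline_sd,
            "baseline_log2_sd": self.baseline_log2_sd,
            "pair_effect_sd": self.pair_effect_sd,
            "intensity_effect_coupling": self.intensity_effect_coupling,
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
        }
        for name, val in nonneg.items():
            if not np.isfinite(val) or val < 0:
                raise ConfigError(f"field '{name}' must be finite and >= 0")
        if not isinstance(self.design, (PairedTwoGroup, MultiGroup)):
            raise ConfigError("field 'design' must be PairedTwoGroup or MultiGroup")
        self.design.validate()
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("field 'seed' must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["design"] = {"kind": type(self.design).__name__, **dataclasses.asdict(self.design)}
        if not isinstance(self.exons_per_gene, (int, np.integer)):
            d["exons_per_gene"] = list(self.exons_per_gene)
        return d

    @staticmethod
    def from_dict(d: dict) -> "SimulationConfig":
        d = dict(d)
        design = d.get("design")
        if isinstance(design, dict):
            design = dict(design)
            kind = design.pop("kind", "PairedTwoGroup")
            cls = {"PairedTwoGroup": PairedTwoGroup, "MultiGroup": MultiGroup}.get(kind)
            if cls is None:
                raise ConfigError(f"field 'design.kind' unknown: {kind!r}")
            d["design"] = cls(**design)
        epg = d.get("exons_per_gene")
        if isinstance(epg, list):
            d["exons_per_gene"] = tuple(epg)
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimulationConfig field(s): {sorted(unknown)}")
        return SimulationConfig(**d)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """True generative quantities on the log2 scale.

    ``gene_log2_expression``: transcript x group baseline-plus-fold-change.
    ``exon_inclusion_log2``: probeset x group deviation of the exon from its
    gene (the quantity NI estimates).  ``as_labels``: the injected
    alternatively spliced probesets with their direction relative to the
    test group.
    """

    gene_log2_expression: pd.DataFrame
    exon_inclusion_log2: pd.DataFrame
    as_labels: frozenset

    def with_updates(self, exon_inclusion_log2=None, as_labels=None) -> "GroundTruth":
        return GroundTruth(
            gene_log2_expression=self.gene_log2_expression,
            exon_inclusion_log2=(
                self.exon_inclusion_log2 if exon_inclusion_log2 is None else exon_inclusion_log2
            ),
            as_labels=self.as_labels if as_labels is None else as_labels,
        )


@dataclass(frozen=True)
class ProbeLevelDataset:
    """Linear-scale probe intensities plus annotation, design and truth.

    ``intensities``: probe x sample (strictly positive, linear scale).
    ``annotation``: per probe -> probeset_id, transcript_id, crosshyb_type,
    gc_bin.  ``background_intensities``: background-probe x sample with a
    leading ``gc_bin`` column.  ``test_group`` names the group in which
    ground-truth effects (fold changes, splicing deltas) were applied for the
    paired design; for the multi-group design each gene has its own target
    group recorded in the truth tables.
    """

    intensities: pd.DataFrame
    annotation: pd.DataFrame
    design: pd.DataFrame
    background_intensities: pd.DataFrame
    truth: GroundTruth | None = None
    test_group: str = "cancer"
    config: SimulationConfig | None = None

    @property
    def probeset_of(self) -> pd.Series:
        return self.annotation["probeset_id"]

    @property
    def transcript_of_probeset(self) -> pd.Series:
        tab = self.annotation[["probeset_id", "transcript_id"]].drop_duplicates()
        return tab.set_index("probeset_id")["transcript_id"]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.design["group"]))

    def validate(self) -> None:
        if (self.intensities.values <= 0).any():
            raise ValueError("intensities must be strictly positive")
        per_probe = self.annotation.groupby(level=0)["probeset_id"].nunique()
        if (per_probe > 1).any():
            raise ValueError("every probe must map to exactly one probeset")
        per_ps = self.annotation.groupby("probeset_id")["transcript_id"].nunique()
        if (per_ps > 1).any():
            raise ValueError("every probeset must map to exactly one transcript")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _gc_bin_levels(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin background mean and sd.  GC-richer bins get brighter background."""
    if config.n_gc_bins == 1:
        scale = np.array([1.0])
    else:
        scale = np.linspace(0.7, 1.3, config.n_gc_bins)
    return config.background_mean * scale, config.background_sd * scale


def simulate_background(
    config: SimulationConfig,
    n_background_probes_per_bin: int = 60,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Background-probe intensity matrix, one block of probes per GC bin.

    Values are Gaussian around the bin-specific background level, floored at
    0.5 so they remain positive.  Deterministic for a fixed config seed.
    """
    if n_background_probes_per_bin < 1:
        raise ConfigError("field 'n_background_probes_per_bin' must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    samples = config.design.sample_table().index
    means, sds = _gc_bin_levels(config)
    blocks, bins, ids = [], [], []
    for b in range(config.n_gc_bins):
        vals = rng.normal(means[b], sds[b], size=(n_background_probes_per_bin, len(samples)))
        blocks.append(np.maximum(vals, 0.5))
        bins.extend([b] * n_background_probes_per_bin)
        ids.extend(f"bg_b{b}_{k:03d}" for k in range(n_background_probes_per_bin))
    out = pd.DataFrame(np.vstack(blocks), index=pd.Index(ids, name="bg_probe_id"), columns=samples)
    out.insert(0, "gc_bin", bins)
    return out


def simulate_dataset(config: SimulationConfig) -> ProbeLevelDataset:
    """Draw a probe-level dataset (with ground truth) under the configured model.

    The random stream is a single seeded generator; draw order is fixed, so an
    identical config (including seed) yields bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design_tab = config.design.sample_table()
    sample_groups = design_tab["group"].to_numpy()
    groups = config.design.groups
    n_samples = len(design_tab)

    # gene / exon / probe bookkeeping
    if isinstance(config.exons_per_gene, (int, np.integer)):
        exons_per_gene = np.full(config.n_genes, int(config.exons_per_gene))
    else:
        lo, hi = config.exons_per_gene
        exons_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    gene_ids = np.array([f"g{i:05d}" for i in range(1, config.n_genes + 1)])
    gene_idx_of_exon = np.repeat(np.arange(config.n_genes), exons_per_gene)
    n_exons = int(exons_per_gene.sum())
    exon_rank = np.concatenate([np.arange(1, k + 1) for k in exons_per_gene])
    probeset_ids = np.array(
        [f"{gene_ids[g]}_e{r:02d}" for g, r in zip(gene_idx_of_exon, exon_rank)]
    )
    exon_idx_of_probe = np.repeat(np.arange(n_exons), config.probes_per_exon)
    probe_rank = np.tile(np.arange(1, config.probes_per_exon + 1), n_exons)
    probe_ids = np.array(
        [f"{probeset_ids[e]}_p{r}" for e, r in zip(exon_idx_of_probe, probe_rank)]
    )
    n_probes = len(probe_ids)

    # gene baselines and exon baseline offsets (log2)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    offset = rng.normal(0.0, config.exon_baseline_sd, n_exons)

    # standardize offsets within gene for the intensity-effect coupling
    z = np.zeros(n_exons)
    if config.intensity_effect_coupling > 0:
        off = pd.Series(offset)
        grp = off.groupby(gene_idx_of_exon)
        mu, sd = grp.transform("mean"), grp.transform(lambda s: s.std(ddof=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            zz = (off - mu) / sd
        z = zz.fillna(0.0).replace([np.inf, -np.inf], 0.0).to_numpy()

    # differential expression: exact count of DE genes, random fold changes
    n_de = int(round(config.frac_de_genes * config.n_genes))
    de_genes = rng.choice(config.n_genes, size=n_de, replace=False)
    fc = np.zeros(config.n_genes)
    fc[de_genes] = rng.normal(config.de_log2fc_mean, config.de_log2fc_sd, n_de)

    # each gene's effects land in one target group (fixed test group for the
    # paired design, a random tissue for the multi-group design)
    if isinstance(config.design, PairedTwoGroup):
        target_group = np.full(config.n_genes, config.design.test_group, dtype=object)
    else:
        target_group = rng.choice(np.array(groups, dtype=object), size=config.n_genes)

    # exon-level realized fold change: coupled to baseline expression
    coupling_factor = np.maximum(0.0, 1.0 + config.intensity_effect_coupling * z)
    exon_fc = fc[gene_idx_of_exon] * coupling_factor

    # alternative splicing: exact count of AS exons, random direction
    n_as = int(round(config.frac_as_exons * n_exons))
    as_exons = rng.choice(n_exons, size=n_as, replace=False) if n_as else np.array([], dtype=int)
    as_direction = rng.choice(np.array(["skipped", "included"], dtype=object), size=n_as)
    as_delta = np.zeros(n_exons)
    for e_i, d in zip(as_exons, as_direction):
        as_delta[e_i] = -config.as_delta_ni if d == "skipped" else config.as_delta_ni

    # per-pair biological effects (paired design only)
    if isinstance(config.design, PairedTwoGroup) and config.pair_effect_sd > 0:
        pair_eff = rng.normal(0.0, config.pair_effect_sd, (config.n_genes, config.design.n_pairs))
        pair_idx = np.array(
            [int(p.replace("pair", "")) - 1 for p in design_tab["pair_id"]]
        )
        pair_term = pair_eff[gene_idx_of_exon][:, pair_idx]
    else:
        pair_term = 0.0

    # true exon-level log2 expression per sample
    in_target = (
        target_group[gene_idx_of_exon][:, None] == sample_groups[None, :]
    )
    shift = (exon_fc + as_delta)[:, None] * in_target
    exon_log2 = baseline[gene_idx_of_exon][:, None] + offset[:, None] + shift + pair_term
    t_lin = 2.0 ** exon_log2

    # probe-level multiplicative model
    f = np.exp(rng.normal(0.0, config.affinity_sd_log, n_probes))
    e = (
        np.exp(rng.normal(0.0, config.noise_sd_log, (n_probes, n_samples)))
        if config.noise_sd_log > 0
        else np.ones((n_probes, n_samples))
    )
    gc_bin = rng.integers(0, config.n_gc_bins, n_probes)
    bin_means, _ = _gc_bin_levels(config)
    pm = t_lin[exon_idx_of_probe] * f[:, None] * e + bin_means[gc_bin][:, None]

    crosshyb = np.where(rng.random(n_probes) < config.crosshyb_type1_prob, 1, 2)

    background = simulate_background(config, rng=rng)

    intensities = pd.DataFrame(
        pm, index=pd.Index(probe_ids, name="probe_id"), columns=design_tab.index
    )
    annotation = pd.DataFrame(
        {
            "probeset_id": probeset_ids[exon_idx_of_probe],
            "transcript_id": gene_ids[gene_idx_of_exon][exon_idx_of_probe],
            "crosshyb_type": crosshyb,
            "gc_bin": gc_bin,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # ground truth tables
    gene_truth = pd.DataFrame(
        baseline[:, None] + fc[:, None] * (target_group[:, None] == np.array(groups, dtype=object)[None, :]),
        index=pd.Index(gene_ids, name="transcript_id"),
        columns=groups,
    )
    incl_shift = (exon_fc - fc[gene_idx_of_exon]) + as_delta
    exon_truth = pd.DataFrame(
        offset[:, None]
        + incl_shift[:, None] * (target_group[gene_idx_of_exon][:, None] == np.array(groups, dtype=object)[None, :]),
        index=pd.Index(probeset_ids, name="probeset_id"),
        columns=groups,
    )
    labels = frozenset(
        (probeset_ids[e_i], str(d)) for e_i, d in zip(as_exons, as_direction)
    )
    truth = GroundTruth(gene_truth, exon_truth, labels)

    test_group = (
        config.design.test_group
        if isinstance(config.design, PairedTwoGroup)
        else config.design.test_group
    )
    ds = ProbeLevelDataset(
        intensities=intensities,
        annotation=annotation,
        design=design_tab,
        background_intensities=background,
        truth=truth,
        test_group=test_group,
        config=config,
    )
    ds.validate()
    return ds


def inject_splicing(
    dataset: ProbeLevelDataset,
    probeset_id: str,
    direction: str,
    delta: float,
    group: str | None = None,
) -> ProbeLevelDataset:
    """Return a copy of ``dataset`` with one probeset's inclusion shifted.

    ``direction='skipped'`` lowers the probeset's intensities in the target
    group by ``delta`` log2 units (divides by ``2**delta`` on the linear
    scale); ``'included'`` raises them.  Ground truth is updated to match.
    """
    if direction not in ("skipped", "included"):
        raise ConfigError("field 'direction' must be 'skipped' or 'included'")
    if not np.isfinite(delta):
        raise ConfigError("field 'delta' must be finite")
    if probeset_id not in set(dataset.annotation["probeset_id"]):
        raise KeyError(f"unknown probeset_id: {probeset_id!r}")
    group = group or dataset.test_group
    if group not in dataset.groups:
        raise ConfigError(f"field 'group' unknown: {group!r}")

    signed = -delta if direction == "skipped" else delta
    factor = 2.0 ** signed
    intens = dataset.intensities.copy()
    probe_mask = (dataset.annotation["probeset_id"] == probeset_id).to_numpy()
    col_mask = (dataset.design["group"] == group).to_numpy()
    block = intens.values[np.ix_(probe_mask, col_mask)] * factor
    vals = intens.values.copy()
    vals[np.ix_(probe_mask, col_mask)] = block
    intens = pd.DataFrame(vals, index=intens.index, columns=intens.columns)

    truth = dataset.truth
    if truth is not None:
        excl = truth.exon_inclusion_log2.copy()
        excl.loc[probeset_id, group] += signed
        labels = truth.as_labels
        if delta != 0:
            labels = frozenset(labels | {(probeset_id, direction)})
        truth = truth.with_updates(exon_inclusion_log2=excl, as_labels=labels)

    return replace(dataset, intensities=intens, truth=truth)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: ProbeLevelDataset, outdir: str | Path) -> list[Path]:
    """Write the TSV triple (+ background, truth, config sidecar) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _w(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t")
        written.append(p)

    _w(dataset.intensities, "intensities.tsv")
    _w(dataset.annotation, "annotation.tsv")
    _w(dataset.design, "design.tsv")
    _w(dataset.background_intensities, "background.tsv")
    if dataset.truth is not None:
        rows = []
        gt = dataset.truth
        for tid, row in gt.gene_log2_expression.iterrows():
            for grp, val in row.items():
                rows.append(("gene_log2", tid, grp, val))
        for pid, row in gt.exon_inclusion_log2.iterrows():
            for grp, val in row.items():
                rows.append(("exon_inclusion_log2", pid, grp, val))
        for pid, d in sorted(gt.as_labels):
            rows.append(("as_label", pid, d, ""))
        truth_df = pd.DataFrame(rows, columns=["kind", "id", "group", "value"])
        _w(truth_df.set_index("kind"), "truth.tsv")
    if dataset.config is not None:
        p = outdir / "config.json"
        p.write_text(json.dumps(dataset.config.to_dict(), indent=2) + "\n")
        written.append(p)
    log.info("wrote dataset (%d probes x %d samples) to %s",
             *dataset.intensities.shape, outdir)
    return written
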
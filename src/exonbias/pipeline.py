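"""Pipeline orchestration, table validation and study drivers.

Stages run in the order simulate -> summarize (RMA and PLIER tracks) ->
filter -> analyze -> report, all driven by one serializable
:class:`PipelineConfig`.  Every artifact is a TSV/JSON file and the run
manifest records a sha256 checksum per file, so identical config + seed
reproduce identical outputs byte for byte.

The module also hosts the two canned studies used for validation:
:func:`bias_study` (a null-splicing simulation with intensity-coupled effect
sizes, contrasting the SI-dG correlation and skipped-exon enrichment of the
PLIER and RMA tracks) and :func:`null_calibration` (type-I error of the NI
test under a global null).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filtering, splicing, summarize as summarize_mod
from .summarize import SummarizationOptions, summarize
from .synthetic import (
    ConfigError,
    MultiGroup,
    PairedTwoGroup,
    ProbeLevelDataset,
    SimulationConfig,
    simulate_dataset,
    write_dataset,
)

log = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FilterSettings",
    "AnalysisSettings",
    "run_pipeline",
    "read_probe_dataset",
    "validate_tables",
    "bias_study",
    "null_calibration",
]


@dataclass(frozen=True)
class FilterSettings:
    design: str = "paired"  # paired | tissue
    dabg_alpha: float = 0.05
    rule_kind: str = "fraction"  # fraction | count
    rule_value: float = 0.5
    min_gene_signal: float = 70.0
    min_other_tissues: int = 5

    def __post_init__(self):
        if self.design not in ("paired", "tissue"):
            raise ConfigError("field 'filtering.design' must be 'paired' or 'tissue'")
        if self.rule_kind not in ("fraction", "count"):
            raise ConfigError("field 'filtering.rule_kind' must be 'fraction' or 'count'")


@dataclass(frozen=True)
class AnalysisSettings:
    mode: str = "paired"  # paired | unpaired
    alphas: tuple = (0.001, 0.05)
    test_group: str | None = None

    def __post_init__(self):
        if self.mode not in ("paired", "unpaired"):
            raise ConfigError("field 'analysis.mode' must be 'paired' or 'unpaired'")


def _from_section(cls, d: dict, name: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    if cls is AnalysisSettings and isinstance(d.get("alphas"), list):
        d = {**d, "alphas": tuple(d["alphas"])}
    return cls(**d)


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    out_dir: str = "exonbias_out"
    log_level: str = "INFO"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    summarization: dict = field(
        default_factory=lambda: {
            "rma": SummarizationOptions(method="rma"),
            "plier": SummarizationOptions(method="iterplier"),
        }
    )
    filtering: FilterSettings = field(default_factory=FilterSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
            "simulation": self.simulation.to_dict(),
            "summarization": {
                k: dataclasses.asdict(v) for k, v in self.summarization.items()
            },
            "filtering": dataclasses.asdict(self.filtering),
            "analysis": {**dataclasses.asdict(self.analysis), "alphas": list(self.analysis.alphas)},
        }

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        known = {"seed", "out_dir", "log_level", "simulation", "summarization", "filtering", "analysis"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs: dict = {}
        for k in ("seed", "out_dir", "log_level"):
            if k in d:
                kwargs[k] = d[k]
        if "simulation" in d:
            sim = d["simulation"]
            sim = {**sim, "seed": sim.get("seed", d.get("seed", 0))}
            kwargs["simulation"] = SimulationConfig.from_dict(sim)
        if "summarization" in d:
            tracks = {}
            for name, sec in d["summarization"].items():
                tracks[name] = _from_section(SummarizationOptions, sec, f"summarization.{name}")
            kwargs["summarization"] = tracks
        if "filtering" in d:
            kwargs["filtering"] = _from_section(FilterSettings, d["filtering"], "filtering")
        if "analysis" in d:
            kwargs["analysis"] = _from_section(AnalysisSettings, d["analysis"], "analysis")
        return PipelineConfig(**kwargs)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# table validation and loading
# ---------------------------------------------------------------------------

def validate_tables(
    intensities: pd.DataFrame, annotation: pd.DataFrame, design: pd.DataFrame
) -> list[str]:
    """Schema checks; returns a list of human-readable issues (empty = clean)."""
    issues: list[str] = []

    def _rows(mask_index) -> str:
        rows = list(mask_index[:10])
        return ", ".join(str(r) for r in rows)

    dup = intensities.index[intensities.index.duplicated()]
    if len(dup):
        issues.append(f"duplicate probe ids in intensities: {_rows(dup)}")
    nonpos = intensities.index[(intensities <= 0).any(axis=1)]
    if len(nonpos):
        issues.append(f"non-positive intensities for probes: {_rows(nonpos)}")
    orphans = intensities.index.difference(annotation.index)
    if len(orphans):
        issues.append(f"probes missing from annotation: {_rows(orphans)}")
    per_probe = annotation.groupby(level=0)["probeset_id"].nunique()
    multi = per_probe.index[per_probe > 1]
    if len(multi):
        issues.append(f"probes mapped to multiple probesets: {_rows(multi)}")
    per_ps = annotation.groupby("probeset_id")["transcript_id"].nunique()
    multi_tx = per_ps.index[per_ps > 1]
    if len(multi_tx):
        issues.append(f"probesets mapped to multiple transcripts: {_rows(multi_tx)}")
    missing_samples = [c for c in intensities.columns if c not in design.index]
    if missing_samples:
        issues.append(f"samples missing from design: {_rows(pd.Index(missing_samples))}")
    return issues


def read_probe_dataset(indir: str | Path, strict: bool = True) -> ProbeLevelDataset:
    """Load the TSV triple written by :func:`exonbias.synthetic.write_dataset`."""
    indir = Path(indir)
    intensities = pd.read_csv(indir / "intensities.tsv", sep="\t", index_col=0)
    annotation = pd.read_csv(indir / "annotation.tsv", sep="\t", index_col=0)
    design = pd.read_csv(
        indir / "design.tsv", sep="\t", index_col=0, keep_default_na=False
    )
    issues = validate_tables(intensities, annotation, design)
    if issues and strict:
        raise ValueError("invalid probe dataset:\n" + "\n".join(issues))
    for msg in issues:
        log.warning("dataset issue: %s", msg)
    bg_path = indir / "background.tsv"
    background = (
        pd.read_csv(bg_path, sep="\t", index_col=0) if bg_path.exists() else pd.DataFrame()
    )
    cfg_path = indir / "config.json"
    config = (
        SimulationConfig.from_dict(json.loads(cfg_path.read_text()))
        if cfg_path.exists()
        else None
    )
    groups = list(dict.fromkeys(design["group"]))
    test_group = config.design.test_group if config is not None else groups[-1]
    return ProbeLevelDataset(
        intensities=intensities,
        annotation=annotation,
        design=design,
        background_intensities=background,
        truth=None,
        test_group=test_group,
        config=config,
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyze_track(
    dataset: ProbeLevelDataset,
    summ,
    kept_probesets,
    settings: AnalysisSettings,
    test_group: str,
) -> dict:
    parent = dataset.transcript_of_probeset
    exon = summ.exon_signal.loc[summ.exon_signal.index.intersection(kept_probesets)]
    mode = "paired_t" if settings.mode == "paired" else "welch_t"
    results = splicing.splice_test_table(
        exon, summ.gene_signal, parent, dataset.design, mode=mode, test_group=test_group
    )
    ni = splicing.normalized_index(exon, summ.gene_signal, parent)
    if settings.mode == "paired":
        records = splicing.splicing_index_paired(ni, summ.gene_signal, dataset.design, test_group)
    else:
        records = splicing.splicing_index_unpaired(ni, summ.gene_signal, dataset.design, test_group)
    pearson, spearman = splicing.si_dg_correlation(records["si"], records["dg"])
    ps = splicing.ps_statistic(summ.exon_signal, summ.gene_signal, parent)
    pd_stat = splicing.pd_statistic(
        summ.exon_signal, summ.gene_signal, parent, dataset.design, test_group
    )
    enrichment = {
        str(a): splicing.enrichment_table(results, alpha_splice=a).to_dict()
        for a in settings.alphas
    }
    strata = splicing.si_strata_summary(results)
    intensity_r = splicing.intensity_effect_correlation(
        summ.exon_signal, parent, dataset.design, test_group
    )
    return {
        "results": results,
        "si_dg_records": records,
        "diagnostics": {
            "pearson_si_dg": pearson,
            "spearman_si_dg": spearman,
            "ps_mean": float(ps.values.mean()),
            "pd_mean": float(pd_stat.mean()),
            "mean_intensity_effect_r": float(intensity_r.mean()) if len(intensity_r) else float("nan"),
            "enrichment": enrichment,
        },
        "strata": strata,
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Run all stages and return the artifact manifest (path -> sha256)."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    sim = config.simulation
    if sim.seed != config.seed:
        sim = dataclasses.replace(sim, seed=config.seed)
    log.info("stage simulate: %d genes, seed %d", sim.n_genes, sim.seed)
    dataset = simulate_dataset(sim)
    files = list(write_dataset(dataset, out / "dataset"))

    test_group = config.analysis.test_group or dataset.test_group
    tracks = {}
    for name, opts in config.summarization.items():
        log.info("stage summarize: track %s (%s, %s)", name, opts.method, opts.background)
        summ = summarize(dataset, opts)
        tracks[name] = summ
        for which, df in (("exon", summ.exon_signal), ("gene", summ.gene_signal)):
            p = out / f"{name}_{which}_signal.tsv"
            df.to_csv(p, sep="\t")
            files.append(p)
        p = out / f"{name}_options.json"
        p.write_text(json.dumps(dataclasses.asdict(opts), indent=2) + "\n")
        files.append(p)

    log.info("stage filter (%s design)", config.filtering.design)
    dabg = filtering.dabg_pvalues(dataset)
    calls = filtering.presence_by_group(
        dabg,
        dataset.design,
        dataset.transcript_of_probeset,
        alpha=config.filtering.dabg_alpha,
        rule=(config.filtering.rule_kind, config.filtering.rule_value),
    )
    plier_track = next(
        (t for t in tracks.values() if t.options.method in ("plier", "iterplier")), None
    )
    if config.filtering.design == "paired":
        gene_linear = (
            plier_track.gene_signal_linear
            if plier_track is not None
            else 2.0 ** next(iter(tracks.values())).gene_signal
        )
        report = filtering.filter_colon_design(
            calls, dataset, gene_linear, min_gene_signal=config.filtering.min_gene_signal
        )
    else:
        report = filtering.filter_tissue_design(
            calls,
            dataset,
            {name: t.gene_signal for name, t in tracks.items()},
            test_tissue=test_group,
            min_other_tissues=config.filtering.min_other_tissues,
        )
    p = out / "filter_report.json"
    p.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    files.append(p)
    for name, ids in (("kept_probesets", report.kept_probesets), ("kept_transcripts", report.kept_transcripts)):
        p = out / f"{name}.tsv"
        pd.Series(list(ids), name=name).to_csv(p, sep="\t", index=False)
        files.append(p)

    analysis_out = {}
    for name, summ in tracks.items():
        log.info("stage analyze: track %s", name)
        res = _analyze_track(dataset, summ, report.kept_probesets, config.analysis, test_group)
        analysis_out[name] = res["diagnostics"]
        p = out / f"{name}_splice_results.tsv"
        res["results"].to_csv(p, sep="\t")
        files.append(p)
        p = out / f"{name}_si_strata.tsv"
        res["strata"].to_csv(p, sep="\t")
        files.append(p)

    p = out / "report.json"
    p.write_text(json.dumps(analysis_out, indent=2, allow_nan=True) + "\n")
    files.append(p)

    manifest = {str(f.relative_to(out)): _sha256(f) for f in files}
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline complete: %d artifacts in %s", len(manifest), out)
    return manifest


# ---------------------------------------------------------------------------
# canned studies
# ---------------------------------------------------------------------------

def bias_study(
    seed: int = 1,
    n_genes: int = 500,
    exons_per_gene: int = 8,
    n_pairs: int = 10,
    coupling: float = 0.5,
    frac_de_genes: float = 0.3,
    alpha_splice: float = 0.05,
) -> dict:
    """Null-splicing simulation contrasting the PLIER and RMA tracks.

    Simulates a paired two-group dataset with no true splicing, heterogeneous
    exon baselines and a positive coupling between an exon's expression level
    and its fold-change magnitude, then summarizes with both tracks and
    measures the SI-dG correlation, the skipped fraction among significant
    probesets on up-regulated genes, and the PS/PD diagnostics.
    """
    config = SimulationConfig(
        n_genes=n_genes,
        exons_per_gene=exons_per_gene,
        design=PairedTwoGroup(n_pairs=n_pairs),
        frac_de_genes=frac_de_genes,
        frac_as_exons=0.0,
        intensity_effect_coupling=coupling,
        seed=seed,
    )
    dataset = simulate_dataset(config)
    parent = dataset.transcript_of_probeset
    out = {"n_probesets": int(dataset.annotation["probeset_id"].nunique())}
    tracks = {
        "plier": SummarizationOptions(method="iterplier"),
        "rma": SummarizationOptions(method="rma"),
    }
    for name, opts in tracks.items():
        summ = summarize(dataset, opts)
        ni = splicing.normalized_index(summ.exon_signal, summ.gene_signal, parent)
        records = splicing.splicing_index_paired(
            ni, summ.gene_signal, dataset.design, dataset.test_group
        )
        pearson, spearman = splicing.si_dg_correlation(records["si"], records["dg"])
        results = splicing.splice_test_table(
            summ.exon_signal, summ.gene_signal, parent, dataset.design, mode="paired_t"
        )
        table = splicing.enrichment_table(results, alpha_splice=alpha_splice)
        ps = splicing.ps_statistic(summ.exon_signal, summ.gene_signal, parent)
        pd_stat = splicing.pd_statistic(
            summ.exon_signal, summ.gene_signal, parent, dataset.design, dataset.test_group
        )
        out[name] = {
            "pearson_si_dg": pearson,
            "spearman_si_dg": spearman,
            "up_skipped_pct": table.up_skipped_pct,
            "down_included_pct": table.down_included_pct,
            "n_up": table.up_included + table.up_skipped,
            "n_down": table.down_included + table.down_skipped,
            "ps_mean": float(ps.values.mean()),
            "pd_mean": float(pd_stat.mean()),
        }
    return out


def null_calibration(
    seed: int = 1,
    n_genes: int = 400,
    exons_per_gene: int = 6,
    n_pairs: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the NI test under a global null (no DE, no splicing)."""
    config = SimulationConfig(
        n_genes=n_genes,
        exons_per_gene=exons_per_gene,
        design=PairedTwoGroup(n_pairs=n_pairs),
        frac_de_genes=0.0,
        frac_as_exons=0.0,
        intensity_effect_coupling=0.0,
        seed=seed,
    )
    dataset = simulate_dataset(config)
    parent = dataset.transcript_of_probeset
    out = {}
    for name, opts in {
        "plier": SummarizationOptions(method="iterplier"),
        "rma": SummarizationOptions(method="rma"),
    }.items():
        summ = summarize(dataset, opts)
        ni = splicing.normalized_index(summ.exon_signal, summ.gene_signal, parent)
        tests = splicing.test_splicing(ni, dataset.design, mode="paired_t")
        rate = float((tests["p"] < alpha).mean())
        out[name] = {"type_i_rate": rate, "n_tests": int(len(tests))}
    n = next(iter(out.values()))["n_tests"]
    out["binomial_3sigma_band"] = [
        alpha - 3 * np.sqrt(alpha * (1 - alpha) / n),
        alpha + 3 * np.sqrt(alpha * (1 - alpha) / n),
    ]
    return out
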
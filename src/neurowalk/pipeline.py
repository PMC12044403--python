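"""End-to-end orchestration: data in (files or synthetic study) ->
preprocessing -> connectivity -> graph metrics -> factorial statistics ->
CSV artifacts.

Per epoch the pipeline computes:

* Pearson connectivity -> reciprocal distance -> global efficiency and the
  five regional (induced-subgraph) efficiencies;
* wPLI (1-40 Hz) -> proportional 75% threshold + binarize -> Louvain
  modularity Q;
* wPLI -> eigenvector centrality -> five regional centrality means.

Metrics land in one long-format table (subject, condition, task, scope,
metric, value), after which every (scope, metric) series is screened with
the KS normality test and tested with the 2 x 2 repeated-measures ANOVA;
significant interactions get Bonferroni-corrected paired post hocs, and
optional covariates are correlated (Spearman) with each metric's
per-subject mean.

Reproducibility: one global seed deterministically derives a per-epoch
sub-seed from (subject, condition, task) by stable hashing, so results do
not depend on iteration order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .connectivity import (connectivity_to_distance, pearson_connectivity,
                           proportional_threshold_binarize, wpli_connectivity)
from .core import (Epoch, RegionMap, default_region_map, metrics_table,
                   write_metrics)
from .graph import (eigenvector_centrality, louvain_partition,
                    network_efficiency, regional_value)
from .preprocess import (average_reference, bandpass_filter,
                         detect_bad_channels, interpolate_channels,
                         remove_line_noise, segment_epochs)
from .stats import bonferroni_pairwise, ks_normality, rm_anova_2x2, \
    spearman_correlation

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline",
            "compute_epoch_metrics", "analyze_metrics"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    mode: str = "synthetic"               # "synthetic" | "files"
    # synthetic mode
    design: str = "null"                  # null | frontal | cross_region
    n_subjects: int = 10
    epoch_length: float = 10.0
    sfreq: float = 250.0
    effect_delta: float = 0.3
    # files mode
    manifest: str | None = None           # CSV: subject,condition,segment,start_s,file
    # preprocessing
    do_preprocess: bool = False
    band: tuple[float, float] = (0.5, 40.0)
    line_freq: float = 50.0
    line_bandwidth: float = 2.0
    flatline_s: float = 5.0
    corr_threshold: float = 0.8
    # connectivity / graph
    wpli_band: tuple[float, float] = (1.0, 40.0)
    wpli_window_s: float = 2.0
    wpli_overlap: float = 0.5
    keep_fraction: float = 0.75
    # task mapping for the plank segments
    plank_segment: str = "plank_end"      # plank_end | plank_start | mean_of_both
    # statistics
    alpha: float = 0.05
    bonferroni_across_scopes: bool = False
    covariates: str | None = None         # CSV keyed by subject
    # bookkeeping
    seed: int = 0
    out_dir: str = "neurowalk_out"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["wpli_band"] = list(self.wpli_band)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        for key in ("band", "wpli_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    normality: pd.DataFrame
    correlations: pd.DataFrame
    failures: list[dict] = field(default_factory=list)


def epoch_seed(global_seed: int, subject: str, condition: str,
               task: str) -> int:
    """Stable sub-seed derived from the global seed and the epoch identity."""
    key = f"{global_seed}|{subject}|{condition}|{task}".encode()
    return zlib.crc32(key) % (2**31)


def compute_epoch_metrics(epoch: Epoch, region_map: RegionMap,
                          config: PipelineConfig) -> list[tuple]:
    """All per-epoch metrics as (subject, condition, task, scope, metric,
    value) rows."""
    rows = []
    key = (epoch.subject_id, epoch.condition, epoch.task)
    present = {l.lower() for l in epoch.recording.labels}
    regions = [r for r in region_map.regions
               if all(e.lower() in present for e in region_map.electrodes(r))]

    # Pearson -> distance -> efficiency
    pear = pearson_connectivity(epoch)
    dist = connectivity_to_distance(pear)
    rows.append((*key, "global", "efficiency", network_efficiency(dist)))
    for region in regions:
        rows.append((*key, region, "efficiency",
                     regional_value(dist, region, region_map, "efficiency")))

    # wPLI -> threshold/binarize -> Louvain Q; wPLI -> centrality
    wpli = wpli_connectivity(epoch, band=config.wpli_band,
                             window_s=config.wpli_window_s,
                             overlap=config.wpli_overlap)
    binary = proportional_threshold_binarize(wpli, keep=config.keep_fraction)
    part = louvain_partition(binary, seed=epoch_seed(config.seed, *key))
    rows.append((*key, "global", "modularity", part.Q))

    cent = eigenvector_centrality(wpli)
    for region in regions:
        rows.append((*key, region, "centrality",
                     regional_value(cent, region, region_map, "centrality")))
    return rows


def _synthetic_epochs(config: PipelineConfig) -> tuple[list[Epoch], RegionMap]:
    from . import synthetic as syn

    kwargs = dict(n_subjects=config.n_subjects, seed=config.seed,
                  epoch_length=config.epoch_length, sfreq=config.sfreq)
    if config.design == "null":
        design = syn.null_study_design(**kwargs)
    elif config.design == "frontal":
        design = syn.frontal_condition_design(delta=config.effect_delta,
                                              **kwargs)
    elif config.design == "cross_region":
        design = syn.cross_region_design(**kwargs)
    else:
        raise ValueError(f"unknown synthetic design {config.design!r}")
    return syn.generate_study(design), design.region_map


def _file_epochs(config: PipelineConfig) -> tuple[list[Epoch], RegionMap]:
    from .io import attach_standard_positions, read_recording

    manifest = pd.read_csv(config.manifest)
    epochs: list[Epoch] = []
    for (subject, condition, path), group in manifest.groupby(
            ["subject", "condition", "file"]):
        rec = read_recording(Path(config.manifest).parent / path)
        if config.do_preprocess:
            rec = bandpass_filter(rec, *config.band)
            rec = remove_line_noise(rec, config.line_freq,
                                    config.line_bandwidth)
            report = detect_bad_channels(rec, config.flatline_s,
                                         config.corr_threshold)
            if report.all_bad:
                rec = attach_standard_positions(rec)
                rec = interpolate_channels(rec, report.all_bad)
            rec = average_reference(rec)
        boundaries = [(row.start_s, row.segment, condition)
                      for row in group.itertuples()]
        epochs.extend(segment_epochs(rec, boundaries, subject_id=str(subject),
                                     epoch_length=config.epoch_length))
    region_map = default_region_map()
    if epochs:
        region_map = region_map.restrict(epochs[0].recording.labels)
    return epochs, region_map


def _apply_plank_mapping(metrics: pd.DataFrame, epochs: list[Epoch],
                         config: PipelineConfig) -> pd.DataFrame:
    """Collapse the plank segments into the plank task cell.

    When epochs carry distinct plank segments, the configured mapping picks
    plank_end (default), plank_start, or the mean of both as "plank
    walking". The synthetic generator emits one plank epoch per cell, so
    this is a pass-through there.
    """
    seg_by_key = {}
    for e in epochs:
        seg_by_key.setdefault(
            (e.subject_id, e.condition, e.task), set()).add(e.segment)
    multi = any(len(v) > 1 for v in seg_by_key.values())
    if not multi:
        return metrics
    if config.plank_segment in ("plank_end", "plank_start"):
        keep = {"elevator", config.plank_segment}
        mask = metrics["segment"].isin(keep)
        out = metrics[mask].drop(columns="segment")
    else:  # mean_of_both
        out = (metrics.drop(columns="segment")
               .groupby(["subject", "condition", "task", "scope", "metric"],
                        as_index=False)["value"].mean())
    return out


def analyze_metrics(metrics: pd.DataFrame, config: PipelineConfig,
                    seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """KS screening + one 2x2 RM-ANOVA per (scope, metric) + post hocs for
    significant interactions. Returns (normality, anova, posthoc) frames."""
    seed = config.seed if seed is None else seed
    norm_rows, anova_rows, posthoc_frames = [], [], []
    combos = metrics[["scope", "metric"]].drop_duplicates().values
    n_scopes = len(combos)
    for scope, metric in combos:
        sub = metrics[(metrics["scope"] == scope)
                      & (metrics["metric"] == metric)]
        try:
            d, p = ks_normality(sub["value"].to_numpy(),
                                seed=epoch_seed(seed, scope, metric, "ks"))
            norm_rows.append((scope, metric, d, p))
        except ValueError as exc:
            logger.warning("KS screen skipped for %s/%s: %s",
                           scope, metric, exc)
        res = rm_anova_2x2(sub)
        for eff in res.effects.values():
            p_report = eff.p
            if config.bonferroni_across_scopes:
                p_report = min(1.0, eff.p * n_scopes)
            anova_rows.append((scope, metric, eff.name, eff.F, eff.df_num,
                               eff.df_den, p_report, eff.eta_p_sq))
        if res["condition x task"].p < config.alpha:
            comps = [
                (("neutral", "elevator"), ("negative", "elevator")),
                (("neutral", "plank"), ("negative", "plank")),
                (("neutral", "elevator"), ("neutral", "plank")),
                (("negative", "elevator"), ("negative", "plank")),
            ]
            ph = bonferroni_pairwise(sub, comps).comparisons
            ph.insert(0, "metric", metric)
            ph.insert(0, "scope", scope)
            posthoc_frames.append(ph)
    normality = pd.DataFrame(norm_rows,
                             columns=["scope", "metric", "ks_stat", "ks_p"])
    anova = pd.DataFrame(anova_rows,
                         columns=["scope", "metric", "effect", "F", "df_num",
                                  "df_den", "p", "eta_p_sq"])
    posthoc = (pd.concat(posthoc_frames, ignore_index=True)
               if posthoc_frames else
               pd.DataFrame(columns=["scope", "metric", "contrast", "t",
                                     "df", "p_raw", "p_adj"]))
    return normality, anova, posthoc


def _correlate_covariates(metrics: pd.DataFrame,
                          config: PipelineConfig) -> pd.DataFrame:
    cols = ["scope", "metric", "covariate", "rho", "p", "n"]
    if config.covariates is None:
        return pd.DataFrame(columns=cols)
    cov = pd.read_csv(config.covariates)
    cov = cov.set_index(cov.columns[0])
    per_subject = (metrics.groupby(["subject", "scope", "metric"],
                                   as_index=False)["value"].mean())
    rows = []
    for (scope, metric), sub in per_subject.groupby(["scope", "metric"]):
        merged = sub.set_index("subject").join(cov, how="inner")
        for col in cov.columns:
            pair = merged[["value", col]].dropna()
            if len(pair) < 4:
                continue
            try:
                rho, p = spearman_correlation(pair["value"], pair[col])
            except ValueError:
                continue
            rows.append((scope, metric, col, rho, p, len(pair)))
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis described by ``config`` and write all artifacts
    to ``config.out_dir``. Per-epoch failures are recorded in a failure
    manifest and do not abort the batch."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mode == "synthetic":
        epochs, region_map = _synthetic_epochs(config)
    elif config.mode == "files":
        if config.manifest is None:
            raise ValueError("files mode needs a manifest CSV")
        epochs, region_map = _file_epochs(config)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    rows, failures = [], []
    seg_rows = []
    for epoch in epochs:
        try:
            metric_rows = compute_epoch_metrics(epoch, region_map, config)
        except Exception as exc:  # keep the batch going
            failures.append({"subject": epoch.subject_id,
                             "condition": epoch.condition,
                             "task": epoch.task, "stage": "metrics",
                             "error": str(exc)})
            logger.error("epoch failed (%s, %s, %s): %s", epoch.subject_id,
                         epoch.condition, epoch.task, exc)
            continue
        rows.extend(metric_rows)
        seg_rows.extend([epoch.segment] * len(metric_rows))

    if not rows:
        raise RuntimeError("no epoch produced metrics; see failure manifest")
    raw = pd.DataFrame(rows, columns=["subject", "condition", "task",
                                      "scope", "metric", "value"])
    raw["segment"] = seg_rows
    mapped = _apply_plank_mapping(raw, epochs, config)
    if "segment" in mapped.columns:
        mapped = mapped.drop(columns="segment")
    # uniqueness check: one value per (subject, condition, task, scope, metric)
    metrics = metrics_table(mapped.itertuples(index=False, name=None))

    normality, anova, posthoc = analyze_metrics(metrics, config)
    correlations = _correlate_covariates(metrics, config)

    write_metrics(metrics, out_dir / "metrics.csv")
    anova.to_csv(out_dir / "anova.csv", index=False, float_format="%.17g")
    posthoc.to_csv(out_dir / "posthoc.csv", index=False, float_format="%.17g")
    normality.to_csv(out_dir / "normality.csv", index=False,
                     float_format="%.17g")
    correlations.to_csv(out_dir / "correlations.csv", index=False,
                        float_format="%.17g")
    if failures:
        pd.DataFrame(failures).to_csv(out_dir / "failures.csv", index=False)
    manifest = {
        "package": "neurowalk",
        "version": __version__,
        "seed": config.seed,
        "config": {**dataclasses.asdict(config),
                   "band": list(config.band),
                   "wpli_band": list(config.wpli_band)},
        "n_epochs": len(epochs),
        "n_failures": len(failures),
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return PipelineResult(metrics, anova, posthoc, normality, correlations,
                          failures)
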
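"""Configuration-driven orchestration of the full study analysis.

``run_pipeline`` takes a study bundle (generated synthetically or loaded
from disk), runs every analysis stage in dependency order - segment
reflectance images, summarize cluster sizes per group, regress size on
exposure time, convert ICP-AES concentrations to per-cell particle counts,
fit first-order uptake kinetics per group, compare groups per timepoint,
and compute the surface-area-to-volume sonoporation readout - and returns a
:class:`StudyReport` of tables, optionally written to disk as TSV with a
config snapshot for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sgio
from .kinetics import (
    KineticConstants,
    compare_groups,
    concentration_to_particles,
    fit_first_order,
    series_from_table,
)
from .morphometry import av_ratio_study, measure_cell
from .segmentation import (
    exposure_regression,
    extract_clusters,
    normalize_image,
    percent_reduction,
    segment_gnp,
    summarize_group,
)
from .synthetic import StudyBundle, StudyConfig, gen_group_study

__all__ = ["PipelineConfig", "StudyReport", "run_pipeline", "write_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-side parameters layered over the study design."""

    study: StudyConfig = StudyConfig()
    k_clusters: int = 3
    threshold_quantile: float = 0.95
    min_cluster_pixels: int = 4
    histogram_bin_um: float = 0.1
    constants: KineticConstants = KineticConstants()
    control_group: float = 0.0
    seed: int = 0


@dataclass
class StudyReport:
    """All per-module output tables plus run metadata."""

    cluster_tables: pd.DataFrame
    cluster_summaries: pd.DataFrame
    reductions: pd.DataFrame
    regressions: pd.DataFrame
    uptake: pd.DataFrame
    kinetic_fits: pd.DataFrame
    uptake_comparisons: pd.DataFrame
    morphometry: pd.DataFrame
    av_increases: pd.DataFrame
    av_comparisons: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name != "metadata"
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = repr(sgio._to_plain(config)).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    bundle: StudyBundle | None = None,
) -> StudyReport:
    """Execute every analysis stage on a study bundle.

    When ``bundle`` is None a synthetic study is generated from
    ``config.study`` (with ``config.seed`` as the master seed).  All numeric
    outputs are deterministic for a fixed config and seed.
    """
    if bundle is None:
        study = dataclasses.replace(config.study, master_seed=config.seed)
        bundle = gen_group_study(study)

    # --- label-free cluster analysis ---------------------------------------
    all_tables = []
    summaries = []
    per_group_tables: dict[float, list[pd.DataFrame]] = {}
    for g, imgs in bundle.images.items():
        tabs = []
        for img, _truth in imgs:
            seg = segment_gnp(
                normalize_image(img),
                k_clusters=config.k_clusters,
                threshold_quantile=config.threshold_quantile,
                min_cluster_pixels=config.min_cluster_pixels,
                seed=config.seed,
            )
            tab = extract_clusters(seg)
            tab.insert(0, "group_min", g)
            tabs.append(tab)
        per_group_tables[g] = tabs
        all_tables.append(pd.concat(tabs, ignore_index=True))
        s = summarize_group(tabs, g, bin_width_um=config.histogram_bin_um)
        summaries.append({
            "group_min": g, "n_clusters": s.n_clusters, "mean_um": s.mean,
            "sd_um": s.sd, "max_um": s.max,
        })
    cluster_tables = pd.concat(all_tables, ignore_index=True)
    cluster_summaries = pd.DataFrame(summaries).sort_values("group_min", ignore_index=True)

    ctrl_mean = float(cluster_summaries.loc[
        cluster_summaries.group_min == config.control_group, "mean_um"].iloc[0])
    reductions = pd.DataFrame([
        {
            "group_min": r.group_min,
            "mean_um": r.mean_um,
            "percent_reduction": percent_reduction(ctrl_mean, r.mean_um),
        }
        for r in cluster_summaries.itertuples()
        if r.group_min != config.control_group
    ])

    x = cluster_summaries.group_min.to_numpy(dtype=float)
    y = cluster_summaries.mean_um.to_numpy(dtype=float)
    reg_rows = []
    for deg in (1, 2):
        if len(x) < deg + 1:  # saturated/underdetermined on tiny designs
            continue
        rr = exposure_regression(x, y, degree=deg)
        reg_rows.append({
            "level": "group_means", "degree": deg, "r_squared": rr.r_squared,
            "pearson_r": rr.pearson_r, "p_model": rr.p_model, "n_points": rr.n_points,
        })
    xi = cluster_tables.group_min.to_numpy(dtype=float)
    yi = cluster_tables.equivalent_diameter_um.to_numpy(dtype=float)
    ri = exposure_regression(xi, yi, degree=1)
    reg_rows.append({
        "level": "individual", "degree": 1, "r_squared": ri.r_squared,
        "pearson_r": ri.pearson_r, "p_model": ri.p_model, "n_points": ri.n_points,
    })
    regressions = pd.DataFrame(reg_rows)

    # --- uptake kinetics ----------------------------------------------------
    uptake = bundle.uptake_table()
    uptake["c_eq_1e4"] = concentration_to_particles(
        uptake.c_m_mgL.clip(lower=0).to_numpy(dtype=float), config.constants
    )
    fits = []
    for g in sorted(bundle.uptake):
        series = series_from_table(uptake, g)
        fit = fit_first_order(series)
        fits.append({
            "group_min": g, "a_max": fit.a_max, "k_per_h": fit.k,
            "se_k": fit.se_k, "df": fit.df, "r_squared": fit.r_squared,
            "p_model": fit.p_model, "p_k": fit.p_k,
        })
    kinetic_fits = pd.DataFrame(fits)

    cmp_rows = []
    for t in sorted(uptake.time_h.unique()):
        sub = uptake[uptake.time_h == t]
        groups = {g: v.c_m_mgL.to_numpy(dtype=float)
                  for g, v in sub.groupby("group_min")}
        if len(groups) < 2 or min(len(v) for v in groups.values()) < 2:
            continue
        comp = compare_groups(groups)
        pw = comp.pairwise.copy()
        pw.insert(0, "time_h", t)
        pw["f_statistic"] = comp.f_statistic
        pw["p_anova"] = comp.p_anova
        cmp_rows.append(pw)
    uptake_comparisons = (
        pd.concat(cmp_rows, ignore_index=True) if cmp_rows else pd.DataFrame()
    )

    # --- morphometry --------------------------------------------------------
    records_by = {
        key: [measure_cell(v) for v in vols]
        for key, vols in bundle.masks.items()
    }
    morph_rows = [
        {
            "group_min": rec.group_min, "time_h": rec.time_h,
            "cell_id": rec.cell_id, "surface_area_um2": rec.surface_area,
            "volume_um3": rec.volume, "av_ratio_per_um": rec.av_ratio,
        }
        for recs in records_by.values() for rec in recs
    ]
    morphometry = pd.DataFrame(morph_rows)
    av_comps, av_increases = av_ratio_study(records_by, config.control_group)
    av_cmp_rows = []
    for t, comp in av_comps.items():
        pw = comp.pairwise.copy()
        pw.insert(0, "time_h", t)
        pw["f_statistic"] = comp.f_statistic
        pw["p_anova"] = comp.p_anova
        av_cmp_rows.append(pw)
    av_comparisons = pd.concat(av_cmp_rows, ignore_index=True)

    metadata = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_images": int(sum(len(v) for v in bundle.images.values())),
        "n_cells": int(sum(len(v) for v in bundle.masks.values())),
    }
    return StudyReport(
        cluster_tables=cluster_tables,
        cluster_summaries=cluster_summaries,
        reductions=reductions,
        regressions=regressions,
        uptake=uptake,
        kinetic_fits=kinetic_fits,
        uptake_comparisons=uptake_comparisons,
        morphometry=morphometry,
        av_increases=av_increases,
        av_comparisons=av_comparisons,
        metadata=metadata,
    )


def write_report(report: StudyReport, outdir: str | Path,
                 config: PipelineConfig | None = None) -> Path:
    """Write every report table as TSV (plus config snapshot) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, tab in report.tables().items():
        sgio.write_table(tab, outdir / f"{name}.tsv")
    if config is not None:
        sgio.write_config_snapshot(config, outdir / "config_snapshot.yaml")
    sgio.write_config_snapshot(report.metadata, outdir / "run_metadata.yaml")
    return outdir
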
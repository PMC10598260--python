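"""End-to-end orchestration: load -> filter -> PCA -> Haar -> scaling ->
biome axes -> quantile aggregation -> spatial statistics.

A single :class:`PipelineConfig` drives every stage; each parameter of the
analysis (windows, bands, n_max, quantile count, detrend period,
thresholds) is a config key with the study default.  Outputs are plain CSV
tables plus a JSON manifest recording the config hash, seed and library
versions, so a rerun with the same config and seed is byte-identical.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomes import (
    RECENT_WINDOW,
    binary_filter,
    difference_axis,
    mean_score,
    project_scores,
    quantile_groups,
    recent_assemblages,
    typical_assemblage,
)
from .errors import PollenScaleError
from .haar import HaarSF, aggregate_hsf, haar_sf
from .ordination import best_correlated_taxon, pc1_series, pca_pc1
from .records import ANALYSIS_WINDOW, PollenRecord, filter_records, load_records, \
    sqrt_transform, to_proportions
from .scaling import CENTENNIAL_BAND, FIT_BAND, MILLENNIAL_BAND, detrend_sinusoid, \
    fit_H, summarize_scaling
from .spatial import grid_metric, morans_i, weighted_correlation

logger = logging.getLogger(__name__)


class PipelineStageError(PollenScaleError):
    def __init__(self, stage: str, site_id: str, original: Exception):
        super().__init__(f"stage {stage!r} failed for site {site_id!r}: {original}")
        self.stage = stage
        self.site_id = site_id
        self.original = original


@dataclass
class AxisStep:
    """One binary comparison in the iterative classification chain."""

    biome_i: str
    biome_j: str
    classes_i: list[str]
    classes_j: list[str]
    group_weights_i: dict[str, float] | None = None
    group_weights_j: dict[str, float] | None = None
    filter_rule: object = "positive"  # rule applied to select sites for the next step

    @property
    def axis_id(self) -> str:
        return f"{self.biome_i},{self.biome_j}"


@dataclass
class PipelineConfig:
    counts_path: str | None = None
    meta_path: str | None = None
    surface_counts_path: str | None = None
    surface_meta_path: str | None = None
    output_dir: str | None = None

    window: tuple[float, float] = ANALYSIS_WINDOW
    min_samples: int = 6
    min_lat: float = 25.0

    n_max: int = 100
    min_samples_per_half: int = 1

    centennial_band: tuple[float, float] = CENTENNIAL_BAND
    millennial_band: tuple[float, float] = MILLENNIAL_BAND
    fit_band: tuple[float, float] = FIT_BAND
    detrend_period: float | None = None  # e.g. 23000.0

    recent_window: tuple[float, float] = RECENT_WINDOW
    transform_order: str = "mean_then_sqrt"
    class_column: str = "intersection_class"
    axis_chain: list[AxisStep] = field(default_factory=list)

    quantile_k: int = 5
    cell_deg: float = 4.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        chain = [AxisStep(**step) for step in raw.pop("axis_chain", [])]
        cfg = cls(**raw)
        cfg.axis_chain = chain
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_two_biome_chain(
    class_i: str = "forest", class_j: str = "open_land"
) -> list[AxisStep]:
    """Minimal chain for the bundled two-biome synthetic world."""
    return [AxisStep(biome_i="Fo", biome_j="Op", classes_i=[class_i],
                     classes_j=[class_j], filter_rule="positive")]


def analyze_record(
    record: PollenRecord,
    config: PipelineConfig,
) -> dict:
    """PC1 -> (optional detrend) -> Haar -> scaling summary for one record."""
    sqrt_asm = sqrt_transform(to_proportions(record))
    pca = pca_pc1(sqrt_asm)
    series = pc1_series(pca)
    if config.detrend_period:
        series, _ = detrend_sinusoid(series.times, series.values,
                                     period=config.detrend_period)
    hsf = haar_sf(series.times, series.values,
                  min_samples_per_half=config.min_samples_per_half)
    summary = summarize_scaling(
        hsf,
        fit_band=config.fit_band,
        centennial_band=config.centennial_band,
        millennial_band=config.millennial_band,
    )
    taxon, r2 = best_correlated_taxon(pca, sqrt_asm)
    return {
        "record": record,
        "pca": pca,
        "series": series,
        "hsf": hsf,
        "summary": summary,
        "best_taxon": taxon,
        "best_taxon_r2": r2,
    }


def aggregate_by_quantile(
    hsf_per_site: dict[str, HaarSF],
    biome_scores: pd.Series,
    k: int = 5,
    n_max: int = 100,
    fit_band: tuple[float, float] = FIT_BAND,
    min_estimates: int = 10,
) -> list[dict]:
    """Average HSFs within equal-count quantile groups of the biome score.

    Returns one dict per group (1 = lowest scores) with the aggregated HSF,
    the fitted exponent over ``fit_band`` (NaN if too few scales), a
    low-confidence flag per scale (fewer than ``min_estimates`` records),
    and the member site ids.  Groups without any HSF are flagged empty.
    """
    shared = biome_scores.index.intersection(list(hsf_per_site))
    groups = quantile_groups(biome_scores.loc[shared], k=k)
    out = []
    for g in range(1, k + 1):
        sites = list(groups.index[groups == g])
        hsfs = [hsf_per_site[s] for s in sites if s in hsf_per_site]
        if not hsfs:
            out.append({"group": g, "sites": sites, "hsf": None, "H": float("nan"),
                        "se_H": float("nan"), "empty": True})
            continue
        agg = aggregate_hsf(hsfs, n_max=n_max)
        try:
            H, se = fit_H(agg, band=fit_band)
        except PollenScaleError:
            H, se = float("nan"), float("nan")
        out.append({
            "group": g,
            "sites": sites,
            "hsf": agg,
            "H": H,
            "se_H": se,
            "low_confidence": agg.n_records < min_estimates,
            "empty": False,
        })
    return out


def run_pipeline(
    config: PipelineConfig,
    records: list[PollenRecord] | None = None,
    surface_records: list[PollenRecord] | None = None,
) -> dict:
    """Run the full analysis and return (and optionally write) all tables."""
    if records is None:
        if not (config.counts_path and config.meta_path):
            raise ValueError("provide records or counts/meta paths in the config")
        records = load_records(config.counts_path, config.meta_path)
    if surface_records is None and config.surface_counts_path:
        surface_records = load_records(
            config.surface_counts_path, config.surface_meta_path
        )

    filtered, report = filter_records(
        records, min_samples=config.min_samples,
        min_lat=config.min_lat, window=config.window,
    )
    logger.info("pipeline: %d/%d records retained", report.n_kept, report.n_input)

    per_site, hsf_per_site, score_rows, hsf_rows = {}, {}, [], []
    for rec in filtered:
        try:
            res = analyze_record(rec, config)
        except PollenScaleError as exc:
            raise PipelineStageError("per_record_analysis", rec.site_id, exc) from exc
        per_site[rec.site_id] = res
        hsf_per_site[rec.site_id] = res["hsf"]
        for t, v in zip(res["series"].times, res["series"].values):
            score_rows.append((rec.site_id, t, v))
        h = res["hsf"]
        for tau, s, nw in zip(h.scales, h.fluctuations, h.n_windows):
            hsf_rows.append((rec.site_id, tau, s, nw))

    site_table = pd.DataFrame([
        {
            "site_id": sid,
            "lat": r["record"].lat,
            "lon": r["record"].lon,
            "region": r["record"].region,
            "n_samples": r["record"].n_samples,
            "explained_fraction_pc1": r["pca"].explained_fraction[0],
            "best_taxon": r["best_taxon"],
            "best_taxon_r2": r["best_taxon_r2"],
            "S_C": r["summary"].S_C,
            "S_M": r["summary"].S_M,
            "H_CM": r["summary"].H_CM,
            "se_H": r["summary"].se_H,
            "beta": r["summary"].beta,
            "coverage_logfrac": r["summary"].coverage_logfrac,
        }
        for sid, r in per_site.items()
    ]).set_index("site_id")

    overall_hsf = aggregate_hsf(list(hsf_per_site.values()), n_max=config.n_max) \
        if hsf_per_site else None

    # --- biome axes -------------------------------------------------------
    axis_tables, score_tables, corr_rows, quantile_bundles = {}, {}, [], {}
    if surface_records and config.axis_chain:
        assemblages, surf_meta = recent_assemblages(
            surface_records, window=config.recent_window,
            transform_order=config.transform_order,
        )
        labels = surf_meta[config.class_column]
        regions = site_table["region"]
        selected = list(per_site)
        for step in config.axis_chain:
            a_i = typical_assemblage(assemblages, labels, step.biome_i,
                                     step.classes_i, step.group_weights_i)
            a_j = typical_assemblage(assemblages, labels, step.biome_j,
                                     step.classes_j, step.group_weights_j)
            axis = difference_axis(a_i, a_j)
            axis_tables[axis.axis_id] = axis

            u_bars = {}
            for sid in selected:
                series = project_scores(per_site[sid]["record"], axis)
                u_bars[sid] = mean_score(series, window=config.window,
                                         site_id=sid).u_bar
            u_series = pd.Series(u_bars, name=axis.axis_id).dropna()
            table = u_series.to_frame("u_bar")
            if u_series.size >= config.quantile_k:
                table["quantile_group"] = quantile_groups(u_series, k=config.quantile_k)
                quantile_bundles[axis.axis_id] = aggregate_by_quantile(
                    hsf_per_site, u_series, k=config.quantile_k,
                    n_max=config.n_max, fit_band=config.fit_band,
                )
            score_tables[axis.axis_id] = table

            for metric in ("S_M", "S_C", "H_CM"):
                sub = site_table.loc[u_series.index, [metric, "coverage_logfrac"]].dropna()
                if len(sub) >= 3 and sub[metric].nunique() > 1:
                    wc = weighted_correlation(
                        u_series.loc[sub.index].to_numpy(),
                        sub[metric].to_numpy(),
                        sub["coverage_logfrac"].to_numpy(),
                        seed=config.seed,
                    )
                    corr_rows.append({"axis_id": axis.axis_id, "metric": metric,
                                      "r": wc.r, "p_perm": wc.p_value, "n": wc.n})

            selected = binary_filter(u_series, step.filter_rule, regions=regions)
            logger.info("axis %s: %d sites selected for next step",
                        axis.axis_id, len(selected))

    # --- spatial stats ----------------------------------------------------
    moran_rows, grids = [], {}
    for metric in ("S_C", "S_M", "H_CM"):
        sub = site_table.dropna(subset=[metric])
        grids[metric] = grid_metric(sub.reset_index(), metric, cell_deg=config.cell_deg)
        if len(sub) >= 3 and sub[metric].nunique() > 1:
            mr = morans_i(sub[metric].to_numpy(), sub["lat"].to_numpy(),
                          sub["lon"].to_numpy(), seed=config.seed)
            moran_rows.append({"metric": metric, "morans_I": mr.I,
                               "expected_I": mr.expected_I, "p_norm": mr.p_norm,
                               "p_perm": mr.p_perm, "n": mr.n})

    result = {
        "filter_report": report,
        "per_site": per_site,
        "site_table": site_table,
        "scores": pd.DataFrame(score_rows, columns=["site_id", "age_bp", "score"]),
        "hsf_table": pd.DataFrame(
            hsf_rows, columns=["site_id", "scale_yr", "S", "n_windows"]),
        "overall_hsf": overall_hsf,
        "axes": axis_tables,
        "biome_scores": score_tables,
        "correlations": pd.DataFrame(corr_rows),
        "quantile_bundles": quantile_bundles,
        "moran": pd.DataFrame(moran_rows),
        "grids": grids,
        "manifest": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_records_in": report.n_input,
            "n_records_kept": report.n_kept,
            "versions": {
                "pollenscale": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
    }
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _hsf_frame(hsf: HaarSF) -> pd.DataFrame:
    df = pd.DataFrame({"scale_yr": hsf.scales, "S": hsf.fluctuations,
                       "n_windows": hsf.n_windows})
    if hsf.n_records is not None:
        df["n_records"] = hsf.n_records
    if hsf.ci_low is not None:
        df["ci_low"] = hsf.ci_low
        df["ci_high"] = hsf.ci_high
    return df


def _write_outputs(result: dict, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result["site_table"].to_csv(out / "site_summary.csv")
    result["scores"].to_csv(out / "scores.csv", index=False)
    result["hsf_table"].to_csv(out / "hsf_records.csv", index=False)
    if result["overall_hsf"] is not None:
        _hsf_frame(result["overall_hsf"]).to_csv(out / "hsf_overall.csv", index=False)
    if result["axes"]:
        pd.concat(
            {aid: ax.values for aid, ax in result["axes"].items()}, names=["axis_id", "taxon"]
        ).rename("value").reset_index().to_csv(out / "axes.csv", index=False)
        pd.concat(result["biome_scores"], names=["axis_id", "site_id"]).reset_index() \
            .to_csv(out / "biome_scores.csv", index=False)
    if len(result["correlations"]):
        result["correlations"].to_csv(out / "correlations.csv", index=False)
    if len(result["moran"]):
        result["moran"].to_csv(out / "moran.csv", index=False)
    for metric, grid in result["grids"].items():
        grid.to_csv(out / f"grid_{metric}.csv", index=False)
    qrows = []
    for axis_id, bundle in result["quantile_bundles"].items():
        for g in bundle:
            if g.get("empty"):
                continue
            frame = _hsf_frame(g["hsf"])
            frame.insert(0, "axis_id", axis_id)
            frame.insert(1, "group", g["group"])
            frame["H_group"] = g["H"]
            qrows.append(frame)
    if qrows:
        pd.concat(qrows).to_csv(out / "hsf_quantiles.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=2, sort_keys=True)
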
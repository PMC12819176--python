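"""End-to-end orchestration: simulate/read -> clean -> segment ->
interpolate -> classify -> metrics -> mixed models -> report.

Every stage writes its table under the output directory, and the report
only copies numbers from those tables (single source of truth). The full
configuration, seed and package version are echoed into the report for
provenance. With a fixed seed a simulator-driven run is deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .glmm import (
    GlmmSpec, compress_proportions, estimated_marginal_means, fit_glmm,
    lrt_vs_null, tukey_contrasts, type3_anova,
)
from .habitats import assign_habitat, bird_season_use, habitat_proportions, read_habitat_polygons, write_habitat_polygons
from .interpolation import default_rules, interpolate_dataset
from .io import DEFAULT_TZ_OFFSET_H, read_fixes, restrict_period, write_fixes
from .metrics import summarize_metrics, trip_metrics
from .segmentation import (
    build_central_timeline, detect_resting_sites, filter_speed_outliers,
    segment_trips, trips_table,
)
from .simulate import SimConfig, default_habitat_map, simulate_population

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config drives the whole run.

    Exactly one of ``fixes_path`` (with ``statuses``) or ``sim`` must be
    set. Thresholds default to the study values: 300 m / 30 min trip
    rule, 70 km/h speed filter, 15-min interpolation grid with the
    60/90-min gap rules.
    """

    out_dir: str = "pipeline_out"
    sim: SimConfig | None = None
    fixes_path: str | None = None
    habitat_path: str | None = None
    statuses: dict = field(default_factory=dict)
    colony_urban: tuple[float, float] | None = None
    colony_wild: tuple[float, float] | None = None
    period: tuple[str, str] | None = None
    dist_m: float = 300.0
    min_away_min: float = 30.0
    max_speed_kmh: float = 70.0
    tz_offset_h: float = DEFAULT_TZ_OFFSET_H
    alpha: float = 0.05
    seed: int = 0
    fit_models: bool = True

    def validate(self) -> "PipelineConfig":
        if (self.sim is None) == (self.fixes_path is None):
            raise ValueError("exactly one of sim config or fixes_path must be given")
        for thr in (self.dist_m, self.min_away_min, self.max_speed_kmh):
            if thr <= 0:
                raise ValueError("all thresholds must be positive")
        if self.sim is None:
            if self.colony_urban is None and self.colony_wild is None:
                raise ValueError("colony coordinates are required")
            if self.habitat_path is None:
                raise ValueError("habitat polygon file is required")
        return self

    def colony_for(self, status: str) -> tuple[float, float]:
        if status == "urban" and self.colony_urban:
            return self.colony_urban
        if status == "wild" and self.colony_wild:
            return self.colony_wild
        if self.sim is not None:
            return self.sim.colony_urban if status == "urban" else self.sim.colony_wild
        raise ValueError(f"no colony configured for status {status!r}")


def _config_echo(cfg: PipelineConfig) -> dict:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        return o
    return enc(cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, persist outputs under ``config.out_dir`` and
    return the machine-readable report."""
    cfg = config.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        habitat_map = default_habitat_map()
        tracks, truth, truth_table = simulate_population(sim_cfg, habitat_map)
        write_fixes(tracks, out / "fixes.csv")
        write_habitat_polygons(habitat_map, out / "habitats.geojson")
        if len(truth.trips):
            truth.trips.to_csv(out / "truth_trips.csv", index=False)
        truth_table.to_csv(out / "truth_table.csv", index=False)
    else:
        tracks = read_fixes(cfg.fixes_path, statuses=cfg.statuses)
        habitat_map = read_habitat_polygons(cfg.habitat_path)
    counts["n_birds"] = len(tracks)
    counts["n_fixes_read"] = int(sum(len(t) for t in tracks))

    if cfg.period is not None:
        tracks = [restrict_period(t, *cfg.period) for t in tracks]
        tracks = [t for t in tracks if len(t)]
        counts["n_fixes_in_period"] = int(sum(len(t) for t in tracks))

    all_trips, central_rows = [], []
    n_outliers = 0
    for tr in tracks:
        clean, removed = filter_speed_outliers(tr, cfg.max_speed_kmh)
        n_outliers += len(removed)
        colony = cfg.colony_for(clean.status)
        sites = detect_resting_sites(clean, colony, tz_offset_h=cfg.tz_offset_h)
        timeline = build_central_timeline(clean, colony, sites)
        central_rows += [
            {
                "bird_id": c.bird_id, "kind": c.kind, "lat": c.lat, "lon": c.lon,
                "active_start": c.start, "active_end": c.end,
            }
            for c in timeline
        ]
        all_trips += segment_trips(
            clean, timeline, cfg.dist_m, cfg.min_away_min, cfg.tz_offset_h
        )
    counts["n_speed_outliers_removed"] = int(n_outliers)
    counts["n_trips"] = len(all_trips)
    counts["n_trips_complete"] = int(sum(t.complete for t in all_trips))
    tt = trips_table(all_trips)
    tt.to_csv(out / "trips.csv", index=False)
    pd.DataFrame(central_rows).to_csv(out / "centrals.csv", index=False)
    if len(tt):
        counts["trips_per_season"] = {
            s: int(n) for s, n in tt[tt.complete]["season"].value_counts().items()
        }

    interp, interp_log = interpolate_dataset(all_trips, default_rules())
    interp.to_csv(out / "interpolated.csv", index=False)
    interp_log.to_csv(out / "interpolation_log.csv", index=False)
    counts["n_locations_original"] = int(interp_log["n_original"].sum()) if len(interp_log) else 0
    counts["n_locations_interpolated"] = int(len(interp))
    counts["n_trips_interpolated"] = int(interp_log["eligible"].sum()) if len(interp_log) else 0

    labelled = assign_habitat(interp, habitat_map)
    use_long = habitat_proportions(labelled)
    use_long.to_csv(out / "habitat_use.csv", index=False)
    use = bird_season_use(labelled)

    colonies = {s: cfg.colony_for(s) for s in {t.status for t in all_trips if t.status}}
    tm = trip_metrics(all_trips, colonies)
    tm.to_csv(out / "trip_metrics.csv", index=False)

    models: dict = {}
    emm_frames = []
    all_cells = {(st, se) for st in ("urban", "wild")
                 for se in ("summer", "autumn", "winter", "spring")}
    cells_ok = (
        len(use) >= 8 and len(tm) >= 8
        and set(map(tuple, use[["status", "season"]].to_numpy())) >= all_cells
        and set(map(tuple, tm[["status", "season"]].drop_duplicates().to_numpy())) >= all_cells
    )
    if cfg.fit_models and not cells_ok:
        logger.warning(
            "run_pipeline: not every status x season cell is observed; "
            "skipping the mixed models"
        )
    if cfg.fit_models and cells_ok:
        use_fit = use.copy()
        use_fit["prop_anthropogenic"] = compress_proportions(
            use_fit["prop_anthropogenic"].to_numpy()
        )
        specs = [("prop_anthropogenic", "beta_logit", use_fit)] + [
            (resp, "gamma_log", tm) for resp in ("duration_h", "max_dist_km", "path_km")
        ]
        for resp, fam, data in specs:
            try:
                res = fit_glmm(data, GlmmSpec(resp, fam, cfg.alpha))
            except Exception as exc:  # pragma: no cover - surfaced in report
                logger.error("model for %s failed: %s", resp, exc)
                models[resp] = {"error": str(exc)}
                continue
            emm = estimated_marginal_means(res)
            emm_frames.append(emm)
            models[resp] = {
                "family": fam,
                "coefficients": res.coefficients().to_dict(orient="records"),
                "sigma_b": res.sigma_b,
                "dispersion": res.dispersion,
                "loglik": res.loglik,
                "type3": type3_anova(res).to_dict(orient="records"),
                "emmeans": emm.to_dict(orient="records"),
                "tukey_season": tukey_contrasts(res, "season").to_dict(orient="records"),
                "null_comparison": lrt_vs_null(res),
            }
        with open(out / "models.json", "w") as fh:
            json.dump(models, fh, indent=1, sort_keys=True, default=float)

    emm_all = pd.concat(emm_frames, ignore_index=True) if emm_frames else None
    summary = summarize_metrics(tm, emm_all) if len(tm) else pd.DataFrame()
    summary.to_csv(out / "metric_summary.csv", index=False)

    report = make_report(counts, use, summary, models, _config_echo(cfg))
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    with open(out / "report.md", "w") as fh:
        fh.write(_render_report_md(report))
    return report


def make_report(counts, use, metric_summary, models, config_echo) -> dict:
    """Collate stage outputs into the run report (numbers copied, never
    recomputed)."""
    by_cell = {}
    if len(use):
        for (status, season), grp in use.groupby(["status", "season"]):
            by_cell[f"{status}:{season}"] = {
                "n_birds": int(len(grp)),
                "mean_prop_anthropogenic": float(grp["prop_anthropogenic"].mean()),
            }
    return {
        "version": __version__,
        "config": config_echo,
        "counts": counts,
        "habitat_use_by_cell": by_cell,
        "metric_summary": metric_summary.to_dict(orient="records") if len(metric_summary) else [],
        "models": models,
    }


def _render_report_md(report: dict) -> str:
    lines = [
        "# Central-place foraging pipeline report",
        "",
        f"package version {report['version']}, seed "
        f"{report['config'].get('seed')}",
        "",
        "## Counts",
    ]
    for k, v in sorted(report["counts"].items()):
        lines.append(f"- {k}: {v}")
    lines += ["", "## Habitat use (mean proportion anthropogenic per cell)"]
    if report["habitat_use_by_cell"]:
        for cell, d in sorted(report["habitat_use_by_cell"].items()):
            lines.append(
                f"- {cell}: {d['mean_prop_anthropogenic']:.3f} (n={d['n_birds']})"
            )
    else:
        lines.append("- no trips: no habitat-use table")
    lines += ["", "## Movement metrics (per status x season)"]
    if report["metric_summary"]:
        for row in report["metric_summary"]:
            lines.append(
                f"- {row['status']}:{row['season']}: n={row['n']}, "
                f"duration {row.get('duration_h_mean', float('nan')):.2f} h, "
                f"max dist {row.get('max_dist_km_mean', float('nan')):.1f} km, "
                f"path {row.get('path_km_mean', float('nan')):.1f} km"
            )
    else:
        lines.append("- no trips: no metrics")
    lines += ["", "## Models"]
    for resp, m in sorted(report.get("models", {}).items()):
        if "error" in m:
            lines.append(f"- {resp}: FAILED ({m['error']})")
            continue
        inter = next(t for t in m["type3"] if t["term"] == "status:season")
        lines.append(
            f"- {resp} ({m['family']}): interaction chi2={inter['chisq']:.2f} "
            f"(df {inter['df']}), p={inter['p']:.3g}"
        )
    lines.append("")
    return "\n".join(lines)


def plot_report(out_dir: str) -> list[str]:
    """Diagnostic box plots per status x season from persisted stage
    outputs; returns the written file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    written = []
    tm = pd.read_csv(out / "trip_metrics.csv")
    use = pd.read_csv(out / "habitat_use.csv")
    season_order = ["summer", "autumn", "winter", "spring"]
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, col, label in zip(
        axes, ["duration_h", "max_dist_km", "path_km"],
        ["Trip duration (h)", "Max distance from colony (km)", "Path length (km)"],
    ):
        data, labels = [], []
        for status in ("urban", "wild"):
            for s in season_order:
                vals = tm[(tm.status == status) & (tm.season == s)][col]
                data.append(vals)
                labels.append(f"{status[0].upper()}-{s[:2]}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel(label)
        ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    p = out / "metrics_boxplots.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(str(p))

    bs = use.drop_duplicates(["bird_id", "status", "season"])
    fig, ax = plt.subplots(figsize=(6, 4))
    data, labels = [], []
    for status in ("urban", "wild"):
        for s in season_order:
            vals = bs[(bs.status == status) & (bs.season == s)]["prop_anthropogenic"]
            data.append(vals)
            labels.append(f"{status[0].upper()}-{s[:2]}")
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("Proportion anthropogenic habitat use")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    p = out / "habitat_boxplots.png"
    fig.savefig(p, dpi=110)
    plt.close(fig)
    written.append(str(p))
    return written
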
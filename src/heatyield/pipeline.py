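"""End-to-end pipeline driver: simulate -> classify -> regress -> report.

Stages (in order): simulate, wetbulb (only when an hourly input is
configured), qc, thresholds, classify, exposure, regress, panel,
composites, report. Each stage reads its inputs from and writes its CSV
outputs to the artifact directory, so any stage can be re-run alone once
its predecessors have produced their files. A run log records the seed,
a config hash, and package versions; the whole pipeline is deterministic
given (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, composites, heat_events, io, synthetic, wetbulb, yield_stats
from .config import PipelineConfig
from .heat_events import SEASONS

logger = logging.getLogger(__name__)

STAGES = [
    "simulate",
    "wetbulb",
    "qc",
    "thresholds",
    "classify",
    "exposure",
    "regress",
    "panel",
    "composites",
    "report",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _config_hash(cfg: PipelineConfig) -> str:
    blob = yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


class Pipeline:
    def __init__(self, cfg: PipelineConfig, outdir: str | Path):
        self.cfg = cfg
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.season = SEASONS[cfg.season_name]

    # -- helpers -----------------------------------------------------------
    def _path(self, name: str) -> Path:
        return self.outdir / name

    def _load_stations(self):
        daily = io.read_daily_csv(self._path("station_daily.csv"))
        meta = io.read_metadata_csv(self._path("station_metadata.csv"))
        return io.station_series_from_frames(daily, meta), meta

    # -- stages ------------------------------------------------------------
    def simulate(self) -> None:
        syn = self.cfg.synthetic
        stations = synthetic.generate_weather_set(syn)
        io.write_daily_csv(stations, self._path("station_daily.csv"))
        io.write_metadata_csv(synthetic.station_county_map(syn), self._path("station_metadata.csv"))

    def wetbulb(self) -> None:
        if not self.cfg.hourly_csv:
            return
        hourly = io.read_hourly_csv(self.cfg.hourly_csv)
        meta = io.read_metadata_csv(self._path("station_metadata.csv"))
        elev = meta.set_index("station_id")["elevation_m"]
        parts = []
        for sid, grp in hourly.groupby("station_id"):
            daily = wetbulb.daily_maxima(grp, float(elev.get(sid, 0.0)))
            daily["station_id"] = sid
            daily["precip_mm"] = np.nan
            parts.append(daily)
        io.write_daily_csv(pd.concat(parts, ignore_index=True), self._path("station_daily.csv"))

    def qc(self) -> None:
        stations, _ = self._load_stations()
        rows = []
        for s in stations:
            rep = heat_events.station_quality_control(s, self.cfg.synthetic.years)
            rows.append(
                {
                    "station_id": s.station_id,
                    "passed": rep.passed,
                    "good_month_fraction": rep.good_month_fraction,
                }
            )
        pd.DataFrame(rows).to_csv(self._path("qc.csv"), index=False)

    def thresholds(self) -> None:
        stations, _ = self._load_stations()
        qc = pd.read_csv(self._path("qc.csv"), dtype={"station_id": str})
        passed = set(qc.loc[qc["passed"], "station_id"])
        thr = [
            heat_events.compute_thresholds(
                s, self.cfg.level, self.cfg.synthetic.base_period, self.season
            )
            for s in stations
            if s.station_id in passed
        ]
        io.thresholds_to_frame(thr).to_csv(self._path("thresholds.csv"), index=False)

    def classify(self) -> None:
        stations, _ = self._load_stations()
        thr = {
            t.station_id: t
            for t in io.frame_to_thresholds(pd.read_csv(self._path("thresholds.csv"), dtype={"station_id": str}))
        }
        parts = []
        for s in stations:
            if s.station_id not in thr:
                continue
            lab = heat_events.classify_days(s, thr[s.station_id])
            lab["station_id"] = s.station_id
            parts.append(lab)
        out = pd.concat(parts, ignore_index=True)
        out.assign(date=out["date"].astype("datetime64[ns]").astype(str)).to_csv(
            self._path("labels.csv"), index=False
        )

    def exposure(self) -> None:
        stations, _ = self._load_stations()
        thr = {
            t.station_id: t
            for t in io.frame_to_thresholds(pd.read_csv(self._path("thresholds.csv"), dtype={"station_id": str}))
        }
        exposures = []
        for s in stations:
            if s.station_id not in thr:
                continue
            exposures.extend(heat_events.season_exposures(s, thr[s.station_id], self.season))
        heat_events.exposures_to_frame(exposures).to_csv(self._path("exposures.csv"), index=False)
        # overlap fraction per station
        df = heat_events.exposures_to_frame(exposures)
        of = (
            df.groupby("station_id")
            .apply(lambda g: g["overlap"].sum() / g["xtmax"].sum() if g["xtmax"].sum() else np.nan,
                   include_groups=False)
            .rename("overlap_fraction")
            .reset_index()
        )
        of.to_csv(self._path("overlap_fraction.csv"), index=False)

    def _yield_panel(self) -> pd.DataFrame:
        path = self._path("yields.csv")
        if not path.exists():
            exp = pd.read_csv(self._path("exposures.csv"), dtype={"station_id": str})
            panel = synthetic.generate_yield_panel(self.cfg.synthetic, exp, crop=self.cfg.crop)
            io.write_yield_csv(panel, path)
        return io.read_yield_csv(path)

    def regress(self) -> None:
        exp = pd.read_csv(self._path("exposures.csv"), dtype={"station_id": str})
        meta = io.read_metadata_csv(self._path("station_metadata.csv"))
        panel = self._yield_panel()
        panel = panel[panel["crop"] == self.cfg.crop]
        results = []
        lat_map = meta.set_index("station_id")["lat"]
        irr_rows = []
        for (sid, county), _ in meta.groupby(["station_id", "county_id"]):
            e = exp[exp["station_id"] == sid].sort_values("year")
            for irr_flag, ysub in panel[panel["county_id"] == county].groupby("irrigated"):
                merged = e.merge(ysub[["year", "yield_bu_acre"]], on="year")
                if len(merged) < 4:
                    continue
                yr = merged["year"].to_numpy()
                res = yield_stats.fit_yield_regression(
                    yield_stats.detrend(yr, merged["yield_bu_acre"]),
                    yield_stats.detrend(yr, merged["dhd"]),
                    yield_stats.detrend(yr, merged["hhd"]),
                    station_id=sid,
                    county_id=county,
                )
                results.append(res)
                irr_rows.append(int(irr_flag))
        df = yield_stats.results_to_frame(results)
        df["irrigated"] = irr_rows
        df["lat"] = df["station_id"].map(lat_map)
        df.to_csv(self._path("regression_coefficients.csv"), index=False)
        yield_stats.summarize_by_latitude(df).to_csv(self._path("latitude_summary.csv"), index=False)
        yield_stats.summarize_by_group(df).to_csv(self._path("group_summary.csv"), index=False)
        # multicollinearity diagnostic per station
        vif_rows = []
        for sid, grp in exp.groupby("station_id"):
            try:
                v = yield_stats.variance_inflation(grp["dhd"], grp["hhd"])
                vif_rows.append({"station_id": sid, "r": v.r, "vif": v.vif})
            except ValueError:
                vif_rows.append({"station_id": sid, "r": np.nan, "vif": np.nan})
        pd.DataFrame(vif_rows).to_csv(self._path("vif.csv"), index=False)

    def panel(self) -> None:
        exp = pd.read_csv(self._path("exposures.csv"), dtype={"station_id": str})
        meta = io.read_metadata_csv(self._path("station_metadata.csv"))
        panel = self._yield_panel()
        fe = yield_stats.fit_fixed_effects(
            panel, exp, crop=self.cfg.crop, station_county=meta
        )
        pd.DataFrame(
            [
                {
                    "beta1": fe.beta1,
                    "beta2": fe.beta2,
                    "se_beta1": fe.se_beta1,
                    "se_beta2": fe.se_beta2,
                    "p_beta1": fe.p_beta1,
                    "p_beta2": fe.p_beta2,
                    "n_obs": fe.n_obs,
                    "n_counties": fe.n_counties,
                    "n_years": fe.n_years,
                }
            ]
        ).to_csv(self._path("fixed_effects.csv"), index=False)

    def composites(self) -> None:
        stations, _ = self._load_stations()
        labels = pd.read_csv(self._path("labels.csv"), dtype={"station_id": str})
        labels["date"] = pd.to_datetime(labels["date"])
        comp_rows, diff_rows = [], []
        for s in stations:
            lab = labels[labels["station_id"] == s.station_id]
            if lab.empty:
                continue
            per_class = {}
            for cls in (heat_events.DRY_HEAT, heat_events.HUMID_HEAT):
                if not (lab["label"] == cls).any():
                    continue
                for window in composites.WINDOWS:
                    c = composites.event_relative_precip(s, lab, cls, window)
                    per_class[(cls, window)] = c
                    comp_rows.append(
                        {
                            "station_id": s.station_id,
                            "event_class": cls,
                            "window": window,
                            "mean_precip_mm": c.mean,
                            "n_events": c.n_events,
                        }
                    )
            for window in composites.WINDOWS:
                key_d = (heat_events.DRY_HEAT, window)
                key_h = (heat_events.HUMID_HEAT, window)
                if key_d in per_class and key_h in per_class:
                    diff, p = composites.composite_difference(per_class[key_d], per_class[key_h])
                    diff_rows.append(
                        {
                            "station_id": s.station_id,
                            "window": window,
                            "humid_minus_dry_mm": diff,
                            "p_value": p,
                        }
                    )
            tm = composites.mean_tmax_by_class(s, lab)
            if len(tm):
                tm.to_csv(
                    self._path("tmax_by_class.csv"),
                    mode="a",
                    header=not self._path("tmax_by_class.csv").exists(),
                    index=False,
                )
        pd.DataFrame(comp_rows).to_csv(self._path("composites.csv"), index=False)
        pd.DataFrame(diff_rows).to_csv(self._path("composite_differences.csv"), index=False)

    def report(self) -> None:
        coeffs = pd.read_csv(self._path("regression_coefficients.csv"), dtype={"station_id": str})
        fe = pd.read_csv(self._path("fixed_effects.csv"))
        non_irr = coeffs[coeffs["irrigated"] == 0]
        table1 = pd.DataFrame(
            [
                {
                    "method": "per_county_regression_area_average",
                    "crop": self.cfg.crop,
                    "beta1_bu_acre_day": non_irr["beta1"].mean(),
                    "beta2_bu_acre_day": non_irr["beta2"].mean(),
                },
                {
                    "method": "fixed_effects_panel",
                    "crop": self.cfg.crop,
                    "beta1_bu_acre_day": fe["beta1"].iloc[0],
                    "beta2_bu_acre_day": fe["beta2"].iloc[0],
                },
            ]
        )
        table1.to_csv(self._path("table1_analogue.csv"), index=False)
        panel = self._yield_panel()
        mean_yield = panel.loc[panel["irrigated"] == 0, "yield_bu_acre"].mean()
        exp = pd.read_csv(self._path("exposures.csv"))
        avg_days = exp["dhd"].groupby(exp["year"]).mean().mean()
        per_day, cumulative = yield_stats.percent_yield_impact(
            non_irr["beta1"].mean(), mean_yield, avg_days
        )
        pd.DataFrame(
            [
                {
                    "crop": self.cfg.crop,
                    "mean_yield_bu_acre": mean_yield,
                    "avg_dry_heat_days": avg_days,
                    "percent_per_day": per_day,
                    "cumulative_percent": cumulative,
                }
            ]
        ).to_csv(self._path("percent_impact.csv"), index=False)

    # -- driver ------------------------------------------------------------
    def run(self, stage: str | None = None) -> Path:
        """Run all stages up to ``stage`` (default: the full pipeline)."""
        stop = stage or "report"
        if stop not in STAGES:
            raise ValueError(f"unknown stage {stop!r}; choose from {STAGES}")
        # fresh tmax_by_class accumulation on every run
        tbc = self._path("tmax_by_class.csv")
        if tbc.exists():
            tbc.unlink()
        for name in STAGES[: STAGES.index(stop) + 1]:
            try:
                getattr(self, name)()
            except Exception as exc:
                self._write_log(failed_stage=name, error=str(exc))
                raise StageError(name, exc) from exc
        self._write_log()
        return self.outdir

    def _write_log(self, failed_stage: str | None = None, error: str | None = None) -> None:
        log = {
            "seed": self.cfg.synthetic.seed,
            "config_hash": _config_hash(self.cfg),
            "heatyield_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "level": self.cfg.level,
            "season": self.cfg.season_name,
            "crop": self.cfg.crop,
        }
        if failed_stage:
            log["failed_stage"] = failed_stage
            log["error"] = error
        with open(self._path("run_log.json"), "w") as fh:
            json.dump(log, fh, indent=2, sort_keys=True)


def run_pipeline(
    cfg: PipelineConfig, outdir: str | Path, stage: str | None = None
) -> Path:
    """Convenience wrapper: build a :class:`Pipeline` and run it."""
    return Pipeline(cfg, outdir).run(stage)
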
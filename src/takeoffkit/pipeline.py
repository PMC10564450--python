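"""End-to-end orchestration: read -> mask -> detect -> wind/wave/motion -> stats.

Runs are deterministic given the config and inputs. A manifest records the
parameter values and the event count surviving each filter stage
(trips -> take-offs -> wind-eligible -> wind-reliable -> wave-eligible ->
both), and every excluded event carries the rule that excluded it, so the
differing sample sizes of the downstream analyses are auditable.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import env_stats, motion_analysis, wave_estimate, wind_estimate
from ._utils import EligibilityError
from .io_logger import Deployment, mask_colony, write_summary_table
from .synthetic_data import ScenarioConfig, sample_scenarios, simulate_trip
from .takeoff_detect import detect_takeoffs, events_table, smooth_speed

logger = logging.getLogger("takeoffkit")

__all__ = ["RunConfig", "process_deployment", "run_pipeline",
           "run_synthetic_batch"]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the published analysis values."""

    # take-off detection
    speed_threshold: float = 4.0       # m/s
    smooth_window: float = 0.4         # s
    min_floating: float = 30.0         # s
    min_flight: float = 30.0           # s
    dip_tolerance: float = 5.0         # s
    # wind
    wind_window: float = 300.0         # s of flight used
    wind_skip_head: float = 10.0       # s after take-off excluded
    # wave
    wave_min_float: float = 900.0      # s
    wave_tail_skip: float = 10.0       # s before take-off excluded
    highpass_fc: float = 0.07          # Hz
    min_waves: int = 30
    # running / flapping
    run_band: tuple = (5.0, 20.0)      # Hz
    var_window: float = 0.6            # s
    run_frac: float = 0.02             # threshold = frac * peak variance
    run_search: tuple = (-20.0, 20.0)  # s around take-off
    flap_band: tuple = (1.8, 4.0)      # Hz
    flap_gap: float = 0.5              # s
    # colony mask (None disables)
    colony: tuple | None = None        # (lat, lon, radius_km)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("run_band", "run_search", "flap_band", "colony"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def process_deployment(dep: Deployment, cfg: RunConfig) -> pd.DataFrame:
    """Run every stage on one deployment; one row per detected take-off.

    Stage failures (eligibility, too few waves, missing coverage) skip the
    event's affected columns rather than aborting, and are recorded in the
    ``exclusions`` column.
    """
    if cfg.colony is not None:
        dep = mask_colony(dep, *cfg.colony)
    if len(dep.gnss) == 0:
        return pd.DataFrame()
    sm = smooth_speed(dep.gnss, cfg.smooth_window)
    events = detect_takeoffs(sm, dep.gnss, threshold=cfg.speed_threshold,
                             min_floating=cfg.min_floating,
                             min_flight=cfg.min_flight,
                             dip_tolerance=cfg.dip_tolerance)
    rows = []
    for k, ev in enumerate(events):
        row = {"bird_id": dep.bird_id, "sex": dep.sex, "event": k}
        row.update(ev.as_record())
        excl = []

        # wind
        if ev.flight_duration >= cfg.wind_window:
            west = wind_estimate.estimate_wind(
                dep.gnss, ev, skip_head=cfg.wind_skip_head,
                window=cfg.wind_window)
            row.update({"Va_fit": west.Va, "Vw": west.Vw,
                        "wind_dir_from": west.dir_from,
                        "delta_aic": west.delta_aic,
                        "wind_reliable": west.reliable})
            if not west.reliable:
                excl.append("wind:unreliable_daic")
        else:
            row["wind_reliable"] = False
            excl.append("wind:flight_lt_5min")

        # wave
        if ev.eligible_wave:
            try:
                wav = wave_estimate.estimate_wave(
                    dep.gnss, ev, min_float=cfg.wave_min_float,
                    tail_skip=cfg.wave_tail_skip, fc=cfg.highpass_fc,
                    min_waves=cfg.min_waves)
                row.update({"Hs": wav.Hs, "n_waves": wav.n_waves,
                            "mean_period": wav.mean_period})
            except EligibilityError as e:
                excl.append(f"wave:{e}")
        else:
            excl.append("wave:float_lt_15min")

        # running + flapping
        var = motion_analysis.hf_variance_series(
            dep.accel, band=cfg.run_band, var_window=cfg.var_window)
        phase = motion_analysis.detect_running(
            dep.accel, var, ev.t_takeoff, search=cfg.run_search,
            frac=cfg.run_frac, var_window=cfg.var_window)
        if phase is None:
            excl.append("motion:no_running_signal")
        else:
            vr, theta_t = motion_analysis.running_kinematics(dep.gnss, phase)
            row.update({"run_start": phase.t_start, "run_end": phase.t_end,
                        "run_duration": phase.duration, "Vr": vr,
                        "takeoff_dir": theta_t})
            cd = motion_analysis.cruising_direction(dep.gnss, ev.t_takeoff)
            if cd is not None:
                row["cruising_dir"] = cd
            bout = motion_analysis.count_flaps(
                dep.accel, phase.t_end, band=cfg.flap_band,
                gap=cfg.flap_gap)
            bout = motion_analysis.flap_frequency(dep.accel, bout)
            row["flap_count"] = bout.count
            if bout.frequency is not None and bout.freq_in_range:
                row["flap_freq"] = bout.frequency
            elif bout.frequency is not None:
                excl.append("flap_freq:out_of_range")

            if row.get("wind_reliable") and "Vw" in row:
                row["air_speed"] = float(env_stats.air_speed(
                    vr, row["Vw"], theta_t, row["wind_dir_from"]))
                row["rel_takeoff_dir"] = float(env_stats.relative_angle(
                    theta_t, row["wind_dir_from"]))

        row["exclusions"] = ";".join(excl)
        rows.append(row)
    return pd.DataFrame(rows)


def _categorize(summary: pd.DataFrame) -> pd.DataFrame:
    ok = summary.dropna(subset=["Vw", "Hs"])
    ok = ok[ok["wind_reliable"].astype(bool)]
    summary["category"] = "none"
    if len(ok) >= 30:
        try:
            (wt, ht), labels = env_stats.categorize_conditions(
                ok["Vw"].to_numpy(), ok["Hs"].to_numpy())
            summary.loc[ok.index, "category"] = labels
            summary.attrs["thresholds"] = {"wind": wt, "wave": ht}
        except Exception as e:
            logger.warning("categorization skipped: %s", e)
    return summary


def run_pipeline(deployments, cfg: RunConfig | None = None,
                 out_dir=None, responses=("run_duration", "Vr",
                                          "flap_count", "flap_freq")):
    """Process deployments and produce the joined summary plus statistics.

    Returns a dict with the per-event ``summary`` table, the ``manifest``
    of stage counts, and (when enough complete cases exist) per-response
    mixed-model AIC comparisons, the v-test on relative take-off
    direction, and the VIF of the wind/wave design. Writes per-stage CSVs
    and a manifest JSON when ``out_dir`` is given.
    """
    cfg = cfg or RunConfig()
    frames = [process_deployment(dep, cfg) for dep in deployments]
    frames = [f for f in frames if len(f)]
    summary = (pd.concat(frames, ignore_index=True)
               if frames else pd.DataFrame())
    manifest = {"parameters": asdict(cfg), "n_trips": len(list(deployments))}
    results = {"summary": summary, "manifest": manifest}
    if len(summary):
        summary = _categorize(summary)
        results["summary"] = summary
        rel = summary["wind_reliable"].fillna(False).astype(bool)
        manifest.update({
            "n_takeoffs": int(len(summary)),
            "n_wind_eligible": int(summary["eligible_wind"].sum()),
            "n_wind_reliable": int(rel.sum()),
            "n_wave_eligible": int(summary["eligible_wave"].sum()),
            "n_wave_estimated": int(summary["Hs"].notna().sum())
            if "Hs" in summary else 0,
            "n_both": int((rel & summary.get(
                "Hs", pd.Series(index=summary.index)).notna()).sum()),
        })
        # directional bias of take-off relative to the wind
        if "rel_takeoff_dir" in summary:
            rels = summary["rel_takeoff_dir"].dropna().to_numpy()
            if rels.size >= 5:
                V, u, p = env_stats.v_test(rels, 0.0)
                results["v_test"] = {"V": V, "u": u, "p": p, "n": rels.size}
        both = summary.dropna(subset=["Vw", "Hs"]) if "Hs" in summary else []
        if len(both) >= 3:
            results["vif"] = env_stats.vif(both[["Vw", "Hs"]]).to_dict()
            results["vif_with_interaction"] = env_stats.vif(
                both[["Vw", "Hs"]], add_interaction=True).to_dict()
        models = {}
        for resp in responses:
            if resp not in summary:
                continue
            try:
                models[resp] = env_stats.fit_lmm_compare(summary, resp)
            except Exception as e:
                logger.info("LMM for %s skipped: %s", resp, e)
        results["models"] = models

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_summary_table(summary, out / "summary.csv")
        if results.get("models"):
            write_summary_table(
                pd.concat([m.as_records() for m in
                           results["models"].values()], ignore_index=True),
                out / "model_comparison.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(_jsonable(manifest), fh, indent=2)
    return results


def run_synthetic_batch(n_trips: int, seed: int,
                        base: ScenarioConfig | None = None,
                        cfg: RunConfig | None = None, out_dir=None):
    """Simulate ``n_trips`` trips with known truth and run the pipeline.

    Returns (results, truth) where ``truth`` is the concatenated
    ground-truth table, one row per simulated take-off.
    """
    scenarios = sample_scenarios(n_trips, seed, base=base)
    deps, truths = [], []
    for sc in scenarios:
        dep, truth = simulate_trip(sc)
        deps.append(dep)
        truths.append(truth)
    truth = pd.concat(truths, ignore_index=True)
    results = run_pipeline(deps, cfg=cfg, out_dir=out_dir)
    results["truth"] = truth
    if out_dir is not None:
        write_summary_table(truth, Path(out_dir) / "truth.csv")
    return results


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
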
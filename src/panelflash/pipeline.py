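"""End-to-end orchestration: flow calibration -> tracking -> L/D statistics.

A single YAML/dict config drives one or two (paired-regime) runs; outputs are
deterministic for a given config + seed and every file embeds the config
hash so reports refuse to mix incompatible runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import flow, ldcycles, light, metrics, transport
from .geometry import ConfigurationError, build_geometry

__all__ = ["validate_config", "run_pipeline", "comparison_table", "config_hash"]

log = logging.getLogger("panelflash")

DEFAULT_CONFIG = {
    "geometry": {},
    "flow": {
        "aeration_vvm": 0.02,
        "regimes": ["unbaffled", "baffled"],
        # scalar, or per-regime mapping {"unbaffled": ..., "baffled": ...}
        "turbulence_intensity": {"unbaffled": 0.10, "baffled": 0.25},
        "eddy_time_s": 0.5,
    },
    "tracking": {
        "n_particles": 1000,
        "dt_s": 0.004,
        "record_dt_s": 0.1,
        "t_max_s": 60.0,
        "seed": 0,
    },
    "light": {
        "I0": 530.0,
        "I_crit": 96.84,
        "calibration_pairs": [[0.28, 5.0], [0.85, 2.0], [1.7, 1.0]],
        "concentration_g_per_l": 0.85,
    },
}


def _merged(config: dict | None) -> dict:
    cfg = {k: dict(v) for k, v in DEFAULT_CONFIG.items()}
    for section, values in (config or {}).items():
        if section not in cfg:
            cfg[section] = values
        elif isinstance(values, dict):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of the canonical JSON form of a config."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def validate_config(config: dict) -> dict:
    """Merge with defaults and check every block before any compute starts."""
    cfg = _merged(config)
    trk = cfg["tracking"]
    if int(trk["n_particles"]) < 2:
        raise ConfigurationError("tracking.n_particles must be >= 2")
    if trk["dt_s"] <= 0 or trk["record_dt_s"] <= 0 or trk["t_max_s"] <= 0:
        raise ConfigurationError("tracking times must be positive")
    ratio = trk["record_dt_s"] / trk["dt_s"]
    if abs(ratio - round(ratio)) > 1e-9:
        raise ConfigurationError("record_dt_s must be an integer multiple of dt_s")
    regimes = cfg["flow"].get("regimes") or [
        "baffled" if cfg["flow"].get("baffled", True) else "unbaffled"
    ]
    for r in regimes:
        if r not in ("baffled", "unbaffled"):
            raise ConfigurationError(f"unknown flow regime {r!r}")
    cfg["flow"]["regimes"] = list(regimes)
    ti = cfg["flow"]["turbulence_intensity"]
    if not isinstance(ti, dict):
        cfg["flow"]["turbulence_intensity"] = {r: float(ti) for r in regimes}
    lt = cfg["light"]
    if "sigma_a" not in lt and not lt.get("calibration_pairs"):
        raise ConfigurationError("light block needs sigma_a or calibration_pairs")
    if lt["concentration_g_per_l"] <= 0:
        raise ConfigurationError("light.concentration_g_per_l must be positive")
    # geometry block validates itself on construction
    build_geometry(cfg["geometry"])
    return cfg


def _light_model(cfg: dict, illuminated_face: str) -> light.LightModel:
    lt = cfg["light"]
    if "sigma_a" in lt:
        return light.LightModel(
            I0=lt["I0"], I_crit=lt["I_crit"], sigma_a=lt["sigma_a"],
            illuminated_face=illuminated_face,
        )
    return light.fit_attenuation(
        [tuple(p) for p in lt["calibration_pairs"]],
        I0=lt["I0"], I_crit=lt["I_crit"], illuminated_face=illuminated_face,
    )


def run_pipeline(
    config: dict | None = None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Execute the configured run(s) and return the report dict.

    When two regimes are configured, the report includes a paired comparison
    with percent-change columns (first regime is the reference).  With
    ``out_dir`` set, trajectory CSVs, summary JSONs and the comparison table
    are written there.
    """
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["tracking"]["seed"] = int(seed)
    chash = config_hash(cfg)

    geom_unbaffled = build_geometry({**cfg["geometry"], "baffle_count": 0})
    geom_baffled = build_geometry(cfg["geometry"])
    conc = cfg["light"]["concentration_g_per_l"]
    rate = cfg["flow"]["aeration_vvm"]
    trk = cfg["tracking"]

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    run_reports = {}
    summaries = {}
    for regime in cfg["flow"]["regimes"]:
        baffled = regime == "baffled"
        geom = geom_baffled if baffled else geom_unbaffled
        log.info("stage=calibrate regime=%s rate=%.3g vvm", regime, rate)
        try:
            fld = flow.calibrate_field(geom, rate, baffled)
            intensity = cfg["flow"]["turbulence_intensity"].get(
                regime, flow.default_turbulence_intensity(baffled)
            )
            fld = flow.turbulence_field(fld, intensity, cfg["flow"]["eddy_time_s"])
        except Exception as exc:
            raise RuntimeError(f"stage 'calibrate' failed for regime {regime}: {exc}") from exc

        log.info("stage=track regime=%s n=%d", regime, trk["n_particles"])
        try:
            traj = transport.track(
                fld,
                geom,
                n=int(trk["n_particles"]),
                dt=trk["dt_s"],
                record_dt=trk["record_dt_s"],
                t_max=trk["t_max_s"],
                seed=int(trk["seed"]),
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'track' failed for regime {regime}: {exc}") from exc

        log.info("stage=ld-stats regime=%s", regime)
        model = _light_model(cfg, geom.illuminated_face)
        series = ldcycles.binarize(traj, model, geom, conc)
        summary = ldcycles.population_summary(
            series,
            provenance={"regime": regime, "aeration_vvm": rate, "config_hash": chash},
        )
        vz = metrics.vertical_velocity(fld, geom)
        vx = metrics.horizontal_velocity(fld, geom)
        run_reports[regime] = {
            "t_av_p_s": summary.t_av_p,
            "mean_light_fraction": summary.mean_light_fraction,
            "bin_5_10_probability": ldcycles.bin_probability(summary, 5.0, 10.0),
            "vz_cm_s": vz,
            "vx_cm_s": vx,
            "n_used": summary.n_used,
            "n_total": summary.n_total,
        }
        summaries[regime] = summary
        if out is not None:
            transport.trajectories_to_csv(traj, out / f"trajectories_{regime}.csv")
            (out / f"summary_{regime}.json").write_text(
                ldcycles.summary_to_json(summary)
            )

    report = {
        "config_hash": chash,
        "seed": int(trk["seed"]),
        "aeration_vvm": rate,
        "concentration_g_per_l": conc,
        "runs": run_reports,
    }
    if len(run_reports) >= 2:
        table = comparison_table(
            [dict(v, regime=k) for k, v in run_reports.items()]
        )
        report["comparison"] = table.to_dict(orient="index")
        if out is not None:
            table.to_csv(out / "comparison.csv")
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    return report


_COMPARE_METRICS = [
    "t_av_p_s",
    "mean_light_fraction",
    "bin_5_10_probability",
    "vz_cm_s",
    "vx_cm_s",
]


def comparison_table(summaries: list[dict]) -> pd.DataFrame:
    """Metric rows x run columns, with percent change vs the first run.

    Runs must stem from the same geometry/config family when hashes are
    present; mismatched hashes are refused.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two run summaries to compare")
    hashes = {s["config_hash"] for s in summaries if "config_hash" in s}
    if len(hashes) > 1:
        raise ValueError(f"refusing to compare runs with different config hashes: {hashes}")
    names = [s.get("regime", f"run{i}") for i, s in enumerate(summaries)]
    data = {
        name: [s.get(m, np.nan) for m in _COMPARE_METRICS]
        for name, s in zip(names, summaries)
    }
    df = pd.DataFrame(data, index=_COMPARE_METRICS)
    ref = names[0]
    for name in names[1:]:
        df[f"pct_change_{name}_vs_{ref}"] = [
            metrics.percent_change(df.at[m, ref], df.at[m, name])
            if df.at[m, ref] not in (0, np.nan)
            else np.nan
            for m in _COMPARE_METRICS
        ]
    return df
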
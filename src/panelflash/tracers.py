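"""Probe-trace simulators and estimators for mixing time and kLa.

The dissolved-oxygen re-aeration trace obeys dC/dt = kLa (C* - C); the pH
pulse response approaches its final value exponentially with a damped
circulation oscillation superposed.  Estimators recover kLa (dynamic
gassing-out regression) and the 5 %-criterion mixing time from such traces.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ProbeTrace",
    "MixingSimParams",
    "FitError",
    "EstimationError",
    "simulate_do_trace",
    "estimate_kla",
    "simulate_ph_trace",
    "estimate_mixing_time",
    "trace_to_csv",
    "traces_from_csv",
]

SECONDS_PER_HOUR = 3600.0


class FitError(RuntimeError):
    """Raised when a re-aeration trace cannot support a kLa fit."""


class EstimationError(RuntimeError):
    """Raised when a probe trace has no stable final value."""


@dataclass(frozen=True)
class ProbeTrace:
    times: np.ndarray  # s, uniform grid
    values: np.ndarray
    probe_id: str = "probe-1"
    kind: str = "DO"  # "DO" or "pH"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) >= 2:
            dts = np.diff(t)
            if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(v)):
            raise ValueError("trace values must be finite")


def simulate_do_trace(
    kla_per_h: float,
    c_star: float,
    c0: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    dt: float = 0.1,
) -> ProbeTrace:
    """Synthetic dissolved-oxygen re-aeration curve, mg/L on a ``dt`` grid."""
    if kla_per_h <= 0:
        raise ValueError("kla must be positive")
    if c0 >= c_star:
        raise ValueError("initial concentration must be below saturation")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    kla_s = kla_per_h / SECONDS_PER_HOUR
    values = c_star - (c_star - c0) * np.exp(-kla_s * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, len(t))
    return ProbeTrace(times=t, values=values, probe_id="do-probe", kind="DO")


def estimate_kla(
    trace: ProbeTrace, c_star: float | None = None
) -> tuple[float, dict]:
    """Recover kLa (1/h) from a re-aeration trace.

    With known saturation ``c_star``: linear regression of ln(C* - C) on t
    (slope = -kLa).  Without it: three-parameter nonlinear least squares over
    (kLa, C*, C0).  Returns (kla_per_h, diagnostics).
    """
    t = np.asarray(trace.times, dtype=float)
    v = np.asarray(trace.values, dtype=float)
    span = v[-1] - v[0]
    if span <= 0 or stats.pearsonr(t, v).statistic < 0.5:
        raise FitError("trace is not an increasing re-aeration curve")

    if c_star is not None:
        deficit = c_star - v
        d0 = c_star - v[0]
        if d0 <= 0 or (deficit > 0).sum() < 3:
            raise FitError("trace saturated from the start; nothing to fit")
        if deficit[deficit > 0][-1] / d0 > 0.25:
            raise FitError("trace spans fewer than two half-lives")
        # drop the near-saturated tail where ln(deficit) is noise-dominated
        ok = deficit > 0.05 * d0
        res = stats.linregress(t[ok], np.log(deficit[ok]))
        kla = -res.slope * SECONDS_PER_HOUR
        diag = {
            "method": "log-linear",
            "stderr_per_h": res.stderr * SECONDS_PER_HOUR,
            "r_value": res.rvalue,
            "n": int(ok.sum()),
        }
        return float(kla), diag

    def model(tt, kla_s, cs, c0):
        return cs - (cs - c0) * np.exp(-kla_s * tt)

    guess = (1.0 / max(t[-1] / 4.0, 1e-6), float(v.max()) * 1.05, float(v[0]))
    popt, pcov = optimize.curve_fit(model, t, v, p0=guess, maxfev=20000)
    kla = popt[0] * SECONDS_PER_HOUR
    if (c_star_fit := popt[1]) - v[-1] < -abs(span):
        raise FitError("nonlinear fit produced an implausible saturation level")
    stderr = float(np.sqrt(pcov[0, 0])) * SECONDS_PER_HOUR if np.all(np.isfinite(pcov)) else np.nan
    return float(kla), {
        "method": "nonlinear",
        "c_star_fit": float(c_star_fit),
        "c0_fit": float(popt[2]),
        "stderr_per_h": stderr,
        "n": len(t),
    }


@dataclass(frozen=True)
class MixingSimParams:
    """Parameters of the synthetic two-probe pH pulse response."""

    ph_initial: float = 4.0
    ph_final: float = 11.0
    circulation_time: float = 9.0  # s, oscillation period
    decay_time: float = 7.5  # s, exponential envelope time constant
    probe_phase_offsets: tuple[float, ...] = (0.0, 2.0)  # s
    oscillation_amplitude: float = 0.1  # fraction of the decaying deviation
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.decay_time <= 0:
            raise ValueError("decay_time must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.oscillation_amplitude < 0.5:
            raise ValueError("oscillation_amplitude must be in [0, 0.5)")


def simulate_ph_trace(
    params: MixingSimParams, duration: float, dt: float = 0.1
) -> list[ProbeTrace]:
    """One synthetic trace per probe; value(0) = ph_initial at every probe.

    deviation(t) = (ph_final - ph_initial) exp(-t / decay_time) g(t) with
    g(t) = 1 + m (cos(2 pi t / T_c + phi) - cos(phi)), so g(0) = 1 exactly and
    g stays within (1 - 2m, 1 + 2m]; the exponential envelope guarantees a
    well-defined settling time.
    """
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    delta = params.ph_final - params.ph_initial
    m = params.oscillation_amplitude
    rng = np.random.default_rng(params.seed)
    traces = []
    for i, offset in enumerate(params.probe_phase_offsets):
        phi = 2.0 * np.pi * offset / params.circulation_time
        if m > 0:
            g = 1.0 + m * (np.cos(2.0 * np.pi * t / params.circulation_time + phi) - np.cos(phi))
        else:
            g = np.ones_like(t)
        values = params.ph_final - delta * np.exp(-t / params.decay_time) * g
        if params.noise_sd > 0:
            values = values + rng.normal(0.0, params.noise_sd, len(t))
        traces.append(
            ProbeTrace(times=t, values=values, probe_id=f"ph-probe-{i + 1}", kind="pH")
        )
    return traces


def settling_time(
    times: np.ndarray, values: np.ndarray, threshold: float
) -> tuple[float, float]:
    """(settling time, final value) for one trace under the 5 % criterion.

    Final value = mean of the last 10 % of samples; settling time = earliest t
    such that every later sample stays within threshold * |final - initial| of
    the final value.
    """
    n_tail = max(1, len(values) // 10)
    final = float(np.mean(values[-n_tail:]))
    span = abs(final - values[0])
    if span == 0:
        return 0.0, final
    tail_spread = np.ptp(values[-n_tail:])
    if tail_spread > threshold / 5.0 * span:
        raise EstimationError(
            f"trace tail is not stable (spread {tail_spread:.3g} vs span {span:.3g})"
        )
    outside = np.abs(values - final) > threshold * span
    if not outside.any():
        return 0.0, final
    last_out = int(np.flatnonzero(outside)[-1])
    if last_out + 1 >= len(values):
        raise EstimationError("trace never settles within the threshold")
    return float(times[last_out + 1]), final


def estimate_mixing_time(
    traces: Sequence[ProbeTrace], threshold: float = 0.05
) -> float:
    """Worst-case (maximum over probes) settling time, seconds."""
    if not traces:
        raise ValueError("need at least one probe trace")
    return max(
        settling_time(np.asarray(tr.times), np.asarray(tr.values), threshold)[0]
        for tr in traces
    )


def trace_to_csv(traces: Sequence[ProbeTrace] | ProbeTrace, path) -> None:
    if isinstance(traces, ProbeTrace):
        traces = [traces]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_s", "value", "probe_id", "kind"])
        for tr in traces:
            for t, v in zip(tr.times, tr.values):
                w.writerow([f"{t:.3f}", f"{v:.8g}", tr.probe_id, tr.kind])


def traces_from_csv(path) -> list[ProbeTrace]:
    groups: dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            g = groups.setdefault(
                row["probe_id"], {"t": [], "v": [], "kind": row["kind"]}
            )
            g["t"].append(float(row["t_s"]))
            g["v"].append(float(row["value"]))
    return [
        ProbeTrace(
            times=np.asarray(g["t"]),
            values=np.asarray(g["v"]),
            probe_id=pid,
            kind=g["kind"],
        )
        for pid, g in groups.items()
    ]
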
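"""Light/dark cycle statistics along tracked trajectories.

A complete L/D cycle is one maximal light interval followed by one maximal
dark interval.  Cycles begin with their light phase; leading and trailing
partial cycles (whose start or end is not observed) are discarded, which is
equivalent to measuring the spacing between successive dark-to-light
transitions.  Per-cell average periods feed the population average, the
flashing frequency f = 1/T, and the period histogram.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import ReactorGeometry
from .light import LightModel, classify_positions
from .transport import TrajectorySet

__all__ = [
    "LDSeries",
    "LDCycleSummary",
    "SummaryError",
    "binarize",
    "cycle_periods",
    "particle_stats",
    "population_summary",
    "summary_to_json",
]


class SummaryError(RuntimeError):
    """Raised when no particle completes a single L/D cycle."""


@dataclass(frozen=True)
class LDSeries:
    particle_id: int
    record_times: np.ndarray
    states: np.ndarray  # bool, True = light

    def __post_init__(self) -> None:
        if len(self.record_times) != len(self.states):
            raise ValueError("states and record_times must have equal length")


@dataclass(frozen=True)
class LDCycleSummary:
    per_particle: list  # rows of (id, T_av_i or None, f_i or None, fraction, n_cycles)
    t_av_p: float
    mean_light_fraction: float
    histogram_edges: np.ndarray  # s
    histogram_probabilities: np.ndarray
    n_used: int
    n_total: int
    provenance: dict = field(default_factory=dict)


def binarize(
    traj: TrajectorySet,
    model: LightModel,
    geom: ReactorGeometry,
    concentration: float,
) -> list[LDSeries]:
    """Classify every recorded position of every particle as light/dark."""
    states = classify_positions(model, geom, traj.positions[:, :, 0], concentration)
    return [
        LDSeries(int(pid), traj.record_times, states[i])
        for i, pid in enumerate(traj.particle_ids)
    ]


def cycle_periods(series: LDSeries | np.ndarray, record_dt: float | None = None) -> np.ndarray:
    """Durations (s) of complete light+dark cycles in a binary series.

    Implemented as differences between consecutive dark->light transition
    times, which drops leading and trailing partial cycles.
    """
    if isinstance(series, LDSeries):
        states = np.asarray(series.states, dtype=bool)
        dt = float(series.record_times[1] - series.record_times[0]) if len(states) > 1 else 0.0
    else:
        states = np.asarray(series, dtype=bool)
        if record_dt is None:
            raise ValueError("record_dt required when passing a raw state array")
        dt = record_dt
    if len(states) < 2:
        return np.empty(0)
    s = states.astype(np.int8)
    starts = np.flatnonzero((s[1:] == 1) & (s[:-1] == 0)) + 1
    if len(starts) < 2:
        return np.empty(0)
    return np.diff(starts) * dt


def particle_stats(series: LDSeries) -> tuple[float | None, float | None, float, int]:
    """Return (T_av_i, f_i, light_fraction_i, n_complete_cycles)."""
    periods = cycle_periods(series)
    fraction = float(np.mean(series.states)) if len(series.states) else 0.0
    if len(periods) == 0:
        return None, None, fraction, 0
    t_av = float(np.mean(periods))
    return t_av, 1.0 / t_av, fraction, int(len(periods))


def population_summary(
    all_series: list[LDSeries],
    bin_width: float = 5.0,
    provenance: dict | None = None,
) -> LDCycleSummary:
    """Population L/D statistics over per-particle averages.

    ``t_av_p`` and the histogram cover only particles with at least one
    complete cycle; the light-time fraction averages over all particles.
    """
    if not all_series:
        raise SummaryError("no series supplied")
    rows = []
    t_avs = []
    fractions = []
    for s in all_series:
        t_av, f, frac, n_cyc = particle_stats(s)
        rows.append((s.particle_id, t_av, f, frac, n_cyc))
        fractions.append(frac)
        if t_av is not None:
            t_avs.append(t_av)
    if not t_avs:
        raise SummaryError("no particle completed a full L/D cycle")
    t_avs = np.asarray(t_avs)
    n_bins = int(np.floor(t_avs.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(t_avs, bins=edges)
    probs = counts / counts.sum()
    return LDCycleSummary(
        per_particle=rows,
        t_av_p=float(t_avs.mean()),
        mean_light_fraction=float(np.mean(fractions)),
        histogram_edges=edges,
        histogram_probabilities=probs,
        n_used=int(len(t_avs)),
        n_total=len(all_series),
        provenance=dict(provenance or {}),
    )


def bin_probability(summary: LDCycleSummary, lo: float, hi: float) -> float:
    """Probability mass of per-particle periods in [lo, hi)."""
    edges = summary.histogram_edges
    mask = (edges[:-1] >= lo) & (edges[1:] <= hi)
    return float(summary.histogram_probabilities[mask].sum())


def summary_to_json(summary: LDCycleSummary) -> str:
    """Serialise a summary deterministically (sorted keys, no timestamps)."""
    payload = {
        "t_av_p_s": summary.t_av_p,
        "mean_light_fraction": summary.mean_light_fraction,
        "histogram": {
            "edges_s": [float(e) for e in summary.histogram_edges],
            "probabilities": [float(p) for p in summary.histogram_probabilities],
        },
        "n_used": summary.n_used,
        "n_total": summary.n_total,
        "provenance": summary.provenance,
    }
    return json.dumps(payload, sort_keys=True, indent=2)
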
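"""Discrete-event simulator of the trial's electric-stimulation rules.

Both fish receive a mild 0.5 V pulse for 300 ms at the start of every 1 s
cycle, phase-locked to trial start. A bite gives the bitten fish one 4 V
transient for 100 ms (overriding any concurrent mild pulse) and relieves
the biter of the mild stimulus for 2 min; a repeat bite inside an open
relief window restarts (does not extend additively beyond) the window.
Mutual same-frame bites apply both rules to both fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ArenaProtocolConfig
from .geometry import BiteEvent

Segment = tuple[float, float, float]  # (start_ms, end_ms, voltage)


@dataclass
class StimulusTrace:
    """Piecewise-constant per-fish voltage schedule (off segments omitted)."""

    fish_id: str
    trial_length_ms: float
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments.sort()
        prev_end = 0.0
        for start, end, _v in self.segments:
            if start < prev_end - 1e-9 or end > self.trial_length_ms + 1e-9:
                raise ValueError("segments must be non-overlapping and inside the trial")
            prev_end = end

    def voltage_at(self, t_ms: float) -> float:
        for start, end, v in self.segments:
            if start <= t_ms < end:
                return v
        return 0.0


def _subtract_intervals(
    segments: list[tuple[float, float]], holes: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Clip [start, end) intervals against a list of hole intervals."""
    out = list(segments)
    for hlo, hhi in holes:
        nxt = []
        for lo, hi in out:
            if hhi <= lo or hlo >= hi:
                nxt.append((lo, hi))
                continue
            if lo < hlo:
                nxt.append((lo, hlo))
            if hhi < hi:
                nxt.append((hhi, hi))
        out = nxt
    return [(lo, hi) for lo, hi in out if hi > lo]


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def simulate_stimulation(
    bites: list[BiteEvent],
    trial_length_ms: float,
    config: ArenaProtocolConfig,
    fish_ids: tuple[str, str] = ("a", "b"),
) -> dict[str, StimulusTrace]:
    """Per-fish stimulus traces for a bite-event stream.

    Bite frames are converted to milliseconds with the configured frame
    interval. Raises if a bite falls outside the trial.
    """
    if trial_length_ms <= 0:
        raise ValueError("trial length must be positive")
    dt = config.frame_interval_ms
    bite_times: dict[str, list[float]] = {f: [] for f in fish_ids}
    transient_times: dict[str, list[float]] = {f: [] for f in fish_ids}
    for ev in bites:
        t_ms = ev.t * dt
        if not 0 <= t_ms <= trial_length_ms:
            raise ValueError(f"bite at frame {ev.t} ({t_ms} ms) outside the trial")
        if ev.biter not in bite_times or ev.bitten not in bite_times:
            raise ValueError(f"bite references unknown fish ids {ev.biter}/{ev.bitten}")
        bite_times[ev.biter].append(t_ms)
        transient_times[ev.bitten].append(t_ms)

    # phase-locked mild pulse onsets, truncated at trial end
    mild: list[tuple[float, float]] = []
    t = 0.0
    while t < trial_length_ms:
        mild.append((t, min(t + config.mild_on_ms, trial_length_ms)))
        t += config.mild_period_ms

    traces: dict[str, StimulusTrace] = {}
    for fid in fish_ids:
        relief = _merge_intervals(
            [(tb, min(tb + config.relief_ms, trial_length_ms)) for tb in bite_times[fid]]
        )
        transients = _merge_intervals(
            [(tb, min(tb + config.transient_ms, trial_length_ms)) for tb in transient_times[fid]]
        )
        mild_kept = _subtract_intervals(mild, relief)
        # a concurrent transient overrides the mild pulse (higher voltage wins)
        mild_kept = _subtract_intervals(mild_kept, transients)
        segments = [(lo, hi, config.mild_voltage) for lo, hi in mild_kept]
        segments += [(lo, hi, config.transient_voltage) for lo, hi in transients]
        traces[fid] = StimulusTrace(
            fish_id=fid, trial_length_ms=trial_length_ms, segments=segments
        )
    return traces


def stimulus_summary(trace: StimulusTrace) -> dict:
    """Accumulated on-time (ms) and duty fraction per voltage level."""
    totals: dict[float, float] = {}
    for start, end, v in trace.segments:
        totals[v] = totals.get(v, 0.0) + (end - start)
    total_on = sum(totals.values())
    return {
        "total_on_ms": {v: ms for v, ms in sorted(totals.items())},
        "duty_fraction": {
            v: ms / trace.trial_length_ms for v, ms in sorted(totals.items())
        },
        "overall_duty_fraction": total_on / trace.trial_length_ms,
        "n_segments": len(trace.segments),
    }


def trace_table(traces: dict[str, StimulusTrace]):
    """Long-form DataFrame of traces: fish_id, start_ms, end_ms, voltage."""
    import pandas as pd

    rows = [
        {"fish_id": fid, "start_ms": s, "end_ms": e, "voltage": v}
        for fid, trace in traces.items()
        for s, e, v in trace.segments
    ]
    return pd.DataFrame(rows, columns=["fish_id", "start_ms", "end_ms", "voltage"])


def plot_trace(trace: StimulusTrace, ax=None):
    """Step plot of one fish's voltage schedule."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(8, 2))
    ts, vs = [0.0], [0.0]
    for start, end, v in trace.segments:
        ts += [start, start, end, end]
        vs += [0.0, v, v, 0.0]
    ts.append(trace.trial_length_ms)
    vs.append(0.0)
    ax.plot(ts, vs, drawstyle="steps-post")
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("voltage (V)")
    ax.set_title(f"stimulus schedule, fish {trace.fish_id}")
    return ax
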
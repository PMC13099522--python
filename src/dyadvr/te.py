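"""Discrete plug-in transfer entropy on symbolized ethograms.

T(P->Q) = H(Q_t | Q_{t-1:t-L}) - H(Q_t | Q_{t-1:t-L}, P_{t-1:t-L}), with
Shannon entropies estimated by plugging in empirical joint frequencies.
Entropies are in bits (log base 2); the estimate is clamped at zero.

Two symbolizations are supported:

* merged ethogram (K=4): per frame, the pair of signs of the frame-to-frame
  change in forward speed and in heading direction, (++), (+-), (-+), (--);
  a zero change counts as '+'.
* 5-level percentile binning (K=5): values split at the series' own
  5/35/65/95th percentiles, boundary values falling to the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .angles import wrap_angle
from .trial import DyadTrial, Trajectory


@dataclass(frozen=True)
class SymbolSeries:
    """Integer symbol sequence over alphabet {0, ..., K-1}."""

    symbols: np.ndarray
    K: int

    def __post_init__(self) -> None:
        s = np.asarray(self.symbols, dtype=np.int64)
        object.__setattr__(self, "symbols", s)
        if self.K < 2:
            raise ValueError("alphabet size K must be >= 2")
        if len(s) and (s.min() < 0 or s.max() >= self.K):
            raise ValueError("symbols must lie in [0, K)")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class TEResult:
    """Transfer entropy in both directions plus the net flow, in bits."""

    te_ab: float
    te_ba: float
    delta_te: float
    K: int
    L: int
    n_samples: int


def merged_ethogram(traj: Trajectory | None = None, *, speed=None, heading=None) -> SymbolSeries:
    """4-symbol series of the signs of speed change and heading change.

    Symbol = 2*(speed decreased) + (heading-change negative); i.e.
    0=(++), 1=(+-), 2=(-+), 3=(--), with zero change mapping to '+'.
    Output length = input length - 1.
    """
    if traj is not None:
        speed = traj.speed
        heading = traj.heading
    speed = np.asarray(speed, dtype=float)
    heading = np.asarray(heading, dtype=float)
    if len(speed) < 2:
        raise ValueError("need at least 2 frames to symbolize changes")
    dspeed = np.diff(speed)
    dheading = wrap_angle(np.diff(heading))
    speed_minus = dspeed < 0
    turn_minus = dheading < 0
    symbols = 2 * speed_minus.astype(np.int64) + turn_minus.astype(np.int64)
    return SymbolSeries(symbols=symbols, K=4)


def percentile_bins(series) -> SymbolSeries:
    """5-level symbolization at the series' 5/35/65/95th percentiles.

    Linear-interpolation quantiles; a value equal to a boundary goes to the
    lower bin ("less than or equal to lowest 5%..."). A constant series
    degenerates to a single occupied bin.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 20:
        raise ValueError("need at least 20 values for stable percentile edges")
    edges = np.percentile(x, [5.0, 35.0, 65.0, 95.0])
    symbols = np.zeros(len(x), dtype=np.int64)
    for edge in edges:
        symbols += (x > edge).astype(np.int64)
    return SymbolSeries(symbols=symbols, K=5)


def _entropy_from_counts(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    n = counts.sum()
    return float(np.log2(n) - (counts * np.log2(counts)).sum() / n)


def _history_codes(symbols: np.ndarray, K: int, L: int) -> np.ndarray:
    """Code of the L-frame history ending at t-1, aligned to targets t=L..n-1."""
    n = len(symbols)
    codes = np.zeros(n - L, dtype=np.int64)
    for lag in range(1, L + 1):
        codes = codes * K + symbols[L - lag : n - lag]
    return codes


def transfer_entropy(src: SymbolSeries, dst: SymbolSeries, L: int = 1) -> float:
    """Plug-in TE estimate (bits) from ``src`` to ``dst`` with history L."""
    if len(src) != len(dst):
        raise ValueError("source and destination series must have equal length")
    n = len(dst)
    if n < L + 1:
        raise ValueError(f"need at least L+1={L + 1} samples")
    q_t = dst.symbols[L:]
    q_hist = _history_codes(dst.symbols, dst.K, L)
    p_hist = _history_codes(src.symbols, src.K, L)
    kq, kqh, kph = dst.K, dst.K**L, src.K**L
    joint_qh = q_t * kqh + q_hist
    joint_qhp = joint_qh * kph + p_hist
    h_qh = _entropy_from_counts(np.bincount(joint_qh, minlength=kq * kqh))
    h_h = _entropy_from_counts(np.bincount(q_hist, minlength=kqh))
    h_qhp = _entropy_from_counts(np.bincount(joint_qhp, minlength=kq * kqh * kph))
    h_hp = _entropy_from_counts(
        np.bincount(q_hist * kph + p_hist, minlength=kqh * kph)
    )
    te = (h_qh - h_h) - (h_qhp - h_hp)
    return max(te, 0.0)


def delta_te(src: SymbolSeries, dst: SymbolSeries, L: int = 1) -> TEResult:
    """TE in both directions plus the net flow src->dst minus dst->src."""
    te_ab = transfer_entropy(src, dst, L)
    te_ba = transfer_entropy(dst, src, L)
    return TEResult(
        te_ab=te_ab,
        te_ba=te_ba,
        delta_te=te_ab - te_ba,
        K=dst.K,
        L=L,
        n_samples=len(dst) - L,
    )


def te_bundle(trial: DyadTrial, L: int = 1) -> dict[str, TEResult]:
    """TE of a trial under all three symbolizations.

    Returns ``{'merged': ..., 'speed': ..., 'turn': ...}``, each a
    :class:`TEResult` with a->b and b->a directions. Speed and turn use the
    logged per-frame values, 5-level percentile binned per fish; the merged
    ethogram uses the sign pairs of their frame-to-frame changes.
    """
    a, b = trial.fish_a, trial.fish_b
    series = {
        "merged": (merged_ethogram(a), merged_ethogram(b)),
        "speed": (percentile_bins(a.speed), percentile_bins(b.speed)),
        "turn": (percentile_bins(a.turn), percentile_bins(b.turn)),
    }
    return {name: delta_te(sa, sb, L) for name, (sa, sb) in series.items()}
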
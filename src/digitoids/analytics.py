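"""Spike-train, waveform, network and statistical post-processing.

Single-neuron traces are summarized by the train metrics

    AR = log10(dV_max / t_train)        (aspect ratio, log10 mV s^-1)
    DR = alpha_env / dV_max             (dissipation rate, s^-1)

where dV_max is the peak-to-peak amplitude of the highest spike, t_train =
t_end - t_start the train duration (t_start: first time V exceeds -60 mV;
t_end: first time after the last spike at which the signal has settled,
|dV/dt| below a tolerance for a sustained window), and alpha_env is the
mean first derivative of the spike-peak envelope.  Single-spike waveforms
yield the peak-to-peak amplitude v_pp, rise rate rr and fall rate fr; the
fall rate is negative by construction (its denominator t_max - t_end < 0).

The balance between diffusive oxygen supply and consumption is captured by
the Thiele modulus Phi^2 = tau_d (tau_nf + tau_f) / (tau_nf tau_f) built
from the characteristic diffusion, basal-consumption and firing-consumption
times.  Network activity is summarized by the mean firing rate (spikes per
neuron per second) and by pairwise event synchronization with an adaptive
coincidence window.  Group comparisons delegate to scipy.stats
(Shapiro-Wilk, Kruskal-Wallis, Mann-Whitney, Spearman).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTrainMetrics", "SpikeShape", "ThieleInputs", "NetworkActivityMetrics",
    "detect_spikes", "train_bounds", "train_metrics", "spike_shape",
    "spike_shapes", "vpp_slope", "thiele_modulus", "mean_firing_rate",
    "event_synchronization", "compare_groups",
]


@dataclass
class SpikeTrainMetrics:
    t_start: float
    t_end: float
    t_train: float
    dV_max: float
    alpha_env: float
    AR: float
    DR: float


@dataclass
class SpikeShape:
    t_max: float
    v_max: float
    v_min: float
    v_pp: float
    rr: float
    fr: float


@dataclass
class ThieleInputs:
    tau_d: float
    tau_nf: float
    tau_f: float
    phi2: float


@dataclass
class NetworkActivityMetrics:
    mFR: float
    Q_sync: float


# ---------------------------------------------------------------------------
# Spike and train detection
# ---------------------------------------------------------------------------

def detect_spikes(t: np.ndarray, v: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Times of upward threshold crossings with positive derivative.

    Crossing times are linearly interpolated between samples; a crossing is
    counted once per upstroke (the trace must fall below the threshold
    before a new spike can be detected).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size == 0 or v.size == 0:
        raise ValueError("empty voltage trace")
    if t.size != v.size:
        raise ValueError("time and voltage arrays must have equal length")
    # strict exceedance: a trace touching the threshold without passing it
    # (zero derivative at the top) is not a spike
    below = v[:-1] <= threshold
    above = v[1:] > threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def train_bounds(t: np.ndarray, v: np.ndarray, start_threshold: float = -60.0,
                 settle_tol: float = 1.0, settle_window: float = 0.05,
                 spike_threshold: float = 0.0) -> tuple[float, float]:
    """(t_start, t_end) of the spike train.

    t_start: first time the signal exceeds ``start_threshold`` (linearly
    interpolated).  t_end: first time at or after the last spike where
    |dV/dt| stays below ``settle_tol`` (mV s^-1) for ``settle_window``
    seconds -- the sampled-data operationalization of "first derivative
    equal to zero"; if the signal never settles, the end of the trace.

    Raises ValueError when no sample exceeds ``start_threshold`` (no train).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    above = np.nonzero(v > start_threshold)[0]
    if above.size == 0:
        raise ValueError("no train: signal never exceeds the start threshold")
    i0 = above[0]
    if i0 == 0:
        t_start = t[0]
    else:
        f = (start_threshold - v[i0 - 1]) / (v[i0] - v[i0 - 1])
        t_start = t[i0 - 1] + f * (t[i0] - t[i0 - 1])

    spikes = detect_spikes(t, v, spike_threshold)
    t_search = spikes[-1] if spikes.size else t_start
    dtv = np.diff(t)
    slopes = np.diff(v) / dtv                 # slope of interval [k, k+1]
    quiet = np.abs(slopes) < settle_tol
    j0 = int(np.searchsorted(t, t_search))
    t_end = t[-1]
    j = j0
    n_int = slopes.size
    while j < n_int:
        if quiet[j]:
            # extend the quiet run and check its span
            k = j
            while k < n_int and quiet[k]:
                k += 1
            if t[k] - t[j] >= settle_window or k == n_int:
                t_end = t[j]
                break
            j = k + 1
        else:
            j += 1
    return float(t_start), float(t_end)


def _peak_segments(t: np.ndarray, v: np.ndarray,
                   threshold: float = 0.0) -> list[tuple[int, int, int]]:
    """Per-spike (start, peak, end) indices.

    Segments run between successive upward threshold crossings; within each
    segment the window is padded outward from the peak to the adjacent
    local minima (the spike onset and after-hyperpolarization trough).
    """
    v = np.asarray(v, dtype=float)
    below = v[:-1] <= threshold
    above = v[1:] > threshold
    cross = np.nonzero(below & above)[0]
    segs = []
    bounds = list(cross) + [v.size - 1]
    for s, e in zip(bounds[:-1], bounds[1:]):
        if e <= s + 1:
            continue
        pk = s + int(np.argmax(v[s:e + 1]))
        i0 = pk
        while i0 > 0 and v[i0 - 1] < v[i0]:
            i0 -= 1
        i1 = pk
        while i1 < v.size - 1 and v[i1 + 1] < v[i1]:
            i1 += 1
        segs.append((i0, pk, i1))
    return segs


def train_metrics(t: np.ndarray, v: np.ndarray, threshold: float = 0.0,
                  start_threshold: float = -60.0, settle_tol: float = 1.0,
                  settle_window: float = 0.05) -> SpikeTrainMetrics:
    """Train-level metrics: bounds, dV_max, envelope slope, AR and DR.

    dV_max is the peak-to-peak amplitude of the highest spike; alpha_env
    the mean finite-difference slope of the spike-peak envelope (NaN with
    fewer than two peaks, in which case DR is NaN too).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    t_start, t_end = train_bounds(t, v, start_threshold, settle_tol,
                                  settle_window, threshold)
    t_train = t_end - t_start
    segs = _peak_segments(t, v, threshold)
    if not segs:
        raise ValueError("no spikes in trace; train metrics undefined")
    peaks = np.array([v[pk] for _, pk, _ in segs])
    times = np.array([t[pk] for _, pk, _ in segs])
    vpps = np.array([v[pk] - v[i0:i1 + 1].min() for i0, pk, i1 in segs])
    dV_max = float(vpps[int(np.argmax(peaks))])
    if peaks.size >= 2:
        alpha_env = float(np.mean(np.diff(peaks) / np.diff(times)))
        DR = alpha_env / dV_max
    else:
        alpha_env = math.nan
        DR = math.nan
    AR = math.log10(dV_max / t_train) if t_train > 0 else math.nan
    return SpikeTrainMetrics(t_start=t_start, t_end=t_end, t_train=t_train,
                             dV_max=dV_max, alpha_env=alpha_env, AR=AR, DR=DR)


def spike_shape(t: np.ndarray, v: np.ndarray,
                window: tuple[int, int]) -> SpikeShape:
    """Waveform metrics for one spike over the index window (i0, i1).

    rr = (v_max - v_start)/(t_max - t_start); fr = (v_max - v_end)/(t_max -
    t_end), negative for a spike that falls after its peak; v_pp = v_max -
    v_min over the window.
    """
    i0, i1 = window
    if i1 <= i0 + 1:
        raise ValueError(f"degenerate spike window {window}")
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    seg = v[i0:i1 + 1]
    pk = i0 + int(np.argmax(seg))
    if pk == i0 or pk == i1:
        raise ValueError("spike window does not bracket a peak")
    v_max, t_max = float(v[pk]), float(t[pk])
    rr = (v_max - v[i0]) / (t_max - t[i0])
    fr = (v_max - v[i1]) / (t_max - t[i1])
    v_min = float(seg.min())
    return SpikeShape(t_max=t_max, v_max=v_max, v_min=v_min,
                      v_pp=v_max - v_min, rr=float(rr), fr=float(fr))


def spike_shapes(t: np.ndarray, v: np.ndarray,
                 threshold: float = 0.0) -> list[SpikeShape]:
    """Shape metrics for every spike in the trace (may be empty)."""
    shapes = []
    for i0, _, i1 in _peak_segments(t, v, threshold):
        try:
            shapes.append(spike_shape(t, v, (i0, i1)))
        except ValueError:
            continue
    return shapes


def vpp_slope(times: np.ndarray, v_pp: np.ndarray) -> float:
    """Least-squares slope over the final four (t, v_pp) points (mV s^-1).

    NaN (missing) with fewer than four spikes.
    """
    times = np.asarray(times, dtype=float)
    v_pp = np.asarray(v_pp, dtype=float)
    if times.size < 4:
        return math.nan
    tt, vv = times[-4:], v_pp[-4:]
    return float(np.polyfit(tt, vv, 1)[0])


# ---------------------------------------------------------------------------
# Regime and network metrics
# ---------------------------------------------------------------------------

def thiele_modulus(h: float, D: float, mp, c_ref: float) -> ThieleInputs:
    """Thiele modulus Phi^2 = tau_d (tau_nf + tau_f) / (tau_nf tau_f).

    tau_d = h^2/D (diffusion); tau_nf = km/R_max (basal consumption);
    tau_f = c_ref/(alpha rho_max) (firing-related consumption, evaluated at
    the reference concentration, conventionally c0).  Phi^2 >> 1 marks the
    diffusion-limited regime.
    """
    if h <= 0 or D <= 0 or c_ref <= 0:
        raise ValueError("h, D and c_ref must be positive")
    tau_d = h * h / D
    tau_nf = mp.km / mp.R_max
    tau_f = c_ref / (mp.alpha_pump * mp.rho_max)
    phi2 = tau_d * (tau_nf + tau_f) / (tau_nf * tau_f)
    return ThieleInputs(tau_d=tau_d, tau_nf=tau_nf, tau_f=tau_f, phi2=phi2)


def mean_firing_rate(rasters, n_neurons: int, duration: float) -> float:
    """Network mean firing rate: total spikes / (n_neurons * duration)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_neurons <= 0:
        raise ValueError("need at least one neuron")
    total = sum(len(r) for r in rasters)
    return total / (n_neurons * duration)


def _local_half_isi(a: np.ndarray) -> np.ndarray:
    """Per-spike coincidence half-window: min of the adjacent intervals."""
    isi = np.diff(a)
    left = isi[np.maximum(np.arange(a.size) - 1, 0)]
    right = isi[np.minimum(np.arange(a.size), isi.size - 1)]
    return np.minimum(left, right)


def _pair_sync(x: np.ndarray, y: np.ndarray) -> float:
    """Event synchronization of two sorted spike trains (adaptive window)."""
    wx = _local_half_isi(x)
    wy = _local_half_isi(y)
    d = x[:, None] - y[None, :]
    tau = 0.5 * np.minimum(wx[:, None], wy[None, :])
    # c(x|y): x-spikes shortly after y-spikes; ties count half to each side
    c_xy = np.count_nonzero((d > 0) & (d <= tau))
    c_yx = np.count_nonzero((-d > 0) & (-d <= tau))
    ties = np.count_nonzero(d == 0)
    return (c_xy + c_yx + ties) / math.sqrt(x.size * y.size)


def event_synchronization(rasters) -> float:
    """Mean pairwise event synchronization Q in [0, 1].

    Coincidences are counted within an adaptive window of half the smaller
    of the local interspike intervals; the pair value is normalized by the
    geometric mean of the spike counts, making Q symmetric, 1 for identical
    trains and 0 for trains with no quasi-coincident events.  Trains with
    fewer than two spikes carry no interval information and are excluded.
    """
    trains = [np.sort(np.asarray(r, dtype=float)) for r in rasters]
    valid = [tr for tr in trains if tr.size >= 2]
    if len(valid) < len(trains):
        logger.info("event_synchronization: excluded %d train(s) with <2 spikes",
                    len(trains) - len(valid))
    if len(valid) < 2:
        raise ValueError("need at least two trains with >= 2 spikes")
    qs = []
    for i in range(len(valid)):
        for j in range(i + 1, len(valid)):
            qs.append(_pair_sync(valid[i], valid[j]))
    return float(np.clip(np.mean(qs), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------

def compare_groups(samples: dict, design: str = "independent",
                   alpha: float = 0.05) -> dict:
    """Normality, omnibus/two-group tests and paired rank correlation.

    ``samples`` maps group name -> 1-D values.  Shapiro-Wilk runs per group
    (>= 3 values required, otherwise reported missing); two groups are
    compared with the two-sided Mann-Whitney test, three or more with
    Kruskal-Wallis.  With ``design='paired'`` and exactly two equal-length
    groups, the Spearman rank correlation is reported as well.
    """
    if not samples:
        raise ValueError("no groups supplied")
    report: dict = {"alpha": alpha, "design": design, "normality": {}}
    groups = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    for name, vals in groups.items():
        if vals.size >= 3:
            w, p = stats.shapiro(vals)
            report["normality"][name] = {
                "W": float(w), "p": float(p), "normal": bool(p >= alpha)}
        else:
            report["normality"][name] = None
    vals = list(groups.values())
    if len(vals) == 2:
        u, p = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        report["test"] = {"name": "mann-whitney", "statistic": float(u),
                          "p": float(p), "significant": bool(p < alpha)}
    elif len(vals) >= 3:
        h, p = stats.kruskal(*vals)
        report["test"] = {"name": "kruskal-wallis", "statistic": float(h),
                          "p": float(p), "significant": bool(p < alpha)}
    else:
        report["test"] = None
    if design == "paired" and len(vals) == 2 and vals[0].size == vals[1].size:
        r, p = stats.spearmanr(vals[0], vals[1])
        report["spearman"] = {"r": float(r), "p": float(p),
                              "significant": bool(p < alpha)}
    return report
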
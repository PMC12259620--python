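"""Ground-truth input generators.

Everything the platform needs to be exercised end-to-end is generated here:
the (h, c0) single-neuron sweep grid, culture-like small-world layouts at a
target edge density, and synthetic voltage traces / spike rasters whose
metrics are known in closed form from their construction parameters.  The
synthetic fixtures return that ground truth alongside the data, so the
analytics can be tested for exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimConfig
from .network import NetworkModel, from_counts

__all__ = ["SweepSpec", "SyntheticTraceSpec", "table2_sweep",
           "culture_like_network", "synthetic_trace", "poisson_rasters",
           "deprivation_pair", "NORMOXIC_C0", "DEPRIVED_C0"]

#: Boundary O2 of normally oxygenated and deprived culture medium (mol m^-3):
#: air saturation and the threshold concentration for cell survival.
NORMOXIC_C0 = 0.2
DEPRIVED_C0 = 0.04

#: Default single-neuron sweep grid: medium heights (mm) crossed with
#: boundary O2 concentrations (mol m^-3), 25 configurations.
SWEEP_H_MM = (3.0, 2.0, 1.0, 0.5, 0.1)
SWEEP_C0 = (0.2, 0.16, 0.12, 0.08, 0.04)


@dataclass
class SweepSpec:
    h_values_mm: tuple = SWEEP_H_MM
    c0_values: tuple = SWEEP_C0


@dataclass
class SyntheticTraceSpec:
    """Piecewise-linear spike-train waveform with closed-form metrics.

    Triangular spikes of given rise/fall times sit on a flat baseline at
    regular intervals; peak heights follow a linear envelope.  All metric
    ground truths (spike times, train bounds, dV_max, envelope slope, per-
    spike v_pp/rr/fr) follow from the parameters by construction.
    """

    n_spikes: int = 5
    spike_amplitude: float = 100.0     # first peak height above baseline (mV)
    baseline: float = -70.0            # mV
    isi: float = 0.1                   # s, peak-to-peak interval
    envelope_slope: float = 0.0        # mV s^-1
    rise_time: float = 1e-3            # s
    fall_time: float = 1e-3            # s
    t_first: float = 0.5               # s, onset of the first spike
    duration: float | None = None      # s; default covers the train + 0.5 s
    dt: float = 5e-5                   # s, sample interval
    noise_sd: float = 0.0              # mV
    seed: int | None = None


def table2_sweep(duration: float = 20.0,
                 h_values_mm=SWEEP_H_MM, c0_values=SWEEP_C0,
                 **overrides) -> list[SimConfig]:
    """Single-neuron configurations over the (h, c0) cross product.

    The default grid is 5 heights x 5 boundary concentrations = 25
    configurations of 20 s each.  Keyword overrides are forwarded to every
    SimConfig (e.g. dt, membrane parameters).
    """
    cfgs = []
    for h_mm in h_values_mm:
        for c0 in c0_values:
            cfgs.append(SimConfig(mode="single_neuron", h=h_mm * 1e-3, c0=c0,
                                  duration=duration, **overrides))
    return cfgs


def culture_like_network(n: int, density_target: float = 0.025,
                         p_rewire: float = 0.5, seed: int | None = None,
                         frac_excitatory: float = 0.8) -> NetworkModel:
    """Small-world layout emulating a dissociated culture on an array.

    Edge count m = round(density * n(n-1)/2) realized through the nearest
    even-degree ring lattice, rewired with probability ``p_rewire``; 80/20
    excitatory/inhibitory phenotypes.
    """
    if not 0.0 < density_target <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    m = round(density_target * n * (n - 1) / 2)
    if m < 1:
        raise ValueError(
            f"density {density_target} gives no edges for {n} vertices")
    return from_counts(n, m, p_rewire, seed, frac_excitatory)


def deprivation_pair(seed: int, n: int = 100, density: float = 0.025,
                     p_rewire: float = 0.5, duration: float = 10.0,
                     h: float = 1e-4) -> tuple[SimConfig, SimConfig]:
    """Paired normoxia / O2-deprivation network configurations.

    The same small-world layout (graph, phenotypes, initial state all set by
    ``seed``) simulated at air saturation (c0 = 0.2 mol m^-3) and at the
    survival-threshold concentration (0.04 mol m^-3).  The medium height
    defaults to 0.1 mm, the depth at which a saturated column keeps the cell
    plane oxygenated while a deprived one starves the pump -- the same
    contrast condition used for the single-neuron illustrations.  The drive
    is heterogeneous (mean 1.5, sd 1.0 uA cm^-2, seeded): roughly half the
    population is intrinsically active and the rest fire only when recruited
    synaptically, as in dissociated cultures, so both the rate and the
    synchrony of the network carry the oxygen signature.
    """
    kw = dict(mode="network", n=n, density=density, p_rewire=p_rewire,
              graph_seed=seed, phenotype_seed=seed + 100, init_seed=seed + 200,
              h=h, duration=duration, I_ext=1.5, I_ext_sd=1.0)
    return (SimConfig(c0=NORMOXIC_C0, **kw), SimConfig(c0=DEPRIVED_C0, **kw))


def synthetic_trace(spec: SyntheticTraceSpec):
    """Generate (t, v, ground_truth) for a synthetic spike train.

    ground_truth keys: spike_times (0 mV upward crossings), t_start, t_end,
    t_train, dV_max, alpha_env, AR, DR, peak_times, peak_heights, v_pp,
    rr, fr (per spike), dVpp_slope.
    """
    b = spec.baseline
    # construct on the sample grid (index arithmetic avoids float fuzz at
    # the piecewise-segment edges, keeping the ground truth exact)
    dt = spec.dt
    on_i = np.round((spec.t_first + spec.isi * np.arange(spec.n_spikes)) / dt
                    ).astype(int)
    n_rise = max(1, round(spec.rise_time / dt))
    n_fall = max(1, round(spec.fall_time / dt))
    pk_i = on_i + n_rise
    fa_i = pk_i + n_fall
    onsets = on_i * dt
    t_peaks = pk_i * dt
    t_falls = fa_i * dt
    peaks = b + spec.spike_amplitude + spec.envelope_slope * (t_peaks - t_peaks[0])
    if np.any(peaks <= 0):
        raise ValueError("peak heights must exceed the 0 mV spike threshold")
    duration = spec.duration or (t_falls[-1] + 0.5)
    nt = int(round(duration / dt)) + 1
    t = np.arange(nt) * dt
    v = np.full(nt, b)
    for k in range(spec.n_spikes):
        v[on_i[k]:pk_i[k] + 1] = b + (peaks[k] - b) * \
            np.linspace(0.0, 1.0, n_rise + 1)
        v[pk_i[k]:fa_i[k] + 1] = peaks[k] + (b - peaks[k]) * \
            np.linspace(0.0, 1.0, n_fall + 1)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        v = v + rng.normal(0.0, spec.noise_sd, size=nt)

    rise = n_rise * dt
    fall = n_fall * dt
    spike_times = onsets + rise * (0.0 - b) / (peaks - b)
    t_start = onsets[0] + rise * (-60.0 - b) / (peaks[0] - b)
    t_end = t_falls[-1]
    vpp = peaks - b
    dV_max = float(vpp.max())
    if spec.n_spikes >= 2:
        alpha_env = float(spec.envelope_slope)
        DR = alpha_env / dV_max
    else:
        alpha_env = float("nan")
        DR = float("nan")
    t_train = t_end - t_start
    gt = {
        "spike_times": spike_times,
        "t_start": float(t_start),
        "t_end": float(t_end),
        "t_train": float(t_train),
        "dV_max": dV_max,
        "alpha_env": alpha_env,
        "AR": float(np.log10(dV_max / t_train)),
        "DR": DR,
        "peak_times": t_peaks,
        "peak_heights": peaks,
        "v_pp": vpp,
        "rr": (peaks - b) / rise,
        "fr": -(peaks - b) / fall,
        "dVpp_slope": (float(spec.envelope_slope)
                       if spec.n_spikes >= 4 else float("nan")),
    }
    return t, v, gt


def poisson_rasters(n_trains: int, rate: float, duration: float,
                    sync_fraction: float = 0.0, seed: int | None = None):
    """Homogeneous Poisson spike trains with a shared-event fraction.

    Each train is the union of a common Poisson train at rate
    ``sync_fraction * rate`` (identical across trains) and an independent
    train at the residual rate, so the expected per-train rate is ``rate``
    and ground-truth synchrony grows with ``sync_fraction``.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if not 0.0 <= sync_fraction <= 1.0:
        raise ValueError("sync_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def _poisson_train(lam: float) -> np.ndarray:
        if lam <= 0:
            return np.empty(0)
        n = rng.poisson(lam * duration)
        return np.sort(rng.uniform(0.0, duration, size=n))

    common = _poisson_train(sync_fraction * rate)
    rasters = []
    for _ in range(n_trains):
        own = _poisson_train((1.0 - sync_fraction) * rate)
        rasters.append(np.sort(np.concatenate([common, own])))
    return rasters
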
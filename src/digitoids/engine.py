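"""Co-simulation of electrophysiology and oxygen transport.

The two time scales are decoupled: membrane, gating, ion and synaptic
dynamics (milliseconds and below) are integrated inside an outer window of
``outer_dt`` (default 50 ms) during which the oxygen concentration at the
cell plane is held fixed; at the end of each window the window-averaged
consumption rate R(c) = R_nf + alpha * <I_pump> is converted to a bottom
flux J = R * h and the diffusion column advanced, updating c(0, t) for the
next window.  outer_dt sits well above the firing/synaptic times and well
below the consumption/diffusion times, which is what makes the splitting
accurate.

In network mode every neuron owns an independent oxygen column (the medium
is laterally uniform, so columns only interact through the synapses); a
shared-column mode averaging R over the population is available for
sensitivity analysis.  The O2-independent comparator runs the identical
network with the pump rate pinned at rho_max and the oxygen module bypassed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._kernel import integrate_window, pack_params
from .network import NetworkModel, generate_watts_strogatz, from_counts
from .neuron import MetabolicParams, MembraneParams, gating_steady_state
from .oxygen import init_column, step_diffusion_many

__all__ = ["SimConfig", "SimResult", "run_single_neuron", "run_network",
           "run_hh_comparator", "run_sweep", "run"]

MODES = ("single_neuron", "network", "hh_comparator")


@dataclass
class SimConfig:
    """Full description of one simulation (protocol + parameters + seeds)."""

    mode: str = "single_neuron"
    h: float = 1e-3                  # medium height (m)
    c0: float = 0.2                  # boundary O2 (mol m^-3)
    D: float = 2.69e-9               # O2 diffusivity in medium (m^2 s^-1)
    duration: float = 20.0           # s
    nz: int = 51                     # O2 grid nodes
    dt: float = 5e-5                 # inner RK4 step (s)
    outer_dt: float = 0.05           # O2 coupling window (s)
    record_dt: float | None = None   # V sampling; default 1e-4 (single) / 1e-3 (net)
    I_ext: float = 2.5               # uA cm^-2 tonic drive; elicits sustained
                                     # firing when the pump is fully fuelled
    I_ext_sd: float = 0.0            # per-neuron drive heterogeneity (uA cm^-2,
                                     # seeded); >0 splits the population into
                                     # pacemakers and synaptically recruited
                                     # followers, as in dissociated cultures
    # network layout: give k, or m_edges, or density (priority in that order)
    n: int = 1
    k: int | None = None
    m_edges: int | None = None
    density: float | None = None
    p_rewire: float = 0.5
    frac_excitatory: float = 0.8
    graph_seed: int = 0
    phenotype_seed: int | None = None
    init_seed: int = 0
    init_jitter_mV: float = 2.0      # de-synchronizing jitter on V(0), network mode
    V_init: float = -67.0
    clamp_ions: bool = False
    shared_column: bool = False
    record_g: bool = False           # also record synaptic conductance traces
    metabolic: MetabolicParams = field(default_factory=MetabolicParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.outer_dt < self.dt:
            raise ValueError("outer_dt must be at least the inner step")

    def resolved_record_dt(self) -> float:
        # single-neuron traces are kept at full integrator resolution so
        # every detected spike is visible as a 0 mV crossing in the trace
        if self.record_dt is not None:
            return self.record_dt
        return self.dt if self.mode == "single_neuron" else 1e-3

    def provenance(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d


@dataclass
class SimResult:
    """Time base, traces, rasters and full provenance of one run."""

    t: np.ndarray                    # voltage time base (s)
    V: np.ndarray                    # (n_neurons, len(t)) mV
    t_c: np.ndarray                  # O2 time base (window boundaries, s)
    c_bottom: np.ndarray             # (n_neurons, len(t_c)) mol m^-3
    spikes: list                     # per-neuron arrays of spike times (s)
    provenance: dict
    network: NetworkModel | None = None
    g_traces: np.ndarray | None = None   # (n_neurons, len(t)), uS cm^-2
    R_window: np.ndarray | None = None   # (n_neurons, n_windows) consumption
                                         # rate per coupling window, mol m^-3 s^-1

    @property
    def n_neurons(self) -> int:
        return self.V.shape[0]

    @property
    def duration(self) -> float:
        return float(self.provenance["duration"])

    def spike_count(self) -> int:
        return int(sum(len(s) for s in self.spikes))

    def save(self, out_dir) -> None:
        """CSV traces + raster + JSON provenance under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vt = pd.DataFrame(self.V.T, columns=[f"V_{i}" for i in range(self.n_neurons)])
        vt.insert(0, "time_s", self.t)
        vt.to_csv(out / "voltage.csv", index=False)
        ct = pd.DataFrame(self.c_bottom.T,
                          columns=[f"c_bottom_{i}" for i in range(self.n_neurons)])
        ct.insert(0, "time_s", self.t_c)
        ct.to_csv(out / "oxygen.csv", index=False)
        rows = [(i, t) for i, st in enumerate(self.spikes) for t in st]
        pd.DataFrame(rows, columns=["neuron_id", "spike_time_s"]).to_csv(
            out / "raster.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


def _build_layout(cfg: SimConfig) -> NetworkModel:
    if cfg.k is not None:
        return generate_watts_strogatz(cfg.n, cfg.k, cfg.p_rewire, cfg.graph_seed,
                                       cfg.frac_excitatory, cfg.phenotype_seed)
    if cfg.m_edges is not None:
        m = cfg.m_edges
    elif cfg.density is not None:
        m = round(cfg.density * cfg.n * (cfg.n - 1) / 2)
    else:
        raise ValueError("network mode needs one of k, m_edges or density")
    return from_counts(cfg.n, m, cfg.p_rewire, cfg.graph_seed,
                       cfg.frac_excitatory, cfg.phenotype_seed)


def _initial_state(cfg: SimConfig, n: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(cfg.init_seed)
    jitter = cfg.init_jitter_mV if n > 1 else 0.0
    V0 = cfg.V_init + jitter * rng.uniform(-1.0, 1.0, size=n)
    Iext = np.full(n, float(cfg.I_ext))
    if cfg.I_ext_sd > 0 and n > 1:
        Iext = np.clip(rng.normal(cfg.I_ext, cfg.I_ext_sd, size=n), 0.0, None)
    Y = np.empty((7, n))
    for i in range(n):
        m, p, g = gating_steady_state(V0[i])
        Y[0, i] = V0[i]
        Y[1, i] = m
        Y[2, i] = p
        Y[3, i] = g
    Y[4, :] = cfg.membrane.Na_i_ref
    Y[5, :] = cfg.membrane.K_bath
    Y[6, :] = 0.0
    return Y, Iext


def _run(cfg: SimConfig) -> SimResult:
    mp, mb = cfg.metabolic, cfg.membrane
    comparator = cfg.mode == "hh_comparator"
    if cfg.mode == "single_neuron" or cfg.n == 1:
        n = 1
        net = None
        AT = np.zeros((1, 1))
        Esyn = np.zeros(1)
        tau = np.full(1, 4e-3)
        gbar = 0.0
    else:
        net = _build_layout(cfg)
        n = net.n
        AT = np.ascontiguousarray(net.A)   # symmetric, so A == A.T
        Esyn = net.E_syn.astype(np.float64)
        tau = net.tau_syn.astype(np.float64)
        gbar = net.g_bar

    rec_dt = cfg.resolved_record_dt()
    rec_stride = max(1, round(rec_dt / cfg.dt))
    steps_per_window = max(1, round(cfg.outer_dt / cfg.dt))
    n_windows = max(1, round(cfg.duration / cfg.outer_dt))
    recs_per_window = steps_per_window // rec_stride
    n_rec = n_windows * recs_per_window

    Y, Iext = _initial_state(cfg, n)
    pv = pack_params(mb, mp)
    Vrec = np.empty((n, n_rec))
    Grec = np.empty((n, n_rec)) if cfg.record_g else np.empty((n, 1))
    spike_cap = 256 * n
    spike_t = np.empty(spike_cap)
    spike_id = np.empty(spike_cap, dtype=np.int64)

    C = np.full((n if not cfg.shared_column else 1, cfg.nz), cfg.c0, dtype=float)
    c_bot = np.full(n, cfg.c0)
    t_c = [0.0]
    c_hist = [c_bot.copy()]
    R_hist = []
    all_spike_t: list[np.ndarray] = []
    all_spike_id: list[np.ndarray] = []

    km = mp.km
    R_max = mp.R_max
    for w in range(n_windows):
        t0 = w * cfg.outer_dt
        if comparator:
            rho = np.full(n, mp.rho_max)
        else:
            s = mp.o2_scale * mp.frac_f * c_bot
            rho = mp.rho_max / (1.0 + np.exp((mp.c_half - s) / mp.c_slope))
        nspk, ipump_mean = integrate_window(
            Y, AT, Esyn, tau, gbar, rho, Iext, pv, cfg.clamp_ions,
            cfg.dt, steps_per_window, t0, rec_stride,
            Vrec, Grec, cfg.record_g, w * recs_per_window, spike_t, spike_id)
        if nspk >= spike_cap:
            raise RuntimeError("spike buffer overflow; reduce outer_dt")
        all_spike_t.append(spike_t[:nspk].copy())
        all_spike_id.append(spike_id[:nspk].copy())
        if not np.all(np.isfinite(Y)):
            raise FloatingPointError(
                f"non-finite neuron state at t={t0 + cfg.outer_dt:.3f} s")
        if not comparator:
            c_nf = mp.frac_nf * c_bot
            R = R_max * c_nf / (km + c_nf) + mp.alpha_pump * ipump_mean
            R_hist.append(R.copy())
            if cfg.shared_column:
                J = np.array([float(np.mean(R)) * cfg.h])
            else:
                J = R * cfg.h
            C = step_diffusion_many(C, J, cfg.h, cfg.D, cfg.c0, cfg.outer_dt)
            c_bot = C[:, 0] if not cfg.shared_column else np.full(n, C[0, 0])
        t_c.append((w + 1) * cfg.outer_dt)
        c_hist.append(c_bot.copy())

    st = np.concatenate(all_spike_t) if all_spike_t else np.empty(0)
    sid = np.concatenate(all_spike_id) if all_spike_id else np.empty(0, dtype=int)
    spikes = [st[sid == i] for i in range(n)]
    t = (np.arange(n_rec) + 1) * rec_stride * cfg.dt
    return SimResult(t=t, V=Vrec, t_c=np.array(t_c),
                     c_bottom=np.array(c_hist).T, spikes=spikes,
                     provenance=cfg.provenance(), network=net,
                     g_traces=Grec if cfg.record_g else None,
                     R_window=np.array(R_hist).T if R_hist else None)


def run_single_neuron(cfg: SimConfig) -> SimResult:
    """One neuron under its oxygen column (operator-split co-simulation)."""
    if cfg.mode != "single_neuron":
        raise ValueError("config mode must be 'single_neuron'")
    return _run(cfg)


def run_network(cfg: SimConfig) -> SimResult:
    """Oxygen-coupled network: per-neuron columns + synaptic propagation."""
    if cfg.mode != "network":
        raise ValueError("config mode must be 'network'")
    return _run(cfg)


def run_hh_comparator(cfg: SimConfig) -> SimResult:
    """O2-independent comparator: identical network, pump pinned at rho_max."""
    if cfg.mode != "hh_comparator":
        raise ValueError("config mode must be 'hh_comparator'")
    return _run(cfg)


def run(cfg: SimConfig) -> SimResult:
    """Dispatch on cfg.mode."""
    return _run(cfg)


def run_sweep(cfgs: list[SimConfig]) -> pd.DataFrame:
    """Run each configuration and tabulate the train metrics per (h, c0).

    Partial failures are recorded in the ``error`` column and the sweep
    continues.  Columns: h_mm, c0, t_train, AR, DR, dV_max, alpha_env,
    n_spikes, phi2, dVpp_slope, mFR.
    """
    from .analytics import (train_metrics, thiele_modulus, spike_shapes,
                            vpp_slope, mean_firing_rate)

    rows = []
    for cfg in cfgs:
        row: dict = {"h_mm": cfg.h * 1e3, "c0": cfg.c0, "error": ""}
        try:
            res = _run(cfg)
            v = res.V[0]
            tm = train_metrics(res.t, v)
            ti = thiele_modulus(cfg.h, cfg.D, cfg.metabolic, cfg.c0)
            shapes = spike_shapes(res.t, v)
            if len(shapes) >= 4:
                dvpp = vpp_slope(np.array([s.t_max for s in shapes]),
                                 np.array([s.v_pp for s in shapes]))
            else:
                dvpp = math.nan
            row.update(
                t_train=tm.t_train, t_start=tm.t_start, t_end=tm.t_end,
                AR=tm.AR, DR=tm.DR, dV_max=tm.dV_max, alpha_env=tm.alpha_env,
                n_spikes=len(res.spikes[0]), phi2=ti.phi2, dVpp_slope=dvpp,
                mFR=mean_firing_rate(res.spikes, res.n_neurons, cfg.duration),
            )
        except Exception as exc:   # noqa: BLE001 - per-row failure is data
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
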
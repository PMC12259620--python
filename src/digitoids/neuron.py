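"""Oxygen-dependent single-neuron model.

The electrophysiology is a Hodgkin-Huxley-type conductance model whose
Na+/K+-ATPase pump is fuelled by the locally available oxygen.  Oxygen
reaching the monolayer is split 75/25 between firing-related consumption
(``c_f = 0.75 c``, feeding the pump-rate sigmoid) and basal metabolism
(``c_nf = 0.25 c``, Michaelis-Menten kinetics).  The pump in turn sets the
ion-concentration dynamics, which move the Na+/K+ Nernst potentials and so
modulate the spike-generating currents: the full coupling path is

    c(0,t) -> rho(c_f) -> I_pump -> [Na+]_i, [K+]_o -> E_Na, E_K -> I_Na, I_K -> V.

Gating kinetics, ion-conservation closures, leak conductances and the
bath-potassium exchange follow the Wei-Ullah-Schiff oxygen-seizure model
that this formulation builds on; every constant is exposed on the parameter
dataclasses.  Temperature is fixed at 37 C (Nernst prefactor 26.64 mV).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .units import mg_per_l_to_mol_m3, g_per_m3_s_to_mol_m3_s

__all__ = [
    "NeuronState",
    "MetabolicParams",
    "MembraneParams",
    "basal_consumption",
    "pump_rate",
    "pump_current",
    "firing_consumption",
    "total_consumption",
    "nernst",
    "sodium_out",
    "potassium_in",
    "membrane_currents",
    "leak_currents",
    "gating_rates",
    "gating_steady_state",
    "gating_derivatives",
    "ion_derivatives",
    "neuron_rhs",
    "resting_state",
]


@dataclass
class NeuronState:
    """Instantaneous state of one neuron.

    V in mV; m, p, n dimensionless gating fractions in [0, 1] (p is the Na+
    inactivation gate); Na_i = intracellular sodium (mM); K_o = extracellular
    potassium (mM).
    """

    V: float
    m: float
    p: float
    n: float
    Na_i: float
    K_o: float

    def validate(self) -> None:
        for name in ("m", "p", "n"):
            x = getattr(self, name)
            if not -1e-9 <= x <= 1 + 1e-9:
                raise ValueError(f"gating variable {name}={x} outside [0, 1]")
        if self.Na_i <= 0 or self.K_o <= 0:
            raise ValueError("ion concentrations must be positive")


@dataclass
class MetabolicParams:
    """Oxygen-consumption parameters (defaults from the reference table).

    sOCR : maximal O2 consumption of a single cell (g s^-1 cell^-1)
    rho_cells : volumetric cell density of the monolayer (cell m^-3)
    km_mg_l : Michaelis-Menten constant (mg L^-1)
    alpha_pump : conversion factor pump transport rate -> O2 rate (0.17)
    rho_max : maximal Na-K pump rate (mol m^-3 s^-1)
    frac_f / frac_nf : oxygen split between firing and basal metabolism
    c_half, c_slope : pump-rate sigmoid midpoint/slope, in sigmoid units
    o2_scale : mol m^-3 -> sigmoid-unit conversion applied to c_f.  The
        default 200 maps air-saturated medium (c = 0.2 mol m^-3, c_f =
        0.15) above the sigmoid midpoint, so a fully oxygenated culture
        runs its pumps near rho_max -- mirroring the parent slice model,
        where normal oxygenation saturates the pump -- while the
        hypoxia-survival threshold (c = 0.04) drives the pump to ~1% of
        rho_max.
    """

    sOCR: float = 5.28e-14
    rho_cells: float = 1.2e13
    km_mg_l: float = 9.79
    alpha_pump: float = 0.17
    rho_max: float = 1.25
    frac_f: float = 0.75
    frac_nf: float = 0.25
    c_half: float = 20.0
    c_slope: float = 3.0
    o2_scale: float = 200.0
    # pump-current sigmoid constants (Wei form)
    na_half: float = 25.0
    na_slope: float = 3.0
    k_half: float = 5.5

    def __post_init__(self) -> None:
        if abs(self.frac_f + self.frac_nf - 1.0) > 1e-12:
            raise ValueError("frac_f + frac_nf must equal 1")
        for name in ("sOCR", "rho_cells", "km_mg_l", "alpha_pump", "rho_max",
                     "c_slope", "o2_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def km(self) -> float:
        """Michaelis-Menten constant in mol m^-3."""
        return mg_per_l_to_mol_m3(self.km_mg_l)

    @property
    def R_max(self) -> float:
        """Saturated basal consumption sOCR * rho_cells, in mol m^-3 s^-1."""
        return g_per_m3_s_to_mol_m3_s(self.sOCR * self.rho_cells)


@dataclass
class MembraneParams:
    """Membrane, ion-closure and bath parameters.

    Conductances in mS cm^-2, capacitance in uF cm^-2.  gamma converts a
    membrane current density (uA cm^-2) into a rate of concentration change
    (mM s^-1); beta is the intra/extracellular volume ratio.  The reference
    concentrations close the two unmodelled ion pools by conservation:

        [K+]_i  = K_i_ref + (Na_i_ref - Na_i)
        [Na+]_o = Na_o_ref - beta * (Na_i - Na_i_ref)

    eps_bath couples extracellular potassium to the bath value K_bath
    (first-order exchange); it is what makes the neurons spontaneously
    active when K_bath is elevated, and is switched off with eps_bath = 0.
    """

    C_m: float = 1.0
    G_Na: float = 30.0
    G_K: float = 25.0
    G_Na_leak: float = 0.0175
    G_K_leak: float = 0.05
    G_Cl: float = 0.05
    E_Cl: float = 26.64 * math.log(6.0 / 130.0)   # reference Cl-: 6 in / 130 out mM
    gamma: float = 0.04445
    beta: float = 7.0
    nernst_coef: float = 26.64
    phi: float = 3.0                               # gating temperature factor
    Na_i_ref: float = 18.0
    Na_o_ref: float = 144.0
    K_i_ref: float = 140.0
    K_bath: float = 4.0
    eps_bath: float = 0.5

    def __post_init__(self) -> None:
        for name in ("C_m", "G_Na", "G_K", "G_Cl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.beta < 1:
            raise ValueError("beta (intra/extracellular volume ratio) must be >= 1")


# ---------------------------------------------------------------------------
# Metabolic operations
# ---------------------------------------------------------------------------

def basal_consumption(c_nf: float, mp: MetabolicParams) -> float:
    """Michaelis-Menten basal O2 consumption R_nf (mol m^-3 s^-1).

    R_nf = sOCR * rho_cells * c_nf / (km + c_nf); zero at zero substrate,
    saturating at R_max = sOCR * rho_cells.
    """
    if c_nf < 0:
        raise ValueError(f"concentration must be >= 0, got {c_nf}")
    return mp.R_max * c_nf / (mp.km + c_nf)


def pump_rate(c_f: float, mp: MetabolicParams) -> float:
    """Oxygen-limited maximal pump transport rate rho(c_f) (mol m^-3 s^-1).

    Sigmoid rho_max / (1 + exp((c_half - s)/c_slope)) with s = o2_scale*c_f;
    strictly increasing in c_f, saturating at rho_max.
    """
    if c_f < 0:
        raise ValueError(f"concentration must be >= 0, got {c_f}")
    s = mp.o2_scale * c_f
    return mp.rho_max / (1.0 + math.exp((mp.c_half - s) / mp.c_slope))


def pump_current(Na_i: float, K_o: float, rho: float,
                 mp: MetabolicParams | None = None) -> float:
    """Na+/K+ pump transport rate I_pump (mol m^-3 s^-1).

    I_pump = rho / (1 + exp((25 - Na_i)/3)) / (1 + exp(5.5 - K_o)):
    bounded by rho, increasing in both substrate concentrations.
    """
    if rho < 0:
        raise ValueError(f"pump rate must be >= 0, got {rho}")
    mp = mp or _DEFAULT_MP
    f_na = 1.0 / (1.0 + math.exp((mp.na_half - Na_i) / mp.na_slope))
    f_k = 1.0 / (1.0 + math.exp(mp.k_half - K_o))
    return rho * f_na * f_k


def firing_consumption(I_pump: float, mp: MetabolicParams) -> float:
    """Firing-related O2 consumption R_f = alpha * I_pump (mol m^-3 s^-1)."""
    if I_pump < 0:
        raise ValueError(f"pump current must be >= 0, got {I_pump}")
    return mp.alpha_pump * I_pump


def total_consumption(c: float, state: NeuronState, mp: MetabolicParams) -> float:
    """Total O2 consumption R(c) = R_nf(0.25 c) + R_f(c_f-limited pump)."""
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    rho = pump_rate(mp.frac_f * c, mp)
    ip = pump_current(state.Na_i, state.K_o, rho, mp)
    return basal_consumption(mp.frac_nf * c, mp) + firing_consumption(ip, mp)


# ---------------------------------------------------------------------------
# Electrophysiology
# ---------------------------------------------------------------------------

_DEFAULT_MP = MetabolicParams()


def nernst(conc_out: float, conc_in: float, coef: float = 26.64) -> float:
    """Nernst (reversal) potential coef * ln(out/in), mV."""
    if conc_out <= 0 or conc_in <= 0:
        raise ValueError("concentrations must be positive for a Nernst potential")
    return coef * math.log(conc_out / conc_in)


def sodium_out(Na_i: float, mb: MembraneParams) -> float:
    """Extracellular sodium from conservation across the two compartments."""
    return mb.Na_o_ref - mb.beta * (Na_i - mb.Na_i_ref)


def potassium_in(Na_i: float, mb: MembraneParams) -> float:
    """Intracellular potassium from electroneutral exchange with sodium."""
    return mb.K_i_ref + (mb.Na_i_ref - Na_i)


def gating_rates(V: float) -> tuple[float, float, float, float, float, float]:
    """Voltage-dependent opening/closing rates (ms^-1).

    Returns (alpha_m, beta_m, alpha_p, beta_p, alpha_n, beta_n) for the Na+
    activation (m), Na+ inactivation (p) and K+ activation (n) gates.
    """
    if abs(V + 30.0) < 1e-9:
        a_m = 1.0  # removable singularity: lim x/(1-exp(-x/10))*0.1 at x->0
    else:
        a_m = 0.1 * (V + 30.0) / (1.0 - math.exp(-0.1 * (V + 30.0)))
    b_m = 4.0 * math.exp(-(V + 55.0) / 18.0)
    a_p = 0.07 * math.exp(-(V + 44.0) / 20.0)
    b_p = 1.0 / (1.0 + math.exp(-0.1 * (V + 14.0)))
    if abs(V + 34.0) < 1e-9:
        a_n = 0.1
    else:
        a_n = 0.01 * (V + 34.0) / (1.0 - math.exp(-0.1 * (V + 34.0)))
    b_n = 0.125 * math.exp(-(V + 44.0) / 80.0)
    return a_m, b_m, a_p, b_p, a_n, b_n


def gating_steady_state(V: float) -> tuple[float, float, float]:
    """Fixed points alpha/(alpha+beta) of the three gates at voltage V."""
    a_m, b_m, a_p, b_p, a_n, b_n = gating_rates(V)
    return a_m / (a_m + b_m), a_p / (a_p + b_p), a_n / (a_n + b_n)


def gating_derivatives(state: NeuronState,
                       mb: MembraneParams | None = None) -> tuple[float, float, float]:
    """First-order gate kinetics dx/dt = phi_x (alpha(1-x) - beta x), in s^-1.

    The temperature factor phi applies to the slow gates p and n; the fast
    activation gate m follows its bare rates.  Rates are per-ms, so the
    result is scaled by 1000 to the per-second base used everywhere else.
    """
    mb = mb or MembraneParams()
    a_m, b_m, a_p, b_p, a_n, b_n = gating_rates(state.V)
    dm = a_m * (1.0 - state.m) - b_m * state.m
    dp = mb.phi * (a_p * (1.0 - state.p) - b_p * state.p)
    dn = mb.phi * (a_n * (1.0 - state.n) - b_n * state.n)
    return 1e3 * dm, 1e3 * dp, 1e3 * dn


def membrane_currents(state: NeuronState,
                      mb: MembraneParams) -> tuple[float, float, float]:
    """Voltage-gated Na+/K+ currents and the Cl- leak (uA cm^-2).

    I_Na = G_Na m^3 p (V - E_Na); I_K = G_K n^4 (V - E_K);
    I_Cl = G_Cl (V - E_Cl), with E_Na, E_K recomputed from the current ion
    concentrations (this is where oxygen reaches the spike generator).
    """
    E_Na = nernst(sodium_out(state.Na_i, mb), state.Na_i, mb.nernst_coef)
    E_K = nernst(state.K_o, potassium_in(state.Na_i, mb), mb.nernst_coef)
    I_Na = mb.G_Na * state.m**3 * state.p * (state.V - E_Na)
    I_K = mb.G_K * state.n**4 * (state.V - E_K)
    I_Cl = mb.G_Cl * (state.V - mb.E_Cl)
    return I_Na, I_K, I_Cl


def leak_currents(state: NeuronState,
                  mb: MembraneParams) -> tuple[float, float]:
    """Non-voltage-sensitive Na+ and K+ leaks (uA cm^-2)."""
    E_Na = nernst(sodium_out(state.Na_i, mb), state.Na_i, mb.nernst_coef)
    E_K = nernst(state.K_o, potassium_in(state.Na_i, mb), mb.nernst_coef)
    return mb.G_Na_leak * (state.V - E_Na), mb.G_K_leak * (state.V - E_K)


def ion_derivatives(state: NeuronState, I_K: float, I_Na: float, I_pump: float,
                    mb: MembraneParams) -> tuple[float, float]:
    """Extracellular K+ and intracellular Na+ dynamics (mM s^-1).

    d[K+]_o/dt  = gamma beta I_K - 2 beta I_pump + eps_bath (K_bath - K_o)
    d[Na+]_i/dt = -gamma I_Na - 3 I_pump

    The 3:2 stoichiometry is the pump's ion exchange per cycle; the bath
    term is the optional first-order exchange with the bulk medium.
    """
    dKo = mb.gamma * mb.beta * I_K - 2.0 * mb.beta * I_pump \
        + mb.eps_bath * (mb.K_bath - state.K_o)
    dNai = -mb.gamma * I_Na - 3.0 * I_pump
    return dKo, dNai


def neuron_rhs(state: NeuronState, c_local: float, I_syn: float, I_ext: float,
               mp: MetabolicParams, mb: MembraneParams,
               clamp_ions: bool = False,
               rho_override: float | None = None):
    """Full state derivative (dV, dm, dp, dn, dNa_i, dK_o).

    Assembles the membrane equation dV/dt = (I_ext - I_Na - I_K - I_Cl +
    I_syn)/C with gating and ion dynamics; E_Na/E_K are recomputed from the
    instantaneous ion concentrations on every evaluation.  ``rho_override``
    bypasses the oxygen dependence (the O2-independent comparator runs with
    rho fixed at rho_max); ``clamp_ions`` freezes Na_i and K_o.
    """
    rho = pump_rate(mp.frac_f * c_local, mp) if rho_override is None else rho_override
    ip = pump_current(state.Na_i, state.K_o, rho, mp)
    I_Na, I_K, I_Cl = membrane_currents(state, mb)
    I_Na_l, I_K_l = leak_currents(state, mb)
    I_Na_tot = I_Na + I_Na_l
    I_K_tot = I_K + I_K_l
    # uA/cm2 over uF/cm2 is mV/ms; scale to the per-second time base
    dV = 1e3 * (I_ext - I_Na_tot - I_K_tot - I_Cl + I_syn) / mb.C_m
    dm, dp, dn = gating_derivatives(state, mb)
    if clamp_ions:
        dKo = dNai = 0.0
    else:
        dKo, dNai = ion_derivatives(state, I_K_tot, I_Na_tot, ip, mb)
    if not (math.isfinite(dV) and math.isfinite(dNai) and math.isfinite(dKo)):
        raise FloatingPointError(f"non-finite derivative at state {state}")
    return dV, dm, dp, dn, dNai, dKo


def resting_state(V: float = -67.0, Na_i: float | None = None,
                  K_o: float | None = None,
                  mb: MembraneParams | None = None) -> NeuronState:
    """A neuron at voltage V with gates at their steady state for that V.

    Na_i defaults to the conservation reference, K_o to the bath value.
    """
    mb = mb or MembraneParams()
    m, p, n = gating_steady_state(V)
    return NeuronState(V=V, m=m, p=p, n=n,
                       Na_i=mb.Na_i_ref if Na_i is None else Na_i,
                       K_o=mb.K_bath if K_o is None else K_o)
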
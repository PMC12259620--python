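# Methods

## Scope and model structure

`digitoids` simulates neuronal monolayers in which electrophysiology is
energetically coupled to oxygen. The model has four interacting parts:
one-dimensional oxygen diffusion through the medium column, oxygen
consumption (basal + firing-related), conductance-based membrane dynamics
with explicit Na⁺/K⁺ pump and ion-concentration dynamics, and chemical
synapses on small-world layouts. Lateral (x–y) diffusion is neglected: its
characteristic time is orders of magnitude longer than axial transport, so
each neuron owns an independent medium column (a shared-column mode exists
for sensitivity analysis).

## Time-scale decoupling

Membrane, gating, ionic and synaptic dynamics live on 10⁻⁴–10⁻² s; oxygen
consumption and axial diffusion on 10⁰–10³ s. The engine therefore
operator-splits: within an outer window of `outer_dt` (default 50 ms) the
neuron ODEs are integrated with the bottom oxygen concentration held fixed;
the window-averaged consumption rate R = R_nf(0.25c) + α·⟨I_pump⟩ is then
converted to a bottom flux J = R·h and the diffusion column advanced.
Halving `outer_dt` changes spike counts by at most one and the oxygen trace
by <1% (tested), confirming the splitting is converged at the default.

## Numerical scheme

The neuron/synapse system is integrated with fixed-step classical RK4 at
`dt` = 50 µs inside a numba-compiled kernel. At this step the fastest mode
(the Na⁺ activation gate, τ ≈ 0.1 ms) is resolved with λ·dt ≈ 0.3, well
inside RK4's stability and accuracy range; an independent adaptive
integration (scipy `solve_ivp` at rtol 10⁻¹⁰ over the pure-Python right-hand
side) reproduces the kernel's spike times to <0.5 ms over a 0.25 s window
(tested). A fixed-step kernel was chosen over an adaptive stiff solver with
event location because synaptic updates fire at every presynaptic spike:
event-located restarts of a ~700-dimensional adaptive solve are prohibitively
slow for 100-neuron, multi-second runs on one CPU, while the fixed step makes
runs strictly deterministic and fast. Spikes are upward crossings of 0 mV
detected on step boundaries; the crossing time is linearly interpolated and
the presynaptic conductance increment is applied at the end of the crossing
step (a delay of at most `dt`, three orders of magnitude below τ_syn).
Between increments conductances decay exactly exponentially.

Oxygen diffusion uses second-order central differences (51 nodes by default)
with a ghost-node Neumann flux at the cell plane and a Dirichlet top
boundary, advanced by unconditionally stable backward Euler. The ghost-node
form makes the discrete steady state match the analytic linear profile
c₀ − (J/D)(h − z) to machine precision, and the implicit M-matrix update
preserves 0 ≤ c ≤ c₀; concentrations are clipped at zero (with a warning)
if a window's fixed flux overdraws a nearly exhausted column.

## Closures and parameter defaults

The printed model leaves several pieces to its cited conductance-model
ancestry (the Wei–Ullah–Schiff oxygen–seizure model); those forms are
adopted and exposed as parameters:

- **Gating kinetics** — standard voltage-dependent first-order kinetics for
  m (Na⁺ activation), p (Na⁺ inactivation) and n (K⁺ activation), with a
  temperature factor φ = 3 on the slow gates.
- **Ion closures** — [K⁺]ᵢ = K_i_ref + (Na_i_ref − Na_i) and
  [Na⁺]ₒ = Na_o_ref − β(Na_i − Na_i_ref), with references 140 / 18 / 144 mM
  and volume ratio β = 7.
- **Leaks** — Cl⁻ leak G_Cl = 0.05 mS cm⁻² with E_Cl from reference Cl⁻
  concentrations (6/130 mM, ≈ −82 mV), plus non-voltage-sensitive Na⁺/K⁺
  leaks (0.0175 / 0.05 mS cm⁻²). The voltage-gated currents are reported
  separately from the leaks; the right-hand side sums both, and the ion
  dynamics use the total Na⁺/K⁺ currents.
- **Bath exchange** — first-order coupling ε(K_bath − [K⁺]ₒ) with
  K_bath = 4 mM (physiological) and ε = 0.5 s⁻¹. Setting ε = 0 disables it.

Metabolic and membrane constants default to the reference parameter table:
D = 2.69·10⁻⁹ m² s⁻¹, sOCR = 5.28·10⁻¹⁴ g s⁻¹ cell⁻¹, ρ_cells = 1.2·10¹³
cell m⁻³, k_m = 9.79 mg L⁻¹, α = 0.17, γ = 0.04445 (mM/s)/(µA/cm²), β = 7,
ρ_max = 1.25 mol m⁻³ s⁻¹, C = 1 µF cm⁻², G_Na = 30 and G_K = 25 mS cm⁻²,
E_syn = 0/−80 mV, τ_syn = 4/8 ms, ḡ_syn = 0.5. The canonical internal oxygen
unit is mol m⁻³ (≡ mM); mg L⁻¹ quantities are converted with the molar mass
32 g mol⁻¹.

**Pump-sigmoid scale.** The pump-rate sigmoid's midpoint (20) and slope (3)
are given in the unit system of the parent slice model, where normal
oxygenation corresponds to ≈30 such units and runs the pump near ρ_max.
Culture saturation here is c₀ = 0.2 mol m⁻³ (c_f = 0.15), so a conversion
`o2_scale` maps c_f into sigmoid units. The default 200 reproduces the
parent model's operating point: saturated medium → ρ ≈ 0.97 ρ_max, the
survival threshold c₀ = 0.04 → ρ ≈ 0.01 ρ_max, and the sweep's c₀ range
spans the whole sigmoid. (A half-activation placement was evaluated and
rejected: it caps the pump at ~16% of ρ_max even in saturated medium, which
decouples oxygen from firing and inverts the comparator ordering.)

**Drive.** Neurons receive a constant external drive I_ext (default
2.5 µA cm⁻², above the ≈1–1.5 µA cm⁻² rheobase at rest). With the closure
above, bath-potassium elevation alone turned out to be an unreliable source
of spontaneous activity — near the firing threshold the pump's net effect is
hyperpolarizing, so a fully fuelled pump *suppresses* marginally driven
cells, the opposite of the intended comparator behaviour. A suprathreshold
tonic drive recovers the intended phenomenology: with the pump pinned at
ρ_max firing is sustained indefinitely, while the oxygen-limited pump lets
ionic gradients run down and the train terminates. For network experiments
the drive can be made heterogeneous (`I_ext_sd`; the deprivation protocol
uses mean 1.5, sd 1.0 µA cm⁻², seeded), splitting the population into
intrinsic pacemakers and synaptically recruited followers as in dissociated
cultures — this is what gives event synchronization a genuine, synaptically
mediated component that oxygen deprivation can degrade.

**Initial conditions.** V = −67 mV (gates at their steady state for that
voltage, ±2 mV seeded jitter across a network), Na_i at its reference,
K_o at the bath value. All seeds are recorded in the result provenance.

## Protocols

- **Single-neuron sweep** — the 5×5 cross product of h ∈ {3, 2, 1, 0.5,
  0.1} mm and c₀ ∈ {0.2, 0.16, 0.12, 0.08, 0.04} mol m⁻³, 20 s each.
- **Deprivation experiment** — six seeded 100-neuron layouts at 2.5% edge
  density (p_rewire = 0.5, 80/20 phenotypes), each run at c₀ = 0.2 and
  0.04 mol m⁻³ under 0.1 mm of medium for 10 s. 0.1 mm is the depth at which
  a saturated column keeps the cell plane oxygenated while a deprived one
  starves the pump; under millimetres of medium both conditions go anoxic
  within seconds and the contrast collapses. 10 s (rather than 20 s) keeps
  the full test suite fast; the effect sizes are unchanged.
- **Comparator** — the identical layout and seeds rerun with ρ ≡ ρ_max and
  the oxygen module bypassed.

## Train-metric conventions

t_start is the first time the signal exceeds −60 mV; because the model's
depolarized inter-spike baseline sits near −57 mV, this marks the onset of
the initial depolarization rather than the first spike — applied uniformly
across configurations it preserves all orderings. t_end operationalizes
"first derivative equal to zero" as |dV/dt| < 1 mV s⁻¹ sustained for 50 ms
after the last spike (exact zeros do not exist on sampled data; both numbers
are configurable). ΔV_max is the peak-to-peak amplitude of the spike with
the highest peak; the envelope derivative α_env is the mean of
finite-difference slopes between consecutive spike peaks. The Thiele
characteristic times are τ_d = h²/D, τ_nf = k_m/R_max and
τ_f = c₀/(α·ρ_max) — stated openly as this package's convention, since only
the combined Φ² formula is fixed by the model definition. Event
synchronization uses the widely adopted adaptive-coincidence-window measure
(window = half the smaller local interspike interval, normalized by the
geometric mean of spike counts); trains with fewer than two spikes carry no
interval information and are excluded.

## What the synthetic fixtures do and do not show

The fixture generators produce (i) piecewise-linear spike trains whose
metrics are known in closed form — recovery tests on them verify the
analytics implementations exactly, but say nothing about detection on noisy,
drifting experimental traces; (ii) Poisson rasters with a controllable
shared-event fraction — these validate the synchronization measure's limits
(1 for identical, ~baseline for independent trains), not its behaviour on
bursty biological rasters; (iii) Watts–Strogatz layouts parameterized by
edge density, emulating the connectivity statistics of cultured networks but
not their spatial embedding or electrode geometry.

## Known limitations

Oxygen is the only metabolite; there is no ATP pool, astrocytic buffering,
synaptic oxygen demand, plasticity, conduction delay, temperature
dependence, or 3-D geometry. The pump-sigmoid unit mapping, the bath/drive
configuration and the supplementary-model closures are this package's
documented choices where the model definition is silent; all are exposed as
parameters. Quantitative agreement with any particular recorded culture
requires tuning the metabolic and drive parameters to that preparation —
the package's tests establish directional and limiting behaviour, not
patch-clamp-level quantitative fidelity.
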
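"""Small-world network layouts and chemical-synapse dynamics.

Cultured neuronal monolayers wire up into small-world graphs: clustering
far above a degree-matched random graph with comparable path lengths.
Layouts are generated with the Watts-Strogatz construction (ring lattice of
mean degree k, each edge rewired with probability p); each undirected edge
{i, j} carries a synapse in both directions, with the reversal potential and
decay constant of the presynaptic neuron's phenotype: excitatory synapses
(80% of neurons) reverse at 0 mV with tau = 4 ms, inhibitory at -80 mV with
tau = 8 ms.  Between presynaptic spikes every conductance decays
exponentially, dg/dt = -g/tau; each presynaptic spike increments the
neuron's outgoing conductance by g_bar = 0.5 uS cm^-2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkModel",
    "SynapseState",
    "GraphMetrics",
    "generate_watts_strogatz",
    "from_counts",
    "assign_phenotypes",
    "build_network",
    "on_presynaptic_spike",
    "decay_synapses",
    "synaptic_current",
    "graph_metrics",
]

E_SYN_EXCITATORY = 0.0       # mV
E_SYN_INHIBITORY = -80.0     # mV
TAU_SYN_EXCITATORY = 4e-3    # s
TAU_SYN_INHIBITORY = 8e-3    # s
G_BAR_DEFAULT = 0.5          # uS cm^-2


@dataclass
class NetworkModel:
    """Adjacency, phenotypes and per-vertex synapse parameters.

    ``A[i, j] == 1`` means an edge between vertices i and j (symmetric,
    zero diagonal); each edge acts as a synapse in both directions driven
    by the presynaptic vertex's phenotype.
    """

    n: int
    A: np.ndarray
    excitatory: np.ndarray          # bool per vertex
    E_syn: np.ndarray               # mV, per presynaptic vertex
    tau_syn: np.ndarray             # s, per presynaptic vertex
    g_bar: float = G_BAR_DEFAULT

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2

    @property
    def density(self) -> float:
        return 2.0 * self.n_edges / (self.n * (self.n - 1))

    def validate(self) -> None:
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency matrix has self-loops")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency matrix must be symmetric")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")


@dataclass
class SynapseState:
    """Per-presynaptic-vertex conductance and last spike time."""

    g: np.ndarray
    t_last_spike: np.ndarray

    @classmethod
    def zeros(cls, n: int) -> "SynapseState":
        return cls(g=np.zeros(n), t_last_spike=np.full(n, -np.inf))


@dataclass
class GraphMetrics:
    clustering: float
    path_length: float
    density: float
    small_worldness: float


def assign_phenotypes(n: int, frac_excitatory: float = 0.8,
                      seed: int | None = None) -> np.ndarray:
    """Boolean excitatory mask with exactly round(frac * n) True entries.

    Round-half-up on the excitatory count; placement shuffled under seed.
    """
    if not 0.0 <= frac_excitatory <= 1.0:
        raise ValueError("frac_excitatory must lie in [0, 1]")
    n_exc = int(np.floor(frac_excitatory * n + 0.5))
    mask = np.zeros(n, dtype=bool)
    mask[:n_exc] = True
    rng = np.random.default_rng(seed)
    rng.shuffle(mask)
    return mask


def build_network(A: np.ndarray, excitatory: np.ndarray,
                  g_bar: float = G_BAR_DEFAULT) -> NetworkModel:
    """Assemble a NetworkModel, deriving E_syn/tau_syn from the phenotypes."""
    n = A.shape[0]
    E_syn = np.where(excitatory, E_SYN_EXCITATORY, E_SYN_INHIBITORY)
    tau_syn = np.where(excitatory, TAU_SYN_EXCITATORY, TAU_SYN_INHIBITORY)
    net = NetworkModel(n=n, A=A.astype(np.float64), excitatory=excitatory,
                       E_syn=E_syn, tau_syn=tau_syn, g_bar=g_bar)
    net.validate()
    return net


def generate_watts_strogatz(n: int, k: int, p_rewire: float, seed: int | None = None,
                            frac_excitatory: float = 0.8,
                            phenotype_seed: int | None = None) -> NetworkModel:
    """Watts-Strogatz small-world layout with phenotype assignment.

    Ring lattice of n vertices each linked to its k nearest neighbours
    (k even), then each edge rewired with probability ``p_rewire`` avoiding
    self-loops and duplicates; the edge count n*k/2 is preserved.
    """
    if k % 2 != 0:
        raise ValueError(f"mean degree k must be even, got {k}")
    if not 2 <= k < n:
        raise ValueError(f"need n > k >= 2, got n={n}, k={k}")
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError("rewiring probability must lie in [0, 1]")
    G = nx.watts_strogatz_graph(n, k, p_rewire, seed=seed)
    A = nx.to_numpy_array(G, dtype=np.float64)
    if phenotype_seed is None:
        phenotype_seed = None if seed is None else seed + 1
    exc = assign_phenotypes(n, frac_excitatory, phenotype_seed)
    return build_network(A, exc)


def from_counts(n_vertices: int, n_edges: int, p_rewire: float = 0.5,
                seed: int | None = None, frac_excitatory: float = 0.8,
                phenotype_seed: int | None = None) -> NetworkModel:
    """Layout from (vertex count, edge count), as digitalized cultures are.

    The nearest even mean degree k = round(2m/n) is used, so the achieved
    edge count is n*k/2 (within one ring-lattice row of the request); it is
    logged when it differs from the request.
    """
    max_edges = n_vertices * (n_vertices - 1) // 2
    if not 0 < n_edges <= max_edges:
        raise ValueError(
            f"{n_edges} edges infeasible for {n_vertices} vertices "
            f"(max {max_edges})")
    k = 2 * max(1, round(n_edges / n_vertices))
    if k >= n_vertices:
        k = n_vertices - 1 if (n_vertices - 1) % 2 == 0 else n_vertices - 2
    achieved = n_vertices * k // 2
    if achieved != n_edges:
        logger.info("from_counts: requested %d edges, ring lattice k=%d gives %d",
                    n_edges, k, achieved)
    return generate_watts_strogatz(n_vertices, k, p_rewire, seed,
                                   frac_excitatory, phenotype_seed)


# ---------------------------------------------------------------------------
# Synapse dynamics (event-driven form; the engine kernel integrates the
# same equations inline)
# ---------------------------------------------------------------------------

def on_presynaptic_spike(syn: SynapseState, j: int, t0: float,
                         g_bar: float = G_BAR_DEFAULT) -> SynapseState:
    """Presynaptic spike of vertex j at time t0: g_j -> g_j + g_bar."""
    syn.g[j] += g_bar
    syn.t_last_spike[j] = t0
    return syn


def decay_synapses(syn: SynapseState, net: NetworkModel, dt: float) -> SynapseState:
    """Exact exponential decay g(t + dt) = g(t) exp(-dt / tau_syn)."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    syn.g *= np.exp(-dt / net.tau_syn)
    return syn


def synaptic_current(V_i: float, syn: SynapseState, net: NetworkModel,
                     i: int) -> float:
    """Total synaptic current onto postsynaptic neuron i (uA cm^-2).

    I_syn_i = sum_j g_j a_ij (E_syn_j - V_i): excitatory inputs drive V
    toward 0 mV, inhibitory toward -80 mV.
    """
    a = net.A[:, i]
    return float(np.sum(syn.g * a * (net.E_syn - V_i)))


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------

def _mean_shortest_path(G: nx.Graph) -> float:
    """Characteristic path length averaged over reachable pairs only."""
    total = 0.0
    count = 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for target, d in dists.items():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        return float("nan")
    return total / count


def graph_metrics(net: NetworkModel, n_random: int = 5,
                  seed: int | None = 0, n_swap_factor: int = 10) -> GraphMetrics:
    """Clustering, characteristic path length, density and small-worldness.

    The small-worldness index sigma = (C/C_rand) / (L/L_rand) uses a seeded
    ensemble of ``n_random`` degree-matched references obtained by double
    edge swaps.  Path lengths average over reachable pairs, so disconnected
    graphs (possible after rewiring) are handled gracefully.
    """
    if net.n == 0 or net.n_edges == 0:
        raise ValueError("graph metrics undefined for an empty graph")
    G = nx.from_numpy_array(net.A)
    C = nx.average_clustering(G)
    L = _mean_shortest_path(G)
    density = net.density

    rng = np.random.default_rng(seed)
    c_rand = []
    l_rand = []
    m = net.n_edges
    for _ in range(n_random):
        R = G.copy()
        try:
            nx.double_edge_swap(R, nswap=n_swap_factor * m,
                                max_tries=100 * n_swap_factor * m,
                                seed=int(rng.integers(2**31 - 1)))
        except nx.NetworkXException:
            pass  # too few swappable edges; use the partial randomization
        c_rand.append(nx.average_clustering(R))
        l_rand.append(_mean_shortest_path(R))
    C_rand = float(np.mean(c_rand))
    L_rand = float(np.mean(l_rand))
    if C_rand <= 0.0:
        # sparse-reference fallback: expected clustering of a random graph
        C_rand = max(density, 1.0 / (net.n * (net.n - 1)))
    sigma = (C / C_rand) / (L / L_rand) if L > 0 and L_rand > 0 else float("nan")
    return GraphMetrics(clustering=C, path_length=L, density=density,
                        small_worldness=sigma)
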
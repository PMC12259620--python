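"""One-dimensional oxygen transport through the culture-medium column.

Oxygen diffuses from the air-medium interface (a Dirichlet boundary held at
the saturation concentration ``c0``) down to the cell monolayer at ``z = 0``,
where the cells remove it as a surface reaction.  Fick's second law

    dc/dt = D d2c/dz2

is discretized with second-order central differences on a uniform grid and
advanced with an unconditionally stable implicit (backward-Euler) step.  The
consumption enters as a Neumann condition at the bottom,
``D dc/dz|_0 = J`` (outward sink flux, mol m^-2 s^-1), imposed through a
ghost node so the discrete steady state reproduces the analytic linear
profile ``c(z) = c0 - (J/D)(h - z)`` exactly.

Volumetric consumption rates (mol m^-3 s^-1, referenced to the medium column
over the monolayer) are converted to the equivalent bottom flux with
:func:`consumption_to_flux`, ``J = R * h``, so that total consumption equals
the rate times the column volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "OxygenColumn",
    "init_column",
    "consumption_to_flux",
    "step_diffusion",
    "bottom_concentration",
    "steady_profile",
]


@dataclass
class OxygenColumn:
    """Discretized axial O2 concentration profile over the medium column.

    Attributes
    ----------
    h : float
        Medium height (m).
    nz : int
        Number of grid nodes.
    z : ndarray
        Node positions (m), ascending, ``z[0] = 0``, ``z[-1] = h``.
    c : ndarray
        O2 concentration per node (mol m^-3).
    D : float
        Diffusion constant of O2 in the medium (m^2 s^-1).
    c0 : float
        Boundary/initial concentration (mol m^-3); pinned at the top node.
    """

    h: float
    nz: int
    z: np.ndarray
    c: np.ndarray
    D: float
    c0: float
    # cached implicit-step factorization, keyed by dt
    _banded_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def dz(self) -> float:
        return self.h / (self.nz - 1)


def init_column(h: float, c0: float, D: float, nz: int = 51) -> OxygenColumn:
    """Create a column uniformly filled with O2-saturated medium.

    The initial condition is ``c(z, 0) = c0`` everywhere: the well starts
    filled with saturated medium.

    Parameters
    ----------
    h : float
        Medium height (m), > 0.
    c0 : float
        Saturation / boundary concentration (mol m^-3), >= 0.
    D : float
        Diffusivity (m^2 s^-1), > 0.
    nz : int
        Grid nodes, >= 3.
    """
    if h <= 0:
        raise ValueError(f"medium height must be positive, got {h}")
    if D <= 0:
        raise ValueError(f"diffusivity must be positive, got {D}")
    if c0 < 0:
        raise ValueError(f"boundary concentration must be >= 0, got {c0}")
    if nz < 3:
        raise ValueError(f"need at least 3 grid nodes, got {nz}")
    z = np.linspace(0.0, h, nz)
    c = np.full(nz, float(c0))
    return OxygenColumn(h=float(h), nz=int(nz), z=z, c=c, D=float(D), c0=float(c0))


def consumption_to_flux(R: float, h: float) -> float:
    """Convert a column-volumetric consumption rate to a bottom surface flux.

    ``J = R * h`` (mol m^-2 s^-1): the monolayer's volumetric rate R
    (mol m^-3 s^-1, referenced to the medium column above it) removed
    through the unit bottom area.
    """
    if R < 0:
        raise ValueError(f"consumption rate must be >= 0, got {R}")
    return R * h


def _banded_matrix(col: OxygenColumn, dt: float) -> np.ndarray:
    """Backward-Euler system matrix in LAPACK banded storage.

    Unknowns are nodes 0..nz-2 (the top node is Dirichlet).  Node 0 uses a
    ghost node carrying the Neumann flux; its J contribution sits in the
    right-hand side.
    """
    n = col.nz - 1
    r = col.D * dt / col.dz**2
    ab = np.zeros((3, n))
    ab[1, :] = 1.0 + 2.0 * r
    ab[0, 1:] = -r          # superdiagonal
    ab[2, :-1] = -r         # subdiagonal
    ab[0, 1] = -2.0 * r     # ghost-node bottom row: coefficient of c1
    return ab


def step_diffusion(col: OxygenColumn, J_bottom: float, dt: float) -> OxygenColumn:
    """Advance the profile by ``dt`` under Fick's law with a bottom sink.

    Implicit (backward-Euler) step; unconditionally stable for any ``dt``.
    The top node stays pinned at ``c0``; concentrations are clipped at zero
    (oxygen cannot go negative; Michaelis-Menten kinetics make zero an
    absorbing floor anyway) with a warning when clipping occurs.

    The column is updated in place and returned.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if J_bottom < 0:
        raise ValueError(f"bottom flux must be >= 0 (consumption only), got {J_bottom}")

    key = float(dt)
    if key not in col._banded_cache:
        col._banded_cache[key] = _banded_matrix(col, dt)
    ab = col._banded_cache[key]

    n = col.nz - 1
    r = col.D * dt / col.dz**2
    b = col.c[:n].copy()
    b[0] -= 2.0 * J_bottom * dt / col.dz       # ghost-node flux term
    b[-1] += r * col.c0                         # known Dirichlet neighbor
    sol = solve_banded((1, 1), ab, b)
    if not np.all(np.isfinite(sol)):
        raise FloatingPointError("non-finite oxygen profile after diffusion step")
    if np.any(sol < 0):
        neg = sol.min()
        if neg < -1e-9 * max(col.c0, 1.0):
            warnings.warn(
                f"oxygen profile clipped at 0 (min {neg:.3e} mol m^-3); "
                "the imposed sink exceeded the available oxygen",
                stacklevel=2,
            )
        sol = np.clip(sol, 0.0, None)
    col.c[:n] = sol
    col.c[-1] = col.c0
    return col


def bottom_concentration(col: OxygenColumn) -> float:
    """O2 concentration perceived by the cells at ``z = 0``."""
    return float(col.c[0])


def steady_profile(col: OxygenColumn, J_bottom: float) -> np.ndarray:
    """Analytic steady state ``c0 - (J/D)(h - z)`` (clipped at zero).

    Reference solution for a constant bottom flux; used for validation.
    """
    return np.clip(col.c0 - (J_bottom / col.D) * (col.h - col.z), 0.0, None)


def step_diffusion_many(
    C: np.ndarray,
    J_bottom: np.ndarray,
    h: float,
    D: float,
    c0: float,
    dt: float,
) -> np.ndarray:
    """Advance many independent columns sharing (h, D, c0, dt) at once.

    ``C`` has shape (n_columns, nz); ``J_bottom`` shape (n_columns,).
    Same scheme as :func:`step_diffusion`, vectorized over the right-hand
    sides of one banded solve.  In-plane (x-y) independence of the medium
    means each neuron's column evolves independently; they only share the
    discretization.
    """
    ncol, nz = C.shape
    dz = h / (nz - 1)
    r = D * dt / dz**2
    n = nz - 1
    ab = np.zeros((3, n))
    ab[1, :] = 1.0 + 2.0 * r
    ab[0, 1:] = -r
    ab[2, :-1] = -r
    ab[0, 1] = -2.0 * r
    b = C[:, :n].T.copy()
    b[0, :] -= 2.0 * np.asarray(J_bottom) * dt / dz
    b[-1, :] += r * c0
    sol = solve_banded((1, 1), ab, b)
    sol = np.clip(sol, 0.0, None)
    out = C.copy()
    out[:, :n] = sol.T
    out[:, -1] = c0
    return out
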
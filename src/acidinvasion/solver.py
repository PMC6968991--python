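"""Method-of-lines discretisation and stiff time integration.

Space is discretised on an equi-spaced grid with the conservative central
difference for a variable diffusion coefficient,

    d/dx (D du/dx)|_r ~ [ (D_{r-1}+D_r) u_{r-1}
                          - (D_{r-1}+2 D_r+D_{r+1}) u_r
                          + (D_r+D_{r+1}) u_{r+1} ] / (2 h^2),

with D = 1 - M for the two tumour fields (matrix obstruction), D = 1 for
acid, and no transport at all for stroma and matrix. Zero-flux boundaries
are enforced by reflecting ghost values of both u and D, which preserves
the discrete conservation property of the stencil. The resulting stiff ODE
system is advanced with a variable-order implicit multistep (BDF-type)
integrator. A linear restoring term pulls any field value that becomes
negative back towards zero (the kinetics are only meaningful on
non-negative densities, and hard clipping would destroy the smoothness the
implicit integrator relies on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .grid import FIELD_NAMES, Grid1D, StateFields
from .kinetics import _raw_reaction
from .params import DimensionlessParams


class SolverError(RuntimeError):
    """Time integration failed (e.g. step-size collapse)."""


@dataclass(frozen=True)
class SolverSettings:
    """Tolerances, stabilisation strength and snapshot schedule.

    rel_tol, abs_tol : integrator tolerances (default 1e-10 each, matching
        the reference resolution; 1e-8 is adequate for sweep-scale work).
    stabilisation_rate : rate (dimensionless, default 100) at which negative
        field values are restored towards zero.
    extinction_threshold : density below which the autocatalytic reaction
        terms of the three cell populations are switched off (default
        1e-12, far below any meaningful density and below the integrator
        tolerances). Rounding noise from the implicit linear solves would
        otherwise nucleate exponential growth in regions the continuum
        solution keeps at exactly zero, e.g. beyond a fully obstructing
        matrix barrier where the acid has already cleared the stroma.
    snapshot_times : strictly increasing times, first >= 0, at which the
        solution is recorded.
    """

    rel_tol: float = 1e-10
    abs_tol: float = 1e-10
    stabilisation_rate: float = 100.0
    extinction_threshold: float = 1e-12
    snapshot_times: tuple = (0.0, 25.0, 50.0)

    def __post_init__(self) -> None:
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("tolerances must be > 0")
        if self.stabilisation_rate < 0:
            raise ValueError("stabilisation_rate must be >= 0")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")
        t = np.asarray(self.snapshot_times, dtype=float)
        if t.size == 0 or t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("snapshot times must be strictly increasing, starting >= 0")
        object.__setattr__(self, "snapshot_times", tuple(t))


@dataclass
class Trajectory:
    """Time-stamped snapshots of a single integration."""

    times: np.ndarray
    states: list
    params: DimensionlessParams
    grid: Grid1D
    settings: SolverSettings = field(default_factory=SolverSettings)

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, t: float, rtol: float = 1e-9) -> StateFields:
        i = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[i], t, rtol=rtol, atol=1e-12):
            raise KeyError(f"no snapshot at t={t}; available: {list(self.times)}")
        return self.states[i]


def variable_diffusion_second_difference(u, D, h: float, r: int) -> float:
    """The conservative stencil at one interior index r (1 <= r <= n-2)."""
    u = np.asarray(u, dtype=float)
    D = np.asarray(D, dtype=float)
    if not (1 <= r <= len(u) - 2):
        raise IndexError(f"r={r} is not an interior index of a field of length {len(u)}")
    return (
        (D[r - 1] + D[r]) * u[r - 1]
        - (D[r - 1] + 2.0 * D[r] + D[r + 1]) * u[r]
        + (D[r] + D[r + 1]) * u[r + 1]
    ) / (2.0 * h * h)


def _diffusion_divergence(u: np.ndarray, D: np.ndarray, h: float) -> np.ndarray:
    """Vectorised stencil on the whole grid with reflecting ghost nodes."""
    ue = np.concatenate(([u[1]], u, [u[-2]]))
    De = np.concatenate(([D[1]], D, [D[-2]]))
    return (
        (De[:-2] + De[1:-1]) * ue[:-2]
        - (De[:-2] + 2.0 * De[1:-1] + De[2:]) * ue[1:-1]
        + (De[1:-1] + De[2:]) * ue[2:]
    ) / (2.0 * h * h)


def negativity_guard(
    state: StateFields, stabilisation_rate: float, deadband: float = 0.0
) -> StateFields:
    """Additive derivative contribution restoring negative field values.

    Contributes ``-lambda * u`` at every point where a field value
    ``u < -deadband`` (shifted by the deadband so the term stays
    continuous), and 0 elsewhere. With the default ``deadband=0`` this is a
    plain linear restoring force below zero. The solver engages the guard a
    hair below zero (at ``-extinction_threshold``): a kink in the
    right-hand side exactly at 0 lets the implicit integrator amplify
    rounding-level chatter of fields that sit at exactly zero.
    """
    if stabilisation_rate < 0:
        raise ValueError("stabilisation rate must be >= 0")
    out = {}
    for name in FIELD_NAMES:
        u = getattr(state, name)
        out[name] = _guard_term(u, stabilisation_rate, deadband)
    return StateFields(**out)


def _guard_term(u: np.ndarray, lam: float, deadband: float) -> np.ndarray:
    return np.where(u < -deadband, -lam * (u + deadband), 0.0)


def assemble_rhs(
    state: StateFields,
    params: DimensionlessParams,
    grid: Grid1D,
    stabilisation_rate: float = 100.0,
    include_reaction: bool = True,
    extinction_threshold: float = 0.0,
) -> StateFields:
    """Full semi-discrete right-hand side on the grid.

    ``include_reaction=False`` switches the kinetics off and is a test hook
    for isolating the transport operator.
    """
    if state.n_points != grid.n_points:
        raise ValueError("state length does not match grid")
    y = state.pack()
    dy = _rhs_vector(y, params, grid, stabilisation_rate, include_reaction, extinction_threshold)
    return StateFields.unpack(dy, grid.n_points)


def _rhs_vector(
    y: np.ndarray,
    p: DimensionlessParams,
    grid: Grid1D,
    lam: float,
    include_reaction: bool = True,
    floor: float = 0.0,
) -> np.ndarray:
    n = grid.n_points
    h = grid.h
    S, T_A, T_M, L, M = y.reshape(5, n)
    if include_reaction:
        dS, dT_A, dT_M, dL, dM = _raw_reaction(S, T_A, T_M, L, M, p)
        if floor > 0:
            # sub-floor populations do not react (see SolverSettings)
            dS = np.where(S < floor, 0.0, dS)
            dT_A = np.where(T_A < floor, 0.0, dT_A)
            dT_M = np.where(T_M < floor, 0.0, dT_M)
    else:
        dS = np.zeros(n)
        dT_A, dT_M, dL, dM = np.zeros(n), np.zeros(n), np.zeros(n), np.zeros(n)
    D_tum = 1.0 - M
    dT_A = dT_A + p.Delta_T * _diffusion_divergence(T_A, D_tum, h)
    dT_M = dT_M + p.Delta_T * _diffusion_divergence(T_M, D_tum, h)
    dL = dL + _diffusion_divergence(L, np.ones(n), h)
    out = np.concatenate([dS, dT_A, dT_M, dL, dM])
    if lam > 0:
        out = out + _guard_term(y, lam, floor)
    return out


def _jacobian_sparsity(n: int) -> sp.csr_matrix:
    """Conservative sparsity pattern of the semi-discrete Jacobian.

    Same-point coupling between all five fields (reaction + the M-dependence
    of the tumour mobilities), nearest-neighbour coupling for the diffusing
    fields and for M through D = 1 - M.
    """
    same = np.ones((5, 5))
    nb = np.zeros((5, 5))
    nb[1, 1] = nb[1, 4] = 1.0  # T_A row: neighbour T_A and M
    nb[2, 2] = nb[2, 4] = 1.0  # T_M row
    nb[3, 3] = 1.0  # L row
    eye = sp.identity(n, format="csr")
    off = sp.diags([np.ones(n - 1), np.ones(n - 1)], [-1, 1], format="csr")
    return (sp.kron(same, eye) + sp.kron(nb, off)).tocsr()


def integrate(
    state0: StateFields,
    params: DimensionlessParams,
    grid: Grid1D,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Advance the semi-discrete system and record the requested snapshots.

    The run is fully deterministic. Raises :class:`SolverError` naming the
    time reached if the implicit integrator fails.
    """
    settings = settings or SolverSettings()
    t_eval = np.asarray(settings.snapshot_times, dtype=float)
    t0, t1 = float(t_eval[0]), float(t_eval[-1])
    y0 = state0.pack()
    lam = settings.stabilisation_rate
    floor = settings.extinction_threshold

    def rhs(t, y):
        return _rhs_vector(y, params, grid, lam, True, floor)

    if t1 == t0:
        sol_states = [StateFields.unpack(y0, grid.n_points)]
        return Trajectory(t_eval.copy(), sol_states, params, grid, settings)

    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method="BDF",
        t_eval=t_eval,
        rtol=settings.rel_tol,
        atol=settings.abs_tol,
        jac_sparsity=_jacobian_sparsity(grid.n_points),
    )
    if not sol.success:
        raise SolverError(
            f"implicit integration failed at t={sol.t[-1] if sol.t.size else t0:.6g}: {sol.message}"
        )
    states = [StateFields.unpack(sol.y[:, k], grid.n_points) for k in range(sol.y.shape[1])]
    return Trajectory(sol.t.copy(), states, params, grid, settings)
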
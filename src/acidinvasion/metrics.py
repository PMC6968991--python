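"""Invasion summary measures: front position, tumour mass, speed, units.

The default front tracker is a threshold crossing: the rightmost location
where the species density still reaches ``eps`` (default 1e-2), linearly
interpolated between grid nodes. An alternative tracker places the front
at the grid point where the field's time derivative is extremal in
magnitude; it exists because edge definitions based on d/dt appear in the
literature, and both are reported in sweep outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid1D, StateFields
from .params import DimensionlessParams

#: distinct from any position: the species is absent at threshold level
ABSENT = None

#: default threshold for front detection
FRONT_EPS = 1e-2

#: integral below which a population is disregarded in sweep summaries
SMALL_POPULATION_CUTOFF = 0.1

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class UnitScales:
    """Dimensional value of one dimensionless time/length unit."""

    time_days: float = 11.57
    length_cm: float = 2.24

    def __post_init__(self) -> None:
        if not (self.time_days > 0 and self.length_cm > 0):
            raise ValueError("unit scales must be > 0")


def _threshold_front(x: np.ndarray, f: np.ndarray, eps: float):
    above = np.where(f >= eps)[0]
    if above.size == 0:
        return ABSENT
    i = int(above[-1])
    if i == len(x) - 1:
        return float(x[-1])
    # f[i] >= eps > f[i+1]: linear interpolation of the crossing
    return float(x[i] + (f[i] - eps) / (f[i] - f[i + 1]) * (x[i + 1] - x[i]))


def front_position(
    state: StateFields,
    grid: Grid1D,
    species: str = "either",
    method: str = "threshold",
    eps: float = FRONT_EPS,
    deriv: StateFields | None = None,
    params: DimensionlessParams | None = None,
):
    """Position of the invading edge of T_A, T_M or their combined front.

    ``species="either"`` returns the rightmost of the two single-species
    fronts. Returns None when the species never reaches the threshold
    (an absent population, distinct from a front at x=0). For
    ``method="max_rate"`` a time-derivative field is required: pass it as
    ``deriv`` or pass ``params`` so it can be assembled here.
    """
    if species == "either":
        fa = front_position(state, grid, "T_A", method, eps, deriv, params)
        fm = front_position(state, grid, "T_M", method, eps, deriv, params)
        present = [f for f in (fa, fm) if f is not None]
        return max(present) if present else ABSENT
    if species not in ("T_A", "T_M"):
        raise ValueError(f"unknown species {species!r}")
    f = getattr(state, species)
    x = grid.x
    if np.all(f < eps):
        return ABSENT
    if method == "threshold":
        return _threshold_front(x, f, eps)
    if method == "max_rate":
        if deriv is None:
            if params is None:
                raise ValueError("max_rate needs a derivative field or params to build one")
            from .solver import assemble_rhs

            deriv = assemble_rhs(state, params, grid, stabilisation_rate=0.0)
        df = getattr(deriv, species)
        return float(x[int(np.argmax(np.abs(df)))])
    raise ValueError(f"unknown front method {method!r}")


def tumour_mass(state: StateFields, grid: Grid1D) -> float:
    """Total tumour burden: the integral of T_A + T_M over the domain."""
    return float(np.trapezoid(state.T_A + state.T_M, grid.x))


def species_integral(state: StateFields, grid: Grid1D, species: str) -> float:
    return float(np.trapezoid(getattr(state, species), grid.x))


def small_population_flag(state: StateFields, grid: Grid1D, species: str) -> bool:
    """True when the species should be kept; False (disregard) when its
    integral falls strictly below the smallness cut-off of 0.1."""
    return not species_integral(state, grid, species) < SMALL_POPULATION_CUTOFF


def invasion_speed(traj, species: str = "either", window: tuple = (25.0, 50.0),
                   method: str = "threshold", eps: float = FRONT_EPS):
    """Mean front speed between two snapshot times, or None if the
    population is absent at either endpoint."""
    t1, t2 = window
    if t2 <= t1:
        raise ValueError("window must be increasing")
    s1, s2 = traj.state_at(t1), traj.state_at(t2)
    f1 = front_position(s1, traj.grid, species, method, eps, params=traj.params)
    f2 = front_position(s2, traj.grid, species, method, eps, params=traj.params)
    if f1 is None or f2 is None:
        return None
    return (f2 - f1) / (t2 - t1)


def to_dimensional(value: float, kind: str, scales: UnitScales = UnitScales()) -> float:
    """Convert a dimensionless time, length or speed to days, cm or cm/day."""
    if kind == "time":
        return value * scales.time_days
    if kind == "length":
        return value * scales.length_cm
    if kind == "speed":
        return value * scales.length_cm / scales.time_days
    raise ValueError(f"unknown kind {kind!r}; expected time, length or speed")


def speed_cm_per_year(value: float, scales: UnitScales = UnitScales()) -> float:
    return to_dimensional(value, "speed", scales) * DAYS_PER_YEAR
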
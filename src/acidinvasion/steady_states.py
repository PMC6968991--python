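"""Homogeneous steady states, linear stability and invasion regimes.

The reaction kinetics admit, besides the all-extinct state, seven
biologically meaningful homogeneous equilibria:

=====  =======================================================================
SS0    healthy tissue, (1, 0, 0, 0, M*) with the matrix level M* arbitrary
SS1    acid-producer monoculture, (0, 1, 0, 1, M*)
SS2    matrix-degrader monoculture, (0, 0, 1, 0, 0)
SS3    tumour-phenotype coexistence with stroma and matrix eradicated
SS4    acid-producers coexisting with stroma (and arbitrary matrix)
SS5    matrix-degraders coexisting with stroma; infeasible whenever c_S > 1
SS6    three-way coexistence of stroma and both phenotypes, matrix eradicated
=====  =======================================================================

States that retain matrix (SS0, SS1, SS4) have a structural zero eigenvalue:
no kinetic term feeds back on M when T_M = 0, so every matrix level is
equally admissible. Stability for those states is therefore also reported
restricted to the non-matrix (S, T_A, T_M, L) subspace.

Stability is evaluated numerically from the analytic Jacobian of the
kinetics; the closed-form equilibria themselves are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .kinetics import reaction_jacobian, reaction_terms
from .params import DimensionlessParams

#: eigenvalue real parts within this band of zero count as marginal
DEFAULT_ZERO_TOL = 1e-8

homogeneous_jacobian = reaction_jacobian


class DegenerateSteadyStateError(ValueError):
    """A closed-form denominator vanished (e.g. c_MA * c_AM = 1 for SS3)."""


@dataclass
class SteadyState:
    label: str
    S: float
    T_A: float
    T_M: float
    L: float
    M: float | None  # None means "free": any matrix level is an equilibrium
    feasible: bool
    note: str = ""
    stability: str = "not-classified"
    leading_eigenvalue_real_part: float | None = None
    nonmatrix_stability: str | None = None
    eigenvalues: np.ndarray | None = field(default=None, repr=False)

    @property
    def m_free(self) -> bool:
        return self.M is None

    def values(self, m_star: float = 1.0) -> tuple:
        """Numeric state point, substituting ``m_star`` for a free matrix level."""
        return (self.S, self.T_A, self.T_M, self.L, m_star if self.m_free else self.M)


def _feasible(vals, m_free: bool) -> bool:
    check = [v for v in vals if v is not None]
    return all(np.isfinite(v) and -1e-14 <= v <= 1.0 + 1e-14 for v in check)


def _mk(label, S, T_A, T_M, L, M, note="") -> SteadyState:
    vals = (S, T_A, T_M, L) + (() if M is None else (M,))
    return SteadyState(label, S, T_A, T_M, L, M, feasible=_feasible(vals, M is None), note=note)


def enumerate_steady_states(
    p: DimensionlessParams,
    include_trivial: bool = False,
    ss6_family_T_A: float = 0.5,
) -> list[SteadyState]:
    """All homogeneous equilibria of the kinetics in closed form.

    ``ss6_family_T_A`` selects the representative of the one-parameter SS6
    family that exists exactly at (c_MA, c_AM) = (1, 1). The all-extinct
    state is omitted unless ``include_trivial`` is set.
    """
    c_MA, c_AM, c_S, d = p.c_MA, p.c_AM, p.c_S, p.delta
    out = []
    if include_trivial:
        out.append(_mk("trivial", 0.0, 0.0, 0.0, 0.0, 0.0, note="all cell populations extinct"))
    out.append(_mk("SS0", 1.0, 0.0, 0.0, 0.0, None))
    out.append(_mk("SS1", 0.0, 1.0, 0.0, 1.0, None))
    out.append(_mk("SS2", 0.0, 0.0, 1.0, 0.0, 0.0))

    den3 = 1.0 - c_MA * c_AM
    if abs(den3) < 1e-12:
        ss3 = SteadyState(
            "SS3", np.nan, np.nan, np.nan, np.nan, 0.0, feasible=False,
            note="degenerate: c_MA * c_AM = 1 makes the coexistence denominator vanish",
        )
        ss3.stability = "not-applicable"
        out.append(ss3)
    else:
        ta = (1.0 - c_MA) / den3
        tm = (1.0 - c_AM) / den3
        out.append(_mk("SS3", 0.0, ta, tm, ta, 0.0))

    den4 = 1.0 - c_S * d
    if abs(den4) < 1e-12:
        ss4 = SteadyState(
            "SS4", np.nan, np.nan, 0.0, np.nan, None, feasible=False,
            note="degenerate: c_S * delta = 1",
        )
        ss4.stability = "not-applicable"
        out.append(ss4)
    else:
        s4 = (1.0 - d) / den4
        t4 = (1.0 - c_S) / den4
        out.append(_mk("SS4", s4, t4, 0.0, t4, None))

    out.append(_mk("SS5", 1.0, 0.0, 1.0 - c_S, 0.0, 0.0))

    if abs(c_MA - 1.0) < 1e-12 and abs(c_AM - 1.0) < 1e-12:
        ta = float(ss6_family_T_A)
        s6 = 1.0 - d * ta
        tm6 = 1.0 - c_S - (1.0 - c_S * d) * ta
        out.append(
            _mk("SS6", s6, ta, tm6, ta, 0.0,
                note=f"one-parameter family at (c_MA, c_AM)=(1,1); representative T_A={ta}")
        )
    else:
        den6 = 1.0 - c_S * d - c_AM * c_MA + c_MA * c_S * d
        if abs(den6) < 1e-12:
            ss6 = SteadyState(
                "SS6", np.nan, np.nan, np.nan, np.nan, 0.0, feasible=False,
                note="degenerate: SS6 denominator vanishes",
            )
            ss6.stability = "not-applicable"
            out.append(ss6)
        else:
            s6 = (1.0 - d - c_AM * c_MA + c_MA * d) / den6
            ta6 = (1.0 - c_S) * (1.0 - c_MA) / den6
            tm6 = (1.0 - c_S) * (1.0 - c_AM) / den6
            out.append(_mk("SS6", s6, ta6, tm6, ta6, 0.0))

    for ss in out:
        if not ss.feasible:
            ss.stability = "not-applicable"
    return out


def classify_stability(
    ss: SteadyState,
    p: DimensionlessParams,
    zero_tol: float = DEFAULT_ZERO_TOL,
    m_star: float = 1.0,
) -> SteadyState:
    """Label a feasible steady state from the eigenvalues of the kinetics Jacobian.

    ``unstable`` if any eigenvalue has real part above ``zero_tol``;
    ``marginal`` if the largest real part sits within ``[-zero_tol,
    zero_tol]`` (the expected outcome for the matrix zero mode of SS0, SS1
    and SS4); ``stable`` otherwise. For marginal states the label
    restricted to the non-matrix subspace is reported as well. The input is
    annotated in place and returned.
    """
    if not ss.feasible:
        ss.stability = "not-applicable"
        return ss
    J = reaction_jacobian(ss.values(m_star=m_star), p)
    eig = np.linalg.eigvals(J)
    lead = float(np.max(eig.real))
    ss.eigenvalues = eig
    ss.leading_eigenvalue_real_part = lead
    if lead > zero_tol:
        ss.stability = "unstable"
    elif lead >= -zero_tol:
        ss.stability = "marginal"
        sub = float(np.max(np.linalg.eigvals(J[:4, :4]).real))
        ss.nonmatrix_stability = (
            "unstable" if sub > zero_tol else "marginal" if sub >= -zero_tol else "stable"
        )
    else:
        ss.stability = "stable"
    return ss


def classify_regime(c_MA: float, c_AM: float, tol: float = 1e-9) -> str:
    """Map a competition pair to one of the four invasion scenarios.

    Inter-species competition below the intra-species level (both c < 1)
    lets the phenotypes coexist and cooperate; above it, one excludes the
    other or (both c > 1) the outcome is initial-condition dependent.
    """
    if c_MA < 0 or c_AM < 0:
        raise ValueError("competition coefficients must be >= 0")
    if abs(c_MA - 1.0) <= tol or abs(c_AM - 1.0) <= tol:
        return "boundary"
    if c_MA < 1.0 and c_AM < 1.0:
        return "stable_coexistence"
    if c_MA > 1.0 and c_AM < 1.0:
        return "exclusion_of_TA"
    if c_MA < 1.0 and c_AM > 1.0:
        return "exclusion_of_TM"
    return "bistable"


def _leading_nonmatrix_eig(target: str, c_MA: float, c_AM: float, p: DimensionlessParams) -> float:
    q = p.replace(c_MA=c_MA, c_AM=c_AM)
    states = {s.label: s for s in enumerate_steady_states(q)}
    ss = states[target]
    if not all(np.isfinite(v) for v in ss.values()):
        return np.nan
    J = reaction_jacobian(ss.values(m_star=1.0), q)
    return float(np.max(np.linalg.eigvals(J[:4, :4]).real))


def critical_competition(
    p: DimensionlessParams,
    axis: str,
    other_value: float = 0.5,
    target_state: str = "SS3",
    bracket: tuple = (0.0, 2.0),
    xtol: float = 1e-6,
) -> float | None:
    """Bisect the stability threshold of SS1 or SS3 along a competition path.

    ``axis`` is ``"c_MA"``, ``"c_AM"`` or ``"symmetric"`` (c_MA = c_AM
    varied together, the other axis then ignores ``other_value``). Returns
    the competition value at which the leading non-matrix eigenvalue of the
    target state changes sign, to within ``xtol``, or None when there is no
    sign change on the bracket.
    """
    if axis not in ("c_MA", "c_AM", "symmetric"):
        raise ValueError(f"unknown axis {axis!r}")
    if target_state not in ("SS1", "SS3"):
        raise ValueError("threshold search supports SS1 and SS3 only")

    def g(c: float) -> float:
        if axis == "symmetric":
            cma, cam = c, c
        elif axis == "c_MA":
            cma, cam = c, other_value
        else:
            cma, cam = other_value, c
        return _leading_nonmatrix_eig(target_state, cma, cam, p)

    lo, hi = bracket

    def _finite_endpoint(c, step):
        # nudge off points where the closed form degenerates (e.g. the
        # hyperbola c_MA * c_AM = 1 at a bracket corner)
        for _ in range(8):
            v = g(c)
            if np.isfinite(v):
                return c, v
            c += step
        return c, np.nan

    lo, glo = _finite_endpoint(lo + (1e-9 if lo == 0.0 else 0.0), 1e-6)
    hi, ghi = _finite_endpoint(hi, -1e-6)
    if not (np.isfinite(glo) and np.isfinite(ghi)) or glo * ghi > 0:
        return None
    return float(brentq(g, lo, hi, xtol=xtol))


def residuals(ss: SteadyState, p: DimensionlessParams, m_star: float = 1.0) -> np.ndarray:
    """Kinetic time-derivatives at a steady state (all ~0 when feasible)."""
    return np.array(reaction_terms(*ss.values(m_star=m_star), p))
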
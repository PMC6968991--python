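"""Pointwise reaction kinetics of the non-dimensional five-field system.

The spatially homogeneous part of the model:

    dS/dt   = S (1 - S) - delta S L
    dT_A/dt = rho_T T_A (1 - c_S S - T_A - c_MA T_M)
    dT_M/dt = rho_T T_M (1 - c_S S - c_AM T_A - T_M)
    dL/dt   = rho_L (T_A - L)
    dM/dt   = -kappa T_M M

Transport (density-dependent diffusion of the tumour fields, free diffusion
of acid) is deliberately kept out of this module so the steady-state
analysis can reuse the pure kinetics; it lives in :mod:`acidinvasion.solver`.

All functions are vectorised: fields may be scalars or same-shape arrays.
"""

from __future__ import annotations

import numpy as np

from .params import DimensionlessParams


def _raw_reaction(S, T_A, T_M, L, M, p: DimensionlessParams):
    # unchecked fast path shared with the solver's right-hand side
    dS = S * (1.0 - S) - p.delta * S * L
    dT_A = p.rho_T * T_A * (1.0 - p.c_S * S - T_A - p.c_MA * T_M)
    dT_M = p.rho_T * T_M * (1.0 - p.c_S * S - p.c_AM * T_A - T_M)
    dL = p.rho_L * (T_A - L)
    dM = -p.kappa * T_M * M
    return dS, dT_A, dT_M, dL, dM


def reaction_terms(S, T_A, T_M, L, M, p: DimensionlessParams):
    """Time derivatives of the five fields under the reaction kinetics only.

    Returns ``(dS, dT_A, dT_M, dL, dM)``, each with the broadcast shape of
    the inputs. Raises ``ValueError`` on non-finite input, which would
    otherwise propagate NaNs silently.
    """
    arrs = [np.asarray(a, dtype=float) for a in (S, T_A, T_M, L, M)]
    for name, a in zip("S T_A T_M L M".split(), arrs):
        if not np.all(np.isfinite(a)):
            raise ValueError(f"non-finite value in field {name}")
    return _raw_reaction(*arrs, p)


def reaction_jacobian(point, p: DimensionlessParams) -> np.ndarray:
    """Analytic 5x5 Jacobian of :func:`reaction_terms` at one state point.

    Field order is (S, T_A, T_M, L, M). Because no kinetic term other than
    the matrix equation involves M, the M column is zero except for its
    diagonal entry ``-kappa T_M``; at any state with ``T_M = 0`` this
    produces the structural zero eigenvalue associated with perturbing the
    matrix density.
    """
    S, T_A, T_M, L, M = (float(v) for v in point)
    J = np.zeros((5, 5))
    # stroma row
    J[0, 0] = 1.0 - 2.0 * S - p.delta * L
    J[0, 3] = -p.delta * S
    # acid-producer row
    J[1, 0] = -p.rho_T * T_A * p.c_S
    J[1, 1] = p.rho_T * (1.0 - p.c_S * S - 2.0 * T_A - p.c_MA * T_M)
    J[1, 2] = -p.rho_T * T_A * p.c_MA
    # matrix-degrader row
    J[2, 0] = -p.rho_T * T_M * p.c_S
    J[2, 1] = -p.rho_T * T_M * p.c_AM
    J[2, 2] = p.rho_T * (1.0 - p.c_S * S - p.c_AM * T_A - 2.0 * T_M)
    # acid row
    J[3, 1] = p.rho_L
    J[3, 3] = -p.rho_L
    # matrix row
    J[4, 2] = -p.kappa * M
    J[4, 4] = -p.kappa * T_M
    return J
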
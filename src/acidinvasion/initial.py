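"""Regularised-step initial data.

The tumour initially occupies the left end of the domain and is bounded by
healthy tissue (stroma + matrix) on the right. The interface is smoothed
with a compactly supported bump-function shoulder of width ``omega``:

    f(x; sigma, omega) = 1                                   x <  sigma - omega
                       = exp(1 - 1 / (1 - z^2)),  z=(x-sigma+omega)/omega,
                                                   sigma - omega <= x < sigma
                       = 0                                   otherwise

so f falls smoothly from 1 to 0 over [sigma - omega, sigma).

Two conventions for placing the steps are supported (see
``InitialConditionSpec.step_convention``):

``"plateau"`` (default)
    The plateau of each field extends to its ``sigma`` and the shoulder
    occupies [sigma, sigma + omega). With the default tissue step at 0.2
    the matrix density is strictly below 1 up to x = 0.3, which is the
    configuration that reproduces the published single-population stall
    positions (acid-producers at x ~ 0.3, matrix-degraders at x ~ 0.2).

``"support"``
    The literal reading of the formula above: the whole support of the
    step, shoulder included, lies in [0, sigma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import Grid1D, StateFields
from .params import InvalidParameterError


def regularised_step(x, sigma: float, omega: float):
    """Smoothed indicator of the tumour-occupied region, values in [0, 1].

    Equals 1 for ``x < sigma - omega``, decays smoothly (C^inf) on
    ``[sigma - omega, sigma)`` and is 0 for ``x >= sigma``. Vectorised in x.
    """
    if not omega > 0:
        raise InvalidParameterError(f"omega must be > 0, got {omega}")
    x = np.asarray(x, dtype=float)
    z = (x - sigma + omega) / omega
    out = np.zeros_like(x)
    out[x < sigma - omega] = 1.0
    mid = (x >= sigma - omega) & (x < sigma)
    zm = z[mid]
    with np.errstate(divide="ignore"):
        out[mid] = np.exp(1.0 - 1.0 / (1.0 - zm**2))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class InitialConditionSpec:
    """Shape parameters of the initial tumour/tissue interface.

    sigma_tissue : step location for the stroma and matrix fields.
    sigma_tumour : step location for the tumour and acid fields (the tumour
        has infiltrated a shorter distance than the tissue has receded).
    omega        : shoulder width of the smoothed step.
    include_TA / include_TM : presence flags for single-population runs; an
        absent population is identically zero (the step function has no
        representation of absence).
    step_convention : "plateau" or "support", see module docstring.
    """

    sigma_tissue: float = 0.2
    sigma_tumour: float = 0.1
    omega: float = 0.1
    include_TA: bool = True
    include_TM: bool = True
    step_convention: str = "plateau"

    def __post_init__(self) -> None:
        for name in ("sigma_tissue", "sigma_tumour"):
            s = getattr(self, name)
            if not (0 < self.omega <= s):
                raise InvalidParameterError(
                    f"need 0 < omega <= {name} (omega={self.omega}, {name}={s})"
                )
        if self.step_convention not in ("plateau", "support"):
            raise InvalidParameterError(
                f"unknown step_convention {self.step_convention!r}"
            )

    def step_location(self, sigma: float) -> float:
        """Location parameter passed to :func:`regularised_step`."""
        return sigma + self.omega if self.step_convention == "plateau" else sigma


def build_initial_state(grid: Grid1D, ics: InitialConditionSpec) -> StateFields:
    """Evaluate the initial data on a grid.

    S and M are the complement of the tissue step; T_A, T_M (where present)
    and L equal the tumour step.
    """
    for name in ("sigma_tissue", "sigma_tumour"):
        loc = ics.step_location(getattr(ics, name))
        if loc >= grid.length:
            raise InvalidParameterError(
                f"step for {name} reaches x={loc}, beyond the domain length {grid.length}"
            )
    x = grid.x
    f_tissue = regularised_step(x, ics.step_location(ics.sigma_tissue), ics.omega)
    f_tumour = regularised_step(x, ics.step_location(ics.sigma_tumour), ics.omega)
    return StateFields(
        S=1.0 - f_tissue,
        T_A=f_tumour * float(ics.include_TA),
        T_M=f_tumour * float(ics.include_TM),
        L=f_tumour.copy(),
        M=1.0 - f_tissue,
    )
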
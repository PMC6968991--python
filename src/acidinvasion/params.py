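"""Model parameters: dimensional rates and the dimensionless groups.

The simulator integrates the non-dimensional system only. Users either supply
the eight dimensionless groups directly (the defaults are the values used for
the published simulation study) or provide a :class:`DimensionalParams` and
convert with :func:`nondimensionalise`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields


class InvalidParameterError(ValueError):
    """A parameter violates a model invariant (e.g. non-positive rate)."""


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional rates and capacities of the five-field invasion model.

    The two tumour phenotypes are biologically identical apart from their
    specialist traits: ``r_T``, ``K_T`` and ``D_T`` are shared by the
    acid-producing and matrix-degrading populations, and the stromal and
    tumour carrying capacities coincide (``K_T = K_S = K``).

    Units: rates in 1/time, diffusivities in length^2/time, ``d_S`` per acid
    concentration per time, ``r_L`` acid per cell per time, ``d_M`` per cell
    per time, capacities in cells (or mass) per volume.
    """

    r_S: float
    K: float
    d_S: float
    r_T: float
    D_T: float
    r_L: float
    d_L: float
    D_L: float
    d_M: float
    K_M: float
    c_S: float = 1.5
    c_MA: float = 0.0
    c_AM: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("c_S", "c_MA", "c_AM"):
                if v < 0:
                    raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
            elif not v > 0:
                raise InvalidParameterError(f"{f.name} must be > 0, got {v}")


@dataclass(frozen=True)
class DimensionlessParams:
    """The eight dimensionless groups governing the rescaled system.

    delta   -- acid-kill strength (stromal death per unit rescaled acid).
    rho_T   -- tumour/stroma growth-rate ratio.
    Delta_T -- tumour/acid diffusivity ratio.
    rho_L   -- acid turnover rate relative to stromal growth.
    kappa   -- matrix-degradation rate relative to stromal growth.
    c_S     -- competition the stroma exerts on both tumour phenotypes.
    c_MA    -- competition of the matrix-degraders on the acid-producers.
    c_AM    -- competition of the acid-producers on the matrix-degraders.

    Defaults are the published simulation values. The stability analysis
    downstream assumes ``delta > 1`` and ``c_S > 1``; violating either is
    allowed (the model stays well-posed) but recorded with a warning.
    """

    delta: float = 12.5
    rho_T: float = 1.0
    Delta_T: float = 4e-5
    rho_L: float = 70.0
    kappa: float = 10.0
    c_S: float = 1.5
    c_MA: float = 0.0
    c_AM: float = 0.0
    #: parameter-regime notes recorded at construction (not an error)
    regime_warnings: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        notes = []
        for f in fields(self):
            if f.name == "regime_warnings":
                continue
            v = getattr(self, f.name)
            if v < 0:
                raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
        if self.delta <= 1:
            notes.append("delta <= 1: acid-only invasion analysis assumes delta > 1")
        if self.c_S <= 1:
            notes.append("c_S <= 1: stability claims assume stroma out-competes tumour (c_S > 1)")
        if notes:
            for n in notes:
                warnings.warn(n, UserWarning, stacklevel=2)
            object.__setattr__(self, "regime_warnings", tuple(notes))

    def replace(self, **kw) -> "DimensionlessParams":
        vals = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "regime_warnings"}
        vals.update(kw)
        return DimensionlessParams(**vals)


def nondimensionalise(dp: DimensionalParams) -> DimensionlessParams:
    """Map dimensional parameters to the dimensionless groups.

    delta = d_S r_L K / (d_L r_S), rho_T = r_T / r_S, Delta_T = D_T / D_L,
    rho_L = d_L / r_S, kappa = d_M K / r_S; the three competition
    coefficients are already dimensionless and pass through unchanged.
    """
    return DimensionlessParams(
        delta=dp.d_S * dp.r_L * dp.K / (dp.d_L * dp.r_S),
        rho_T=dp.r_T / dp.r_S,
        Delta_T=dp.D_T / dp.D_L,
        rho_L=dp.d_L / dp.r_S,
        kappa=dp.d_M * dp.K / dp.r_S,
        c_S=dp.c_S,
        c_MA=dp.c_MA,
        c_AM=dp.c_AM,
    )
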
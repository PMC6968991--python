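"""1-D spatial grid and the container for the five spatial fields."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FIELD_NAMES = ("S", "T_A", "T_M", "L", "M")


@dataclass(frozen=True)
class Grid1D:
    """Equi-spaced grid on [0, length] with n_points nodes."""

    n_points: int = 200
    length: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("n_points must be >= 3")
        if not self.length > 0:
            raise ValueError("length must be > 0")

    @property
    def h(self) -> float:
        return self.length / (self.n_points - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n_points)


@dataclass
class StateFields:
    """The five spatial fields, one value per grid node each."""

    S: np.ndarray
    T_A: np.ndarray
    T_M: np.ndarray
    L: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.S)
        for name in FIELD_NAMES:
            a = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, a)
            if a.shape != (n,):
                raise ValueError("all five fields must share one length")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"non-finite value in field {name}")

    @property
    def n_points(self) -> int:
        return len(self.S)

    def pack(self) -> np.ndarray:
        """Stack the fields into one vector (field-major order)."""
        return np.concatenate([getattr(self, name) for name in FIELD_NAMES])

    @classmethod
    def unpack(cls, y: np.ndarray, n_points: int) -> "StateFields":
        y = np.asarray(y, dtype=float)
        if y.shape != (5 * n_points,):
            raise ValueError("vector length does not match 5 * n_points")
        parts = y.reshape(5, n_points)
        return cls(*parts)

    def copy(self) -> "StateFields":
        return StateFields(*(getattr(self, n).copy() for n in FIELD_NAMES))
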
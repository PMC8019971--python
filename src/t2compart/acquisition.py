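"""Acquisition geometry and the logarithmic T2 grid.

The multi-echo protocol modeled here is a CPMG-style 32-echo train with
equally spaced echoes (TE = 10..320 ms at the defaults) and TR = 1000 ms.
The inversion grid is 200 logarithmically spaced T2 time constants spanning
1-3000 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AcquisitionParams", "T2Grid"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Multi-echo spin-echo acquisition parameters.

    Parameters
    ----------
    n_echoes : int
        Number of echoes in the train (>= 2).
    echo_spacing : float
        Inter-echo spacing in ms; echo k occurs at ``k * echo_spacing``
        (1-based), so the last TE is 320 ms at the defaults.
    repetition_time : float
        Sequence TR in ms. Not used by the decay model directly (steady-state
        saturation is folded into proton density) but carried for provenance.
    excitation_flip : float
        Excitation pulse angle in degrees; the model assumes an ideal 90.
    t1_assumed : float
        Fixed longitudinal relaxation time (ms) used for every column of the
        decay basis. Multi-echo T2 fits over a 320 ms train are insensitive
        to T1, so a single model constant is used.
    """

    n_echoes: int = 32
    echo_spacing: float = 10.0
    repetition_time: float = 1000.0
    excitation_flip: float = 90.0
    t1_assumed: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_echoes < 2:
            raise ValueError(f"n_echoes must be >= 2, got {self.n_echoes}")
        if not self.echo_spacing > 0:
            raise ValueError(f"echo_spacing must be > 0, got {self.echo_spacing}")
        if not self.t1_assumed > 0:
            raise ValueError(f"t1_assumed must be > 0, got {self.t1_assumed}")
        if self.excitation_flip != 90.0:
            raise ValueError("only an ideal 90 degree excitation is modeled")

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times in ms, ``k * echo_spacing`` for k = 1..n_echoes."""
        return self.echo_spacing * np.arange(1, self.n_echoes + 1, dtype=float)


@dataclass(frozen=True)
class T2Grid:
    """Logarithmically spaced grid of candidate T2 time constants (ms).

    Construct with :meth:`geometric` for the standard grid; the constructor
    accepts any strictly increasing geometric sequence (a single node is
    allowed, which is convenient for testing).
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("grid must contain at least one T2 value")
        if np.any(v <= 0):
            raise ValueError("all grid T2 values must be positive")
        if v.size > 1 and np.any(np.diff(v) <= 0):
            raise ValueError("grid values must be strictly increasing")
        if v.size > 2:
            ratios = v[1:] / v[:-1]
            if np.max(np.abs(ratios / ratios.mean() - 1.0)) > 1e-12:
                raise ValueError("grid must be logarithmically (geometrically) spaced")

    @classmethod
    def geometric(cls, t_min: float = 1.0, t_max: float = 3000.0, n: int = 200) -> "T2Grid":
        """The standard grid: ``n`` log-spaced nodes over ``[t_min, t_max]``."""
        if not (0 < t_min < t_max):
            raise ValueError("require 0 < t_min < t_max")
        if n < 1:
            raise ValueError("n must be >= 1")
        if n == 1:
            return cls(values=(math.sqrt(t_min * t_max),))
        # np.geomspace keeps the log-spacing ratio constant to rounding error
        return cls(values=tuple(np.geomspace(t_min, t_max, n)))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)
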
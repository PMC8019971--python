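"""Extended phase graph (EPG) forward model for CPMG echo trains.

When the refocusing pulses deviate from 180 degrees, part of the transverse
magnetization is stored along the longitudinal axis between echoes and later
recalled as stimulated echoes. The EPG recursion tracks this exactly through
configuration states F(k), Z(k) indexed by the integer dephasing order k
imposed by the crusher gradients. At exactly 180 degrees no longitudinal
storage occurs and each echo reduces to the mono-exponential exp(-TE/T2).

The recursion per inter-echo interval is

    relax(tau) -> shift -> RF(alpha) -> shift -> relax(tau),  tau = ESP / 2,

with the echo read from |F(0)| after the final relaxation. Stored Z states
relax with T1; longitudinal regrowth toward equilibrium during the train is
not modeled (the magnetization prepared by the excitation is the only signal
source), matching the convention of multi-echo T2 analysis.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams, T2Grid

__all__ = ["DecayBasis", "epg_decay", "build_basis"]


@dataclass(frozen=True)
class DecayBasis:
    """Dictionary of EPG echo trains, one column per grid T2.

    ``matrix`` has shape (n_echoes, n_t2); entry (k, j) is the echo-k
    amplitude (per unit initial magnetization) of a pure-T2_j pool at the
    stored refocusing flip angle.
    """

    matrix: np.ndarray
    flip_angle: float
    acquisition: AcquisitionParams
    grid: T2Grid

    @property
    def n_echoes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_t2(self) -> int:
        return self.matrix.shape[1]


def _validate_flip(flip_angle: float) -> None:
    if not (90.0 <= flip_angle <= 180.0):
        raise ValueError(f"refocusing flip angle must be in [90, 180] deg, got {flip_angle}")


def _epg_trains(t2: np.ndarray, t1: float, flip_deg: float, acq: AcquisitionParams) -> np.ndarray:
    """EPG echo amplitudes for a vector of T2 values; shape (n_echoes, len(t2))."""
    n = acq.n_echoes
    m = t2.size
    # Orders 0..n; states beyond n cannot refocus within the train.
    n_states = n + 1
    Fp = np.zeros((n_states, m), dtype=complex)   # F(k), k >= 0
    Fm = np.zeros((n_states, m), dtype=complex)   # conj(F(-k)), k >= 0
    Z = np.zeros((n_states, m), dtype=complex)

    # Ideal 90 excitation along the refocusing axis (CPMG condition): F(0) = 1.
    Fp[0] = 1.0
    Fm[0] = 1.0

    tau = acq.echo_spacing / 2.0
    E2 = np.exp(-tau / t2)[None, :]
    E1 = np.exp(-tau / t1)

    a = np.deg2rad(flip_deg)
    c2 = np.cos(a / 2.0) ** 2
    s2 = np.sin(a / 2.0) ** 2
    s = np.sin(a)
    c = np.cos(a)

    out = np.empty((n, m), dtype=float)
    for k in range(n):
        # relax tau
        Fp *= E2
        Fm *= E2
        Z *= E1
        # gradient shift by +1
        f0 = np.conj(Fm[1]).copy()
        Fp[1:] = Fp[:-1]
        Fp[0] = f0
        Fm[:-1] = Fm[1:]
        Fm[-1] = 0.0
        # refocusing pulse about the CPMG axis
        Fp_new = c2 * Fp + s2 * Fm - 1j * s * Z
        Fm_new = s2 * Fp + c2 * Fm + 1j * s * Z
        Z_new = -0.5j * s * Fp + 0.5j * s * Fm + c * Z
        Fp, Fm, Z = Fp_new, Fm_new, Z_new
        # gradient shift by +1
        f0 = np.conj(Fm[1]).copy()
        Fp[1:] = Fp[:-1]
        Fp[0] = f0
        Fm[:-1] = Fm[1:]
        Fm[-1] = 0.0
        # relax tau; echo forms at F(0)
        Fp *= E2
        Fm *= E2
        Z *= E1
        out[k] = np.abs(Fp[0])
    return out


def epg_decay(
    t2: float,
    t1: float,
    flip_angle: float,
    acq: AcquisitionParams | None = None,
) -> np.ndarray:
    """Echo-train amplitudes of a single T2 pool under imperfect refocusing.

    Parameters
    ----------
    t2, t1 : float
        Relaxation times in ms. ``t1`` is the model constant applied to the
        stored longitudinal states.
    flip_angle : float
        Refocusing pulse angle in degrees, in [90, 180].
    acq : AcquisitionParams, optional
        Echo-train geometry (defaults to the 32-echo, 10 ms spacing protocol).

    Returns
    -------
    numpy.ndarray
        Echo amplitudes (unitless, per unit initial magnetization), length
        ``acq.n_echoes``. At 180 degrees this equals ``exp(-TE_k / t2)``.
    """
    acq = acq or AcquisitionParams()
    if not t2 > 0:
        raise ValueError(f"t2 must be > 0, got {t2}")
    if not t1 > 0:
        raise ValueError(f"t1 must be > 0, got {t1}")
    _validate_flip(flip_angle)
    return _epg_trains(np.array([t2], dtype=float), t1, flip_angle, acq)[:, 0]


@functools.lru_cache(maxsize=1024)
def _build_basis_cached(grid: T2Grid, flip_key: int, resolution: float, acq: AcquisitionParams) -> DecayBasis:
    flip_angle = flip_key * resolution
    matrix = _epg_trains(grid.array, acq.t1_assumed, flip_angle, acq)
    matrix.setflags(write=False)
    return DecayBasis(matrix=matrix, flip_angle=flip_angle, acquisition=acq, grid=grid)


def build_basis(
    grid: T2Grid,
    flip_angle: float,
    acq: AcquisitionParams | None = None,
    cache_resolution: float = 0.1,
) -> DecayBasis:
    """Decay-basis matrix with one EPG column per grid T2.

    Results are cached keyed on the flip angle rounded to ``cache_resolution``
    degrees (the angle-search resolution), so repeated voxel fits at the same
    angle reuse the matrix.
    """
    acq = acq or AcquisitionParams()
    _validate_flip(flip_angle)
    flip_key = int(round(flip_angle / cache_resolution))
    return _build_basis_cached(grid, flip_key, cache_resolution, acq)
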
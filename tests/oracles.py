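"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own algorithms: the isochromat
simulator integrates Bloch rotation matrices spin by spin instead of the
configuration-state recursion, and the non-negative least squares oracle
enumerates candidate active sets with plain ``lstsq`` instead of an
iterative solver.
"""

from __future__ import annotations

import itertools

import numpy as np


def isochromat_cpmg(
    t2: float,
    t1: float,
    flip_deg: float,
    n_echoes: int = 32,
    echo_spacing: float = 10.0,
    n_spins: int = 2048,
) -> np.ndarray:
    """Brute-force CPMG echo magnitudes by Bloch simulation of many spins.

    Each spin accumulates a fixed crusher-gradient phase per half interval,
    with phases uniformly spanning [0, 2pi); the voxel signal is the complex
    mean of the transverse magnetization at each echo. T2/T1 relaxation is
    applied over each half interval (no longitudinal regrowth, matching the
    model being checked). The 90 degree excitation puts the magnetization
    along the refocusing axis (x), satisfying the CPMG condition.
    """
    tau = echo_spacing / 2.0
    phi = 2.0 * np.pi * np.arange(n_spins) / n_spins
    cp, sp = np.cos(phi), np.sin(phi)
    e2 = np.exp(-tau / t2)
    e1 = np.exp(-tau / t1)
    a = np.deg2rad(flip_deg)
    ca, sa = np.cos(a), np.sin(a)

    mx = np.ones(n_spins)
    my = np.zeros(n_spins)
    mz = np.zeros(n_spins)
    out = np.empty(n_echoes)
    for k in range(n_echoes):
        # relax + crusher dephasing over the first half interval
        mx, my = e2 * (cp * mx - sp * my), e2 * (sp * mx + cp * my)
        mz = e1 * mz
        # refocusing rotation about x
        my, mz = ca * my + sa * mz, -sa * my + ca * mz
        # second half interval
        mx, my = e2 * (cp * mx - sp * my), e2 * (sp * mx + cp * my)
        mz = e1 * mz
        out[k] = abs(np.mean(mx + 1j * my))
    return out


def exhaustive_nnls(A: np.ndarray, y: np.ndarray, max_support: int = 4) -> tuple[np.ndarray, float]:
    """Global NNLS optimum by enumerating active sets up to ``max_support``.

    Solves the unconstrained least squares on every column subset of size
    <= max_support, keeps solutions with all-non-negative coefficients, and
    returns the feasible solution with the smallest residual norm. This is
    the exact global optimum whenever the true optimum's support size is
    within the cap (every feasible subset solution is feasible for the full
    problem, and the optimum is itself a subset solution).
    """
    n = A.shape[1]
    best_x = np.zeros(n)
    best_r = float(np.linalg.norm(y))
    for size in range(1, max_support + 1):
        for cols in itertools.combinations(range(n), size):
            sub = A[:, cols]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(coef < 0):
                continue
            r = float(np.linalg.norm(sub @ coef - y))
            if r < best_r - 1e-15:
                best_r = r
                best_x = np.zeros(n)
                best_x[list(cols)] = coef
    return best_x, best_r


def gaussian_intersection(m1: float, s1: float, m2: float, s2: float) -> float:
    """Crossing of two Gaussian pdfs between their means (closed form).

    Roots of the quadratic from equating log densities; returns the root
    lying between m1 and m2.
    """
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 + 2.0 * np.log(s1 / s2)
    if a == 0:
        return -c / b
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    lo, hi = min(m1, m2), max(m1, m2)
    inside = [r for r in roots if lo <= r <= hi]
    assert len(inside) == 1, f"expected one crossing between means, got {roots}"
    return float(inside[0])
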
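"""Independent reference implementations used only by the tests.

Everything here deliberately avoids the package's computational paths:
the equilibrium root is found by scanning/bracketing the binding
condition exactly as written, magnetization is propagated by explicit
fine-step RK4 rather than eigendecomposition, and the two-site exchange
line shape is written out from the hand-derived 2x2 diagonalization.
"""

from __future__ import annotations

import cmath
import math

import numpy as np
from scipy.optimize import brentq


# --- equilibrium -----------------------------------------------------------


def equilibrium_condition(pl: float, k1_on, k1_off, A, P0, L0) -> float:
    """The binding equilibrium condition in [PL], exactly as formulated."""
    return k1_off * pl - (L0 - A * pl) * (P0 - A * pl) * k1_on


def bracketed_root(k1_on, k1_off, k2, k2_prime, P0, L0, n_grid=100_000) -> float:
    """Sign-change bracketing scan of the equilibrium condition + refinement.

    Scans [0, min(P0, L0)/A] on a uniform grid for the sign change, then
    refines inside the bracketing interval with Brent's method on the
    literal condition.
    """
    A = 1.0 + (k2 / k2_prime if k2 > 0 else 0.0)
    if L0 == 0.0:
        return 0.0
    hi = min(P0, L0) / A
    xs = np.linspace(0.0, hi, n_grid)
    fs = equilibrium_condition(xs, k1_on, k1_off, A, P0, L0)
    sign = np.sign(fs)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        # root sits at the upper end (k1_off == 0 stoichiometric limit)
        return hi
    lo_x, hi_x = xs[idx[0]], xs[idx[0] + 1]
    return brentq(
        equilibrium_condition, lo_x, hi_x, args=(k1_on, k1_off, A, P0, L0),
        xtol=1e-30, rtol=1e-15,
    )


def two_state_closed_form(kd: float, P0: float, L0: float) -> float:
    """Textbook two-state binding quadratic: [PL] from Kd and totals."""
    b = P0 + L0 + kd
    return 0.5 * (b - math.sqrt(b * b - 4.0 * P0 * L0))


# --- hand-assembled generator (term by term from the rate equations) -------


def hand_generator(k1_on, k1_off, k2, k2_prime, omega_P, omega_PL, R2, L_free):
    """The 3x3 exchange generator written out entry by entry."""
    i2pi = 2j * math.pi
    return np.array(
        [
            [-i2pi * omega_P - R2 - k1_on * L_free, k1_off, 0.0],
            [k1_on * L_free, -i2pi * omega_PL - R2 - k1_off - k2, k2_prime],
            [0.0, k2, -i2pi * omega_P - R2 - k2_prime],
        ],
        dtype=complex,
    )


# --- fine-step explicit propagation ---------------------------------------


def _rk4_step_matrix(G: np.ndarray, h: float) -> np.ndarray:
    """One classical RK4 step for the linear system dM/dt = G M."""
    A = G * h
    n = np.eye(G.shape[0], dtype=complex)
    return n + A + A @ A / 2.0 + A @ A @ A / 6.0 + A @ A @ A @ A / 24.0


def _substeps(G: np.ndarray, dt: float, rate_factor: float) -> int:
    max_rate = np.max(np.abs(G))
    return max(1, int(math.ceil(dt * rate_factor * max_rate)))


def rk4_propagate(G: np.ndarray, M0: np.ndarray, dt: float, n: int,
                  rate_factor: float = 1000.0) -> np.ndarray:
    """Detected signal at times 0, dt, ..., (n-1) dt by explicit RK4.

    Step size is dt / ceil(dt * rate_factor * max|G_ij|), i.e. at most
    1/rate_factor of the fastest rate; substeps within one dwell are
    composed by matrix powers of the single-step operator.
    """
    k = _substeps(G, dt, rate_factor)
    S = np.linalg.matrix_power(_rk4_step_matrix(G, dt / k), k)
    out = np.empty(n, dtype=complex)
    M = np.asarray(M0, dtype=complex).copy()
    for j in range(n):
        out[j] = M.sum()
        M = S @ M
    return out


def rk4_echo(G: np.ndarray, M0: np.ndarray, tau: float,
             rate_factor: float = 1000.0) -> np.ndarray:
    """Spin echo by fine-step integration: evolve tau/2, conjugate, evolve."""
    if tau == 0.0:
        return np.asarray(M0, dtype=complex).copy()
    k = _substeps(G, tau / 2.0, rate_factor)
    S = np.linalg.matrix_power(_rk4_step_matrix(G, tau / (2.0 * k)), k)
    return S @ np.conj(S @ np.asarray(M0, dtype=complex))


# --- closed-form two-site exchange ----------------------------------------


def two_site_eigensystem(a11: complex, a22: complex, b12: float, b21: float):
    """Hand-diagonalized 2x2 generator [[a11, b12], [b21, a22]]."""
    tr = a11 + a22
    disc = cmath.sqrt((a11 - a22) ** 2 + 4.0 * b12 * b21)
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    return lam1, lam2


def two_site_fid(
    k_ab: float, k_ba: float, omega_a: float, omega_b: float, R2: float,
    M0: np.ndarray, t: np.ndarray,
) -> np.ndarray:
    """Closed-form detected signal of two exchanging sites.

    States a, b exchange at rates k_ab (a->b) and k_ba (b->a); the
    solution is built from the hand-derived eigenvalues/eigenvectors of
    the 2x2 generator, not from a numerical eigen-solver.
    """
    a11 = -2j * math.pi * omega_a - R2 - k_ab
    a22 = -2j * math.pi * omega_b - R2 - k_ba
    b12, b21 = k_ba, k_ab
    lam1, lam2 = two_site_eigensystem(a11, a22, b12, b21)
    m_a, m_b = complex(M0[0]), complex(M0[1])
    if abs(lam1 - lam2) < 1e-12 * max(abs(lam1), 1.0):
        # degenerate: G = lam I (only when exchange and shift both vanish)
        return (m_a + m_b) * np.exp(lam1 * t)
    # eigenvectors v_i = (b12, lam_i - a11); expansion M0 = c1 v1 + c2 v2
    v1 = np.array([b12, lam1 - a11], dtype=complex)
    v2 = np.array([b12, lam2 - a11], dtype=complex)
    if b12 == 0.0:  # decoupled special case: v built from the other column
        v1 = np.array([lam1 - a22, b21], dtype=complex)
        v2 = np.array([0.0, 1.0], dtype=complex) if b21 == 0 else v2
    det = v1[0] * v2[1] - v2[0] * v1[1]
    c1 = (m_a * v2[1] - m_b * v2[0]) / det
    c2 = (m_b * v1[0] - m_a * v1[1]) / det
    w1 = c1 * (v1[0] + v1[1])
    w2 = c2 * (v2[0] + v2[1])
    return w1 * np.exp(lam1 * t) + w2 * np.exp(lam2 * t)


def two_site_matrix_exp(
    k_ab: float, k_ba: float, omega_a: float, omega_b: float, R2: float, tau: float
) -> np.ndarray:
    """exp(G tau) of the 2x2 two-site generator via the hand eigensystem."""
    a11 = -2j * math.pi * omega_a - R2 - k_ab
    a22 = -2j * math.pi * omega_b - R2 - k_ba
    b12, b21 = k_ba, k_ab
    lam1, lam2 = two_site_eigensystem(a11, a22, b12, b21)
    if abs(lam1 - lam2) < 1e-12 * max(abs(lam1), 1.0):
        return cmath.exp(lam1 * tau) * np.eye(2)
    G = np.array([[a11, b12], [b21, a22]], dtype=complex)
    # spectral decomposition exp(G t) = e^{l1 t} P1 + e^{l2 t} P2 with
    # projectors P_i = (G - l_j I) / (l_i - l_j)
    I = np.eye(2, dtype=complex)
    P1 = (G - lam2 * I) / (lam1 - lam2)
    P2 = (G - lam1 * I) / (lam2 - lam1)
    return cmath.exp(lam1 * tau) * P1 + cmath.exp(lam2 * tau) * P2


# --- test-local spectrum processing ----------------------------------------


def process_fid(fid: np.ndarray, dwell: float, zero_fill: int = 2,
                apodize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Restated processing conventions: window, halve first point, FFT.

    Returns (frequency axis, real spectrum) with a -iW-evolving species
    appearing at +W Hz.
    """
    n = len(fid)
    proc = fid.astype(complex).copy()
    if apodize:
        proc *= np.cos(0.5 * math.pi * np.arange(n) / (n - 1))
    proc[0] *= 0.5
    n_total = n * zero_fill
    spec = np.fft.fftshift(np.fft.fft(np.conj(proc), n=n_total))
    freq = np.fft.fftshift(np.fft.fftfreq(n_total, d=dwell))
    return freq, spec.real
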
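"""Shared forward model: bilinear neural dynamics and balloon-Windkessel
hemodynamics.

This is the single implementation used both to *generate* synthetic BOLD
data and to *predict* BOLD during model inversion, so that the generator
is, by construction, a point in the inversion's model space.

Neural model (per region vector z, external inputs u):

    dz/dt = (A + sum_j u_j B_j) z + C u

Hemodynamics (per region; vasodilatory signal s, flow f, volume v,
deoxyhemoglobin q; f, v, q integrated in log space for positivity):

    ds/dt = z - kappa * s - gamma * (f - 1)
    df/dt = s
    tau dv/dt = f - v**(1/alpha)
    tau dq/dt = f * E(f, rho)/rho - v**(1/alpha) * q / v
    E(f, rho) = 1 - (1 - rho)**(1/f)

BOLD (percent signal change):

    y = 100 * V0 * (k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v))
    k1 = 7 rho, k2 = 2, k3 = 2 rho - 0.2

Integration is fixed-step 4th-order Runge-Kutta on a fine grid with
piecewise-constant inputs; scan-rate series are obtained by decimation at
scan onsets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import GroundTruth, HemodynamicParams, ground_truth_stable

__all__ = [
    "simulate_neural_states",
    "simulate_bold_fine",
    "decimate",
    "predict_bold_scans",
    "hemo_arrays",
]


@njit(cache=True)
def _neural_rk4(A, Bstack, C, U, dt):  # pragma: no cover - jitted
    n_fine, n_inputs = U.shape
    n = A.shape[0]
    Z = np.zeros((n_fine, n))
    z = np.zeros(n)
    M = np.empty((n, n))
    drive = np.empty(n)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    zt = np.empty(n)
    for t in range(n_fine - 1):
        # effective coupling and drive for this (piecewise-constant) bin
        for i in range(n):
            for j in range(n):
                M[i, j] = A[i, j]
                for m in range(n_inputs):
                    M[i, j] += U[t, m] * Bstack[m, i, j]
            acc = 0.0
            for m in range(n_inputs):
                acc += C[i, m] * U[t, m]
            drive[i] = acc
        for i in range(n):
            k1[i] = 0.0
            for j in range(n):
                k1[i] += M[i, j] * z[j]
            k1[i] += drive[i]
        for i in range(n):
            zt[i] = z[i] + 0.5 * dt * k1[i]
        for i in range(n):
            k2[i] = 0.0
            for j in range(n):
                k2[i] += M[i, j] * zt[j]
            k2[i] += drive[i]
        for i in range(n):
            zt[i] = z[i] + 0.5 * dt * k2[i]
        for i in range(n):
            k3[i] = 0.0
            for j in range(n):
                k3[i] += M[i, j] * zt[j]
            k3[i] += drive[i]
        for i in range(n):
            zt[i] = z[i] + dt * k3[i]
        for i in range(n):
            k4[i] = 0.0
            for j in range(n):
                k4[i] += M[i, j] * zt[j]
            k4[i] += drive[i]
        for i in range(n):
            z[i] = z[i] + dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        Z[t + 1] = z
    return Z


@njit(cache=True)
def _hemo_deriv(z, s, lf, lv, lq, kappa, gamma, tau, alpha, rho):
    # pragma: no cover - jitted
    f = np.exp(lf)
    v = np.exp(lv)
    q = np.exp(lq)
    E = 1.0 - (1.0 - rho) ** (1.0 / f)
    fv = v ** (1.0 / alpha)
    ds = z - kappa * s - gamma * (f - 1.0)
    dlf = s / f
    dlv = (f - fv) / (tau * v)
    dlq = (f * E / rho - fv * q / v) / (tau * q)
    return ds, dlf, dlv, dlq


@njit(cache=True)
def _balloon_rk4(Z, dt, kappa, gamma, tau, alpha, rho, V0):
    # pragma: no cover - jitted
    n_fine, n = Z.shape
    Y = np.zeros((n_fine, n))
    for i in range(n):
        k1b = 7.0 * rho[i]
        k2b = 2.0
        k3b = 2.0 * rho[i] - 0.2
        s = 0.0
        lf = 0.0
        lv = 0.0
        lq = 0.0
        for t in range(n_fine):
            v = np.exp(lv)
            q = np.exp(lq)
            Y[t, i] = (
                100.0
                * V0[i]
                * (k1b * (1.0 - q) + k2b * (1.0 - q / v) + k3b * (1.0 - v))
            )
            if t == n_fine - 1:
                break
            z = Z[t, i]  # piecewise-constant neural drive over the bin
            a1, b1, c1, d1 = _hemo_deriv(
                z, s, lf, lv, lq, kappa[i], gamma[i], tau[i], alpha[i], rho[i]
            )
            a2, b2, c2, d2 = _hemo_deriv(
                z,
                s + 0.5 * dt * a1,
                lf + 0.5 * dt * b1,
                lv + 0.5 * dt * c1,
                lq + 0.5 * dt * d1,
                kappa[i],
                gamma[i],
                tau[i],
                alpha[i],
                rho[i],
            )
            a3, b3, c3, d3 = _hemo_deriv(
                z,
                s + 0.5 * dt * a2,
                lf + 0.5 * dt * b2,
                lv + 0.5 * dt * c2,
                lq + 0.5 * dt * d2,
                kappa[i],
                gamma[i],
                tau[i],
                alpha[i],
                rho[i],
            )
            a4, b4, c4, d4 = _hemo_deriv(
                z,
                s + dt * a3,
                lf + dt * b3,
                lv + dt * c3,
                lq + dt * d3,
                kappa[i],
                gamma[i],
                tau[i],
                alpha[i],
                rho[i],
            )
            s += dt / 6.0 * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
            lf += dt / 6.0 * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
            lv += dt / 6.0 * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
            lq += dt / 6.0 * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        Y[n_fine - 1, i] = (
            100.0
            * V0[i]
            * (
                k1b * (1.0 - np.exp(lq))
                + k2b * (1.0 - np.exp(lq - lv))
                + k3b * (1.0 - np.exp(lv))
            )
        )
    return Y


def simulate_neural_states(
    A: np.ndarray,
    B: list[np.ndarray] | np.ndarray,
    C: np.ndarray,
    U: np.ndarray,
    fine_dt: float,
    check_stability: bool = True,
) -> np.ndarray:
    """Integrate the bilinear neural model from rest.

    Parameters are the fixed coupling ``A`` (n x n, Hz), per-input
    modulations ``B`` and driving weights ``C`` (n x n_inputs); ``U`` holds
    the inputs on the fine grid (n_fine x n_inputs, piecewise constant).
    Returns neuronal states (n_fine x n).  Refuses unstable systems.
    """
    A = np.asarray(A, float)
    Bstack = np.asarray(B, float)
    if Bstack.ndim == 2:
        Bstack = Bstack[None]
    C = np.asarray(C, float)
    U = np.ascontiguousarray(np.atleast_2d(U), dtype=float)
    if U.shape[1] != C.shape[1] or Bstack.shape[0] != C.shape[1]:
        raise ValueError("inputs, B and C disagree on the number of inputs")
    if check_stability and not ground_truth_stable(A, list(Bstack)):
        raise ValueError("unstable neural system: Re(eig) >= 0 for some input state")
    return _neural_rk4(
        np.ascontiguousarray(A), np.ascontiguousarray(Bstack), np.ascontiguousarray(C), U, float(fine_dt)
    )


def hemo_arrays(
    hemo: HemodynamicParams, n_regions: int = 2, scale: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Per-region hemodynamic parameter arrays, optionally with per-region
    log-scaling factors for kappa and tau (used during inversion)."""
    out = {
        name: np.full(n_regions, getattr(hemo, name), dtype=float)
        for name in ("kappa", "gamma", "tau", "alpha", "rho", "V0")
    }
    if scale is not None:
        scale = np.asarray(scale, float).reshape(2, n_regions)
        out["kappa"] = out["kappa"] * np.exp(scale[0])
        out["tau"] = out["tau"] * np.exp(scale[1])
    return out


def simulate_bold_fine(
    Z: np.ndarray, hemo: dict[str, np.ndarray] | HemodynamicParams, fine_dt: float
) -> np.ndarray:
    """Balloon-Windkessel BOLD (percent signal) on the fine grid."""
    Z = np.ascontiguousarray(np.atleast_2d(Z), dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("neural states contain non-finite values")
    if isinstance(hemo, HemodynamicParams):
        bad = hemo.validate()
        if bad:
            raise ValueError("; ".join(bad))
        hemo = hemo_arrays(hemo, Z.shape[1])
    return _balloon_rk4(
        Z,
        float(fine_dt),
        hemo["kappa"],
        hemo["gamma"],
        hemo["tau"],
        hemo["alpha"],
        hemo["rho"],
        hemo["V0"],
    )


def decimate(fine_series: np.ndarray, n_sub: int) -> np.ndarray:
    """Sample a fine-grid series at scan onsets (every ``n_sub``-th point)."""
    return np.asarray(fine_series)[::n_sub]


def predict_bold_scans(
    A: np.ndarray,
    B: list[np.ndarray] | np.ndarray,
    C: np.ndarray,
    U: np.ndarray,
    fine_dt: float,
    tr: float,
    hemo: dict[str, np.ndarray] | HemodynamicParams,
    check_stability: bool = True,
) -> np.ndarray:
    """Scan-sampled BOLD prediction for one parameter set (n_scans x n)."""
    n_sub = round(tr / fine_dt)
    if abs(n_sub * fine_dt - tr) > 1e-9:
        raise ValueError("fine_dt must divide TR")
    Z = simulate_neural_states(A, B, C, U, fine_dt, check_stability=check_stability)
    Y = simulate_bold_fine(Z, hemo, fine_dt)
    return decimate(Y, n_sub)


def simulate_truth(truth: GroundTruth, U: np.ndarray, fine_dt: float, tr: float) -> np.ndarray:
    """Noiseless scan-sampled BOLD for a ground-truth parameter set."""
    return predict_bold_scans(truth.A, truth.B, truth.C, U, fine_dt, tr, truth.hemo)
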
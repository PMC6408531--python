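"""Jit-compiled Kalman filter/smoother cores.

Two small fixed-size filters: a 4-dimensional-state filter with 2-dimensional
observations for the paired-location movement models, and a 2-dimensional
(position, velocity) filter with scalar observations for the integrated
Ornstein-Uhlenbeck model.  Both return the exact marginal log-likelihood via
the innovation decomposition; companion routines run fixed-interval
Rauch-Tung-Striebel smoothing.  Covariance updates use the Joseph form, which
stays positive semidefinite under the diffuse initialization.  The 4x4
products are unrolled explicitly: at this size the loop code beats generic
matrix-multiply dispatch by a wide margin inside the optimizer hot path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True, inline="always")
def _mm4(A, B, out):  # pragma: no cover - jit
    for i in range(4):
        for j in range(4):
            s = 0.0
            for k in range(4):
                s += A[i, k] * B[k, j]
            out[i, j] = s


@njit(cache=True, inline="always")
def _mmt4(A, B, out):  # pragma: no cover - jit  (A @ B.T)
    for i in range(4):
        for j in range(4):
            s = 0.0
            for k in range(4):
                s += A[i, k] * B[j, k]
            out[i, j] = s


@njit(cache=True)
def filter4(a0, P0, T, c, Q, obs_state, H, y, R, n_states, store):
    """Filter the 4-state system; returns (loglik, ok, pred/filt moments).

    ``obs_state`` must be sorted.  When ``store`` is False the moment arrays
    are allocated with length 1 and only the log-likelihood is meaningful.
    """
    m = obs_state.shape[0]
    ns = n_states if store else 1
    pred_a = np.zeros((ns, 4))
    pred_P = np.zeros((ns, 4, 4))
    filt_a = np.zeros((ns, 4))
    filt_P = np.zeros((ns, 4, 4))
    a = a0.copy()
    P = P0.copy()
    tmp = np.empty((4, 4))
    tmp2 = np.empty((4, 4))
    ll = 0.0
    ok = True
    j = 0
    for k in range(n_states):
        if k > 0:
            Tk = T[k - 1]
            an = np.empty(4)
            for i in range(4):
                s = c[k - 1, i]
                for q_ in range(4):
                    s += Tk[i, q_] * a[q_]
                an[i] = s
            a = an
            _mm4(Tk, P, tmp)
            _mmt4(tmp, Tk, tmp2)
            Qk = Q[k - 1]
            for i in range(4):
                for q_ in range(4):
                    P[i, q_] = tmp2[i, q_] + Qk[i, q_]
        if store:
            pred_a[k] = a
            pred_P[k] = P
        while j < m and obs_state[j] == k:
            Hj = H[j]
            PHt = np.empty((4, 2))
            for r_ in range(4):
                for c_ in range(2):
                    acc = 0.0
                    for q_ in range(4):
                        acc += P[r_, q_] * Hj[c_, q_]
                    PHt[r_, c_] = acc
            S00 = R[j, 0, 0]
            S01 = R[j, 0, 1]
            S11 = R[j, 1, 1]
            for q_ in range(4):
                S00 += Hj[0, q_] * PHt[q_, 0]
                S01 += Hj[0, q_] * PHt[q_, 1]
                S11 += Hj[1, q_] * PHt[q_, 1]
            det = S00 * S11 - S01 * S01
            if det <= 0.0 or not np.isfinite(det):
                ok = False
                return -np.inf, ok, pred_a, pred_P, filt_a, filt_P
            v0 = y[j, 0]
            v1 = y[j, 1]
            for q_ in range(4):
                v0 -= Hj[0, q_] * a[q_]
                v1 -= Hj[1, q_] * a[q_]
            i00 = S11 / det
            i01 = -S01 / det
            i11 = S00 / det
            quad = v0 * (i00 * v0 + i01 * v1) + v1 * (i01 * v0 + i11 * v1)
            ll += -LOG2PI - 0.5 * np.log(det) - 0.5 * quad
            # K = P H^T S^{-1}
            K = np.empty((4, 2))
            for r_ in range(4):
                K[r_, 0] = PHt[r_, 0] * i00 + PHt[r_, 1] * i01
                K[r_, 1] = PHt[r_, 0] * i01 + PHt[r_, 1] * i11
            for r_ in range(4):
                a[r_] += K[r_, 0] * v0 + K[r_, 1] * v1
            # Joseph form: (I-KH) P (I-KH)' + K R K'
            IKH = np.empty((4, 4))
            for r_ in range(4):
                for c_ in range(4):
                    IKH[r_, c_] = (1.0 if r_ == c_ else 0.0) - (
                        K[r_, 0] * Hj[0, c_] + K[r_, 1] * Hj[1, c_]
                    )
            _mm4(IKH, P, tmp)
            _mmt4(tmp, IKH, tmp2)
            Rj = R[j]
            for r_ in range(4):
                kr0 = K[r_, 0] * Rj[0, 0] + K[r_, 1] * Rj[1, 0]
                kr1 = K[r_, 0] * Rj[0, 1] + K[r_, 1] * Rj[1, 1]
                for c_ in range(4):
                    P[r_, c_] = tmp2[r_, c_] + kr0 * K[c_, 0] + kr1 * K[c_, 1]
            j += 1
        if store:
            filt_a[k] = a
            filt_P[k] = P
    return ll, ok, pred_a, pred_P, filt_a, filt_P


@njit(cache=True)
def smooth4(T, pred_a, pred_P, filt_a, filt_P):
    """Rauch-Tung-Striebel pass; returns smoothed means and covariances."""
    n = filt_a.shape[0]
    sm_a = np.zeros((n, 4))
    sm_P = np.zeros((n, 4, 4))
    sm_a[n - 1] = filt_a[n - 1]
    sm_P[n - 1] = filt_P[n - 1]
    for k in range(n - 2, -1, -1):
        Tk = T[k]
        # J = filt_P[k] T^T pred_P[k+1]^{-1}
        J = np.linalg.solve(pred_P[k + 1].T, (filt_P[k] @ Tk.T).T).T
        sm_a[k] = filt_a[k] + J @ (sm_a[k + 1] - pred_a[k + 1])
        dP = sm_P[k + 1] - pred_P[k + 1]
        sm_P[k] = filt_P[k] + J @ dP @ J.T
    return sm_a, sm_P


@njit(cache=True)
def filter2(a0, P0, T, c, Q, obs_state, h_var, y, n_states, store):
    """Scalar-observation filter for a 2-dimensional (x, v) state.

    Observation ``j`` loads on the position component of state
    ``obs_state[j]`` with noise variance ``h_var[j]``.
    """
    m = obs_state.shape[0]
    ns = n_states if store else 1
    pred_a = np.zeros((ns, 2))
    pred_P = np.zeros((ns, 2, 2))
    filt_a = np.zeros((ns, 2))
    filt_P = np.zeros((ns, 2, 2))
    a = a0.copy()
    P = P0.copy()
    ll = 0.0
    ok = True
    j = 0
    for k in range(n_states):
        if k > 0:
            t00 = T[k - 1, 0, 0]
            t01 = T[k - 1, 0, 1]
            t10 = T[k - 1, 1, 0]
            t11 = T[k - 1, 1, 1]
            a0_ = t00 * a[0] + t01 * a[1] + c[k - 1, 0]
            a1_ = t10 * a[0] + t11 * a[1] + c[k - 1, 1]
            a = np.array([a0_, a1_])
            p00 = t00 * P[0, 0] + t01 * P[1, 0]
            p01 = t00 * P[0, 1] + t01 * P[1, 1]
            p10 = t10 * P[0, 0] + t11 * P[1, 0]
            p11 = t10 * P[0, 1] + t11 * P[1, 1]
            Pn = np.empty((2, 2))
            Pn[0, 0] = p00 * t00 + p01 * t01 + Q[k - 1, 0, 0]
            Pn[0, 1] = p00 * t10 + p01 * t11 + Q[k - 1, 0, 1]
            Pn[1, 0] = p10 * t00 + p11 * t01 + Q[k - 1, 1, 0]
            Pn[1, 1] = p10 * t10 + p11 * t11 + Q[k - 1, 1, 1]
            P = Pn
        if store:
            pred_a[k] = a
            pred_P[k] = P
        while j < m and obs_state[j] == k:
            F = P[0, 0] + h_var[j]
            if F <= 0.0 or not np.isfinite(F):
                ok = False
                return -np.inf, ok, pred_a, pred_P, filt_a, filt_P
            v = y[j] - a[0]
            ll += -0.5 * (LOG2PI + np.log(F) + v * v / F)
            k0 = P[0, 0] / F
            k1 = P[1, 0] / F
            a = np.array([a[0] + k0 * v, a[1] + k1 * v])
            # Joseph form with H = [1, 0]
            b00 = 1.0 - k0
            Pn = np.empty((2, 2))
            Pn[0, 0] = b00 * b00 * P[0, 0] + k0 * k0 * h_var[j]
            Pn[0, 1] = b00 * (P[0, 1] - k1 * P[0, 0]) + k0 * k1 * h_var[j]
            Pn[1, 0] = Pn[0, 1]
            Pn[1, 1] = (
                P[1, 1]
                - 2.0 * k1 * P[0, 1]
                + k1 * k1 * P[0, 0]
                + k1 * k1 * h_var[j]
            )
            P = Pn
            j += 1
        if store:
            filt_a[k] = a
            filt_P[k] = P
    return ll, ok, pred_a, pred_P, filt_a, filt_P


@njit(cache=True)
def smooth2(T, pred_a, pred_P, filt_a, filt_P):
    n = filt_a.shape[0]
    sm_a = np.zeros((n, 2))
    sm_P = np.zeros((n, 2, 2))
    sm_a[n - 1] = filt_a[n - 1]
    sm_P[n - 1] = filt_P[n - 1]
    for k in range(n - 2, -1, -1):
        Tk = T[k]
        J = np.linalg.solve(pred_P[k + 1].T, (filt_P[k] @ Tk.T).T).T
        sm_a[k] = filt_a[k] + J @ (sm_a[k + 1] - pred_a[k + 1])
        dP = sm_P[k + 1] - pred_P[k + 1]
        sm_P[k] = filt_P[k] + J @ dP @ J.T
    return sm_a, sm_P
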
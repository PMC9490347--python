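"""Compiled hot path for the energy + gradient evaluation.

The L-BFGS search evaluates the full functional thousands of times per
minimization; this module provides a numba-compiled single-pass kernel that
is numerically identical (to round-off) to the vectorized assembly in
:mod:`bundlemech.energy`, which remains the readable reference and is
cross-checked against this kernel in the test suite.  If numba is
unavailable the package transparently falls back to the numpy path.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(fn):
            return fn
        return deco


@njit(cache=True, fastmath=False)
def energy_gradient_kernel(theta, l, d0, ddiag, A0, K, C1, C2, C3,
                           Nc, B, lat, clamped):
    """Total energy and dE/dtheta in one pass.

    Returns (energy, grad); a joint angle difference at +-pi yields
    (inf, zeros).  ``lat`` is the (m, n) lateral-load table, ``B`` the
    per-filament bending stiffness.
    """
    m, n = theta.shape
    grad = np.zeros((m, n))

    # bending (direct angle dependence) + singularity guard
    E = 0.0
    for i in range(m):
        bi = 2.0 * B[i] / l
        for j in range(1, n):
            dt = theta[i, j] - theta[i, j - 1]
            if abs(dt) >= math.pi - 1e-9:
                return np.inf, np.zeros((m, n))
            t = math.tan(0.5 * dt)
            c = math.cos(0.5 * dt)
            E += bi * t * t
            dEd = bi * t / (c * c)
            grad[i, j] += dEd
            grad[i, j - 1] -= dEd

    # node coordinates
    x = np.empty((m, n + 1))
    y = np.empty((m, n + 1))
    for i in range(m):
        cx = 0.0
        cy = i * d0
        x[i, 0] = cx
        y[i, 0] = cy
        for j in range(n):
            cx += l * math.cos(theta[i, j])
            cy += l * math.sin(theta[i, j])
            x[i, j + 1] = cx
            y[i, j + 1] = cy

    Fx = np.zeros((m, n + 1))
    Fy = np.zeros((m, n + 1))
    half_lK = 0.5 * l * K

    # vertical springs, rest length d0
    inv_d0sq = 1.0 / (d0 * d0)
    for i in range(m - 1):
        for j in range(n + 1):
            vx = x[i + 1, j] - x[i, j]
            vy = y[i + 1, j] - y[i, j]
            dist = math.sqrt(vx * vx + vy * vy)
            ext = dist - d0
            E += half_lK * ext * ext * inv_d0sq
            if dist > 0.0:
                coef = l * K * ext * inv_d0sq / dist
                fx = coef * vx
                fy = coef * vy
                Fx[i + 1, j] += fx
                Fy[i + 1, j] += fy
                Fx[i, j] -= fx
                Fy[i, j] -= fy

    # diagonal springs, rest length ddiag
    inv_ddsq = 1.0 / (ddiag * ddiag)
    for i in range(m - 1):
        for j in range(n):
            # forward diagonal: (i, j) -> (i+1, j+1)
            vx = x[i + 1, j + 1] - x[i, j]
            vy = y[i + 1, j + 1] - y[i, j]
            dist = math.sqrt(vx * vx + vy * vy)
            ext = dist - ddiag
            E += half_lK * ext * ext * inv_ddsq
            if dist > 0.0:
                coef = l * K * ext * inv_ddsq / dist
                fx = coef * vx
                fy = coef * vy
                Fx[i + 1, j + 1] += fx
                Fy[i + 1, j + 1] += fy
                Fx[i, j] -= fx
                Fy[i, j] -= fy
            # backward diagonal: (i, j+1) -> (i+1, j)
            vx = x[i + 1, j] - x[i, j + 1]
            vy = y[i + 1, j] - y[i, j + 1]
            dist = math.sqrt(vx * vx + vy * vy)
            ext = dist - ddiag
            E += half_lK * ext * ext * inv_ddsq
            if dist > 0.0:
                coef = l * K * ext * inv_ddsq / dist
                fx = coef * vx
                fy = coef * vy
                Fx[i + 1, j] += fx
                Fy[i + 1, j] += fy
                Fx[i, j + 1] -= fx
                Fy[i, j + 1] -= fy

    # overlap penalty on both triangles of each quad
    c2a = C2 / A0
    for i in range(m - 1):
        for j in range(n):
            u1x = x[i + 1, j] - x[i, j]
            u1y = y[i + 1, j] - y[i, j]
            wx = x[i + 1, j + 1] - x[i, j]
            wy = y[i + 1, j + 1] - y[i, j]
            u2x = x[i + 1, j + 1] - x[i, j + 1]
            u2y = y[i + 1, j + 1] - y[i, j + 1]

            cross = u1x * wy - u1y * wx
            A = 0.5 * abs(cross)
            s = 1.0 if cross > 0.0 else (-1.0 if cross < 0.0 else 0.0)
            g = C1 * math.exp(-c2a * A)
            E += g
            dEdA = -c2a * g
            gux = 0.5 * dEdA * s * wy
            guy = -0.5 * dEdA * s * wx
            gwx = -0.5 * dEdA * s * u1y
            gwy = 0.5 * dEdA * s * u1x
            Fx[i + 1, j] += gux
            Fy[i + 1, j] += guy
            Fx[i + 1, j + 1] += gwx
            Fy[i + 1, j + 1] += gwy
            Fx[i, j] -= gux + gwx
            Fy[i, j] -= guy + gwy

            cross = u2x * wy - u2y * wx
            A = 0.5 * abs(cross)
            s = 1.0 if cross > 0.0 else (-1.0 if cross < 0.0 else 0.0)
            g = C1 * math.exp(-c2a * A)
            E += g
            dEdA = -c2a * g
            gux = 0.5 * dEdA * s * wy
            guy = -0.5 * dEdA * s * wx
            gwx = -0.5 * dEdA * s * u2y
            gwy = 0.5 * dEdA * s * u2x
            Fx[i + 1, j + 1] += gux + gwx
            Fy[i + 1, j + 1] += guy + gwy
            Fx[i, j + 1] -= gux
            Fy[i, j + 1] -= guy
            Fx[i, j] -= gwx
            Fy[i, j] -= gwy

    # loads and pinned penalty
    for i in range(m):
        E += Nc * x[i, n]
        Fx[i, n] += Nc
        for j in range(1, n + 1):
            E += lat[i, j - 1] * (y[i, j] - y[i, 0])
            Fy[i, j] += lat[i, j - 1]
        dy = y[i, n] - y[i, 0]
        E += C3 * dy * dy
        Fy[i, n] += 2.0 * C3 * dy

    # chain rule: node j moves with angle k iff j >= k
    for i in range(m):
        sx = 0.0
        sy = 0.0
        for j in range(n, 0, -1):
            sx += Fx[i, j]
            sy += Fy[i, j]
            grad[i, j - 1] += l * (
                -math.sin(theta[i, j - 1]) * sx
                + math.cos(theta[i, j - 1]) * sy
            )

    if clamped:
        for i in range(m):
            E += C3 * (theta[i, 0] ** 2 + theta[i, n - 1] ** 2)
            grad[i, 0] += 2.0 * C3 * theta[i, 0]
            grad[i, n - 1] += 2.0 * C3 * theta[i, n - 1]

    return E, grad
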
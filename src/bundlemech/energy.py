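"""The bundle energy functional, its analytic gradient, and internal pressures.

Total energy::

    E = Eb + Ee + El + Ec

* ``Eb``   — discrete bending energy, sum over interior joints of
  ``(2 B_i/l) tan^2((theta_ij - theta_i(j-1))/2)``: the circumscribed-circle
  curvature ``kappa = (2/l) tan(dtheta/2)`` in ``(B/2) kappa^2 l`` per joint.
* ``Ee``   — elastic-matrix interaction: Hookean springs between vertical
  neighbours (``Ee1``) and along both diagonals of each quad (``Ee1+``,
  ``Ee1-``), plus an exponential overlap penalty on the quad triangle areas
  (``Ee2 = sum g(A)``, ``g(A) = C1 exp(-C2 A/A0)``).
* ``El``   — loading potentials: axial compression ``Nc`` acting on the free
  filament ends, and a lateral pinching load on the outer filaments.
* ``Ec``   — stiff quadratic penalties imposing pinned (equal end heights)
  and, for clamped bundles, horizontal end tangents.

The gradient with respect to the angles is assembled analytically: every
coordinate-dependent term first contributes a force ``dE/d(node position)``;
the chain rule through the cumulative-sum geometry then reduces to a reversed
cumulative sum of those forces (node j moves with segment k iff j >= k).
Bending and clamping act on the angles directly.  Finite differences are the
test-suite oracle for the whole assembly.

A joint angle difference approaching +-pi makes the bending tangent singular;
such states are reported as non-finite energy (the minimizer's line search
then backtracks) rather than silently clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import BundleGeometry, BundleState, ModelParams, build_geometry

__all__ = [
    "EnergyBreakdown",
    "bending_energy",
    "spring_energy",
    "overlap_penalty",
    "overlap_energy",
    "loading_energy",
    "constraint_energy",
    "total_energy",
    "energy_and_gradient",
    "energy_gradient",
    "interaction_pressure",
]

# Angle differences with |diff| >= pi - _TAN_GUARD are treated as singular.
_TAN_GUARD = 1e-9


@dataclass
class EnergyBreakdown:
    """Per-term energies; ``total`` is their sum (non-finite on tan blow-up)."""

    Eb: float
    Ee1: float
    Ee1_plus: float
    Ee1_minus: float
    Ee2: float
    El1: float
    El2: float
    Ec1: float
    Ec2: float
    total: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# individual terms
# ---------------------------------------------------------------------------

def bending_energy(params: ModelParams, state: BundleState):
    """Bending energy per filament and total.

    Returns ``(per_filament, total)``; the total is ``inf`` if any joint
    angle difference reaches +-pi.
    """
    dtheta = np.diff(state.theta, axis=1)
    B = params.bending_stiffness()
    if np.any(np.abs(dtheta) >= np.pi - _TAN_GUARD):
        per = np.full(params.m, np.inf)
        return per, np.inf
    # circumscribed-circle curvature kappa = (2/l) tan(dtheta/2), so the
    # per-joint energy (B/2) kappa^2 l carries the prefactor 2B/l
    t2 = np.tan(0.5 * dtheta) ** 2
    per = (2.0 * B / params.l) * t2.sum(axis=1)
    return per, float(per.sum())


def _hooke(dist: np.ndarray, rest: float, K: float, l: float) -> float:
    return float(l * 0.5 * K * (((dist - rest) / rest) ** 2).sum())


def spring_energy(params: ModelParams, geom: BundleGeometry):
    """Hookean matrix energies (Ee1, Ee1+, Ee1-), densities per unit length."""
    K, l = params.K, params.l
    Ee1 = _hooke(geom.d, params.d0, K, l)
    Ee1p = _hooke(geom.d_plus, params.d0_diag, K, l)
    Ee1m = _hooke(geom.d_minus, params.d0_diag, K, l)
    return Ee1, Ee1p, Ee1m


def overlap_penalty(A, params: ModelParams):
    """g(A) = C1 exp(-C2 A / A0): diverging-at-contact area penalty."""
    return params.C1 * np.exp(-params.C2 * np.asarray(A, dtype=float) / params.A0)


def overlap_energy(params: ModelParams, geom: BundleGeometry) -> float:
    """Ee2: sum of g over both triangles of every quad."""
    return float(overlap_penalty(geom.areas, params).sum())


def loading_energy(params: ModelParams, geom: BundleGeometry):
    """(El1, El2): axial load potential and lateral pinching potential."""
    El1 = float(params.Nc * geom.coords[:, -1, 0].sum())
    table = params.lateral_load_table()
    dy = geom.coords[:, 1:, 1] - geom.coords[:, 0, 1][:, None]
    El2 = float((table * dy).sum())
    return El1, El2


def constraint_energy(params: ModelParams, geom: BundleGeometry,
                      state: BundleState):
    """(Ec1, Ec2): pinned end-height penalty; clamped end-tangent penalty."""
    dy_end = geom.coords[:, -1, 1] - geom.coords[:, 0, 1]
    Ec1 = float(params.C3 * (dy_end ** 2).sum())
    Ec2 = 0.0
    if params.boundary == "clamped":
        Ec2 = float(
            params.C3 * ((state.theta[:, 0] ** 2).sum()
                         + (state.theta[:, -1] ** 2).sum())
        )
    return Ec1, Ec2


def total_energy(params: ModelParams, state: BundleState) -> EnergyBreakdown:
    """Assemble the geometry once and sum every energy term."""
    geom = build_geometry(params, state)
    _, Eb = bending_energy(params, state)
    Ee1, Ee1p, Ee1m = spring_energy(params, geom)
    Ee2 = overlap_energy(params, geom)
    El1, El2 = loading_energy(params, geom)
    Ec1, Ec2 = constraint_energy(params, geom, state)
    total = Eb + Ee1 + Ee1p + Ee1m + Ee2 + El1 + El2 + Ec1 + Ec2
    return EnergyBreakdown(Eb, Ee1, Ee1p, Ee1m, Ee2, El1, El2, Ec1, Ec2, total)


# ---------------------------------------------------------------------------
# gradient assembly
# ---------------------------------------------------------------------------

def _interaction_forces(params: ModelParams, coords: np.ndarray) -> np.ndarray:
    """dEe/d(coords) for the interaction terms Ee1 + Ee1+/- + Ee2 only."""
    F = np.zeros_like(coords)
    K, l = params.K, params.l

    def spring_force(vec, rest):
        dist = np.linalg.norm(vec, axis=-1)
        coef = l * K * (dist - rest) / rest ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dist[..., None] > 0, vec / dist[..., None], 0.0)
        return coef[..., None] * unit

    f = spring_force(coords[1:] - coords[:-1], params.d0)
    F[1:] += f
    F[:-1] -= f
    f = spring_force(coords[1:, 1:] - coords[:-1, :-1], params.d0_diag)
    F[1:, 1:] += f
    F[:-1, :-1] -= f
    f = spring_force(coords[1:, :-1] - coords[:-1, 1:], params.d0_diag)
    F[1:, :-1] += f
    F[:-1, 1:] -= f

    # Overlap: A = |cross(u, w)|/2, dg/dA = -(C2/A0) g(A).
    u1 = coords[1:, :-1] - coords[:-1, :-1]
    w = coords[1:, 1:] - coords[:-1, :-1]
    u2 = coords[1:, 1:] - coords[:-1, 1:]

    def area_grads(u, wv):
        cross = u[..., 0] * wv[..., 1] - u[..., 1] * wv[..., 0]
        A = 0.5 * np.abs(cross)
        s = np.sign(cross)
        dEdA = -(params.C2 / params.A0) * params.C1 * np.exp(
            -params.C2 * A / params.A0
        )
        gu = 0.5 * dEdA[..., None] * np.stack(
            [s * wv[..., 1], -s * wv[..., 0]], axis=-1
        )
        gw = 0.5 * dEdA[..., None] * np.stack(
            [-s * u[..., 1], s * u[..., 0]], axis=-1
        )
        return gu, gw

    gu1, gw1 = area_grads(u1, w)     # triangle 1: u from (i,j), w from (i,j)
    F[1:, :-1] += gu1
    F[1:, 1:] += gw1
    F[:-1, :-1] -= gu1 + gw1
    gu2, gw2 = area_grads(u2, w)     # triangle 2: u into (i+1,j+1), w too
    F[1:, 1:] += gu2 + gw2
    F[:-1, 1:] -= gu2
    F[:-1, :-1] -= gw2
    return F


def _coordinate_forces(params: ModelParams, coords: np.ndarray) -> np.ndarray:
    """dE/d(coords) for every coordinate-dependent term."""
    F = _interaction_forces(params, coords)
    # axial load on the free ends
    F[:, -1, 0] += params.Nc
    # lateral loads on nodes j = 1..n (node 0 is fixed; its force never
    # propagates to an angle)
    F[:, 1:, 1] += params.lateral_load_table()
    # pinned penalty
    dy_end = coords[:, -1, 1] - coords[:, 0, 1]
    F[:, -1, 1] += 2.0 * params.C3 * dy_end
    return F


def _chain_to_angles(params: ModelParams, state: BundleState,
                     F: np.ndarray) -> np.ndarray:
    """Chain-rule coordinate forces through the cumulative-sum geometry.

    d(node j)/d(theta_k) = l(-sin theta_k, cos theta_k) for j >= k, so the
    angle gradient is a reversed cumulative sum of node forces.
    """
    S = np.cumsum(F[:, ::-1], axis=1)[:, ::-1]        # S[:, k] = sum_{j>=k} F
    l = params.l
    return l * (
        -np.sin(state.theta) * S[:, 1:, 0] + np.cos(state.theta) * S[:, 1:, 1]
    )


def energy_and_gradient(params: ModelParams, state: BundleState,
                        use_kernel: bool = True):
    """(total energy, m x n gradient dE/dtheta); gradient zeroed if singular.

    Dispatches to the compiled single-pass kernel when available; the
    vectorized assembly below is the reference path (``use_kernel=False``)
    and agrees with the kernel to round-off.
    """
    if use_kernel and _kernels.HAVE_NUMBA:
        E, grad = _kernels.energy_gradient_kernel(
            np.ascontiguousarray(state.theta, dtype=float),
            params.l, params.d0, params.d0_diag, params.A0,
            params.K, params.C1, params.C2, params.C3, params.Nc,
            params.bending_stiffness(),
            np.ascontiguousarray(params.lateral_load_table()),
            params.boundary == "clamped",
        )
        return float(E), grad
    return _energy_and_gradient_numpy(params, state)


def _energy_and_gradient_numpy(params: ModelParams, state: BundleState):
    geom = build_geometry(params, state)
    dtheta = np.diff(state.theta, axis=1)
    if np.any(np.abs(dtheta) >= np.pi - _TAN_GUARD):
        return np.inf, np.zeros_like(state.theta)

    breakdown = _energy_from_geometry(params, geom, state)
    F = _coordinate_forces(params, geom.coords)
    grad = _chain_to_angles(params, state, F)

    # bending: direct angle dependence
    B = params.bending_stiffness()
    half = 0.5 * dtheta
    dEd = (2.0 * B[:, None] / params.l) * np.tan(half) / np.cos(half) ** 2
    grad[:, 1:] += dEd
    grad[:, :-1] -= dEd

    # clamped end-tangent penalty: direct angle dependence
    if params.boundary == "clamped":
        grad[:, 0] += 2.0 * params.C3 * state.theta[:, 0]
        grad[:, -1] += 2.0 * params.C3 * state.theta[:, -1]
    return breakdown.total, grad


def _energy_from_geometry(params: ModelParams, geom: BundleGeometry,
                          state: BundleState) -> EnergyBreakdown:
    _, Eb = bending_energy(params, state)
    Ee1, Ee1p, Ee1m = spring_energy(params, geom)
    Ee2 = overlap_energy(params, geom)
    El1, El2 = loading_energy(params, geom)
    Ec1, Ec2 = constraint_energy(params, geom, state)
    total = Eb + Ee1 + Ee1p + Ee1m + Ee2 + El1 + El2 + Ec1 + Ec2
    return EnergyBreakdown(Eb, Ee1, Ee1p, Ee1m, Ee2, El1, El2, Ec1, Ec2, total)


def energy_gradient(params: ModelParams, state: BundleState) -> np.ndarray:
    """Analytic gradient dE/dtheta_ij as an m x n matrix."""
    return energy_and_gradient(params, state)[1]


def interaction_pressure(params: ModelParams, state: BundleState) -> np.ndarray:
    """Internal pressure field: |dEe/d(node position)| at each node.

    Only the matrix interaction terms (springs + overlap penalty) enter, so
    the rest state has zero pressure everywhere.  Shape (m, n+1).
    """
    coords = build_geometry(params, state).coords
    F = _interaction_forces(params, coords)
    return np.linalg.norm(F, axis=-1)


def pressure_to_csv(params: ModelParams, state: BundleState, path) -> None:
    """Export the pressure field: columns filament,index,x,y,pressure."""
    import pandas as pd

    coords = build_geometry(params, state).coords
    p = interaction_pressure(params, state)
    m, npts = p.shape
    fil, idx = np.meshgrid(np.arange(1, m + 1), np.arange(npts), indexing="ij")
    pd.DataFrame(
        {
            "filament": fil.ravel(),
            "index": idx.ravel(),
            "x": coords[..., 0].ravel(),
            "y": coords[..., 1].ravel(),
            "pressure": p.ravel(),
        }
    ).to_csv(path, index=False)
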
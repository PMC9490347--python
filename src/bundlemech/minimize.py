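"""Multi-start local energy minimization with L-BFGS.

Stable configurations are local minima of the bundle energy.  Following the
multi-start strategy of the model, minimization is initialized from four
small-amplitude archetypal seeds — undeformed, globally buckled, pinched and
internally buckled — and each converged state is classified; minima from
different seeds that coincide (same label, energies within 1%) are merged,
while distinct labels within 1% of the lowest energy are reported as
co-minimal (bistable cells of the phase diagrams).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .classify import classify_state
from .energy import EnergyBreakdown, energy_and_gradient, total_energy
from .model import BundleState, ModelParams, rest_state

__all__ = [
    "MinimizationResult",
    "seed_state",
    "minimize_energy",
    "enumerate_minima",
    "SEED_KINDS",
    "SEED_AMPLITUDE",
    "PROBE_AMPLITUDE",
]

log = logging.getLogger(__name__)

SEED_KINDS = ("undeformed", "global", "pinched", "internal")
SEED_AMPLITUDE = 1e-2    # archetypal seed amplitude (rad)
PROBE_AMPLITUDE = 1e-3   # stability-probe perturbation amplitude (rad)
MERGE_RTOL = 0.01        # minima within 1% in energy may merge / tie


@dataclass
class MinimizationResult:
    state: BundleState
    energy: EnergyBreakdown
    converged: bool
    iterations: int
    grad_norm: float


def _segment_positions(params: ModelParams) -> np.ndarray:
    """Arc-length midpoints of the n segments."""
    return (np.arange(params.n) + 0.5) * params.l


def seed_state(kind: str, params: ModelParams,
               amplitude: float = SEED_AMPLITUDE,
               seed: int = 0) -> BundleState:
    """Construct one of the four archetypal starting configurations.

    * undeformed: all angles zero.
    * global: a single-arch profile theta = a cos(pi s / L), identical on
      every filament (the Euler shape's tangent angle).
    * pinched: the same profile with opposite signs on the two bundle
      halves, mirrored about the mid-row (antisymmetric, P = 1).
    * internal: a multi-arch profile theta = a env_i cos(w pi s / L) whose
      wavemode w comes from the kink-model optimal mode (rounded, >= 1) and
      whose lateral envelope env_i = sin(pi (i-1)/(m-1)) peaks at the bundle
      centre and vanishes on the outer filaments.

    Deterministic for a given ``seed`` (the seed only matters for future
    randomized variants; the archetypes themselves are noise-free).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if kind not in SEED_KINDS:
        raise ValueError(f"unknown seed kind {kind!r}")
    m, n = params.m, params.n
    theta = np.zeros((m, n))
    if kind == "undeformed":
        return BundleState(theta)
    s = _segment_positions(params)
    if kind == "global":
        theta[:] = amplitude * np.cos(np.pi * s / params.L)
    elif kind == "pinched":
        profile = amplitude * np.cos(np.pi * s / params.L)
        sign = np.sign(np.arange(m) - 0.5 * (m - 1))  # -1 lower, +1 upper
        theta[:] = -sign[:, None] * profile
    else:  # internal
        from .criterion import optimal_mode

        n_star, _, _ = optimal_mode(params.K, params.B_in, params.L)
        wavemode = max(1, int(round(n_star)))
        envelope = np.sin(np.pi * np.arange(m) / (m - 1))
        envelope[0] = envelope[-1] = 0.0  # outer filaments exactly straight
        theta[:] = (
            amplitude * envelope[:, None]
            * np.cos(wavemode * np.pi * s / params.L)
        )
    return BundleState(theta)


def minimize_energy(params: ModelParams, state0: BundleState,
                    tol: float = 1e-6,
                    max_iter: int = 20000,
                    bound: float | None = None) -> MinimizationResult:
    """L-BFGS minimization of the total energy from a given start.

    Converged means the gradient infinity-norm at the returned point is at
    most ``tol``.  A non-finite starting energy raises; non-finite energies
    met during the search are handled by the line search backtracking.

    ``bound`` restricts every angle to [-bound, bound] (L-BFGS-B box):
    stability probes use a tight box so the search cannot jump across basin
    boundaries, and follow-up minimizations a generous one to exclude
    non-locally folded states (which the local overlap penalty by
    construction does not forbid).
    """
    e0 = total_energy(params, state0).total
    if not np.isfinite(e0):
        raise ValueError("starting state has non-finite energy")
    shape = state0.theta.shape

    def fun(x):
        e, g = energy_and_gradient(params, BundleState(x.reshape(shape)))
        return e, g.ravel()

    x = state0.theta.ravel()
    bounds = None
    if bound is not None:
        x = np.clip(x, -bound, bound)
        bounds = [(-bound, bound)] * x.size
    nit = 0
    # restart with a fresh quasi-Newton memory when the line search
    # plateaus (ftol stop) before the gradient tolerance is met
    for _ in range(3):
        res = optimize.minimize(
            fun, x, jac=True, method="L-BFGS-B", bounds=bounds,
            options={
                "maxiter": max_iter - nit,
                "maxfun": 10 * max_iter,
                "gtol": tol,
                "ftol": 1e-14,
                "maxcor": 10,
            },
        )
        x = res.x
        nit += int(res.nit)
        if np.max(np.abs(res.jac)) <= tol or nit >= max_iter or res.nit == 0:
            break
    state = BundleState(x.reshape(shape))
    breakdown = total_energy(params, state)
    _, grad = energy_and_gradient(params, state)
    grad_norm = float(np.max(np.abs(grad)))
    if bound is not None:
        # at an active box face the projected gradient is what vanishes
        at_lo = np.isclose(x, -bound)
        at_hi = np.isclose(x, bound)
        g = grad.ravel().copy()
        g[at_lo] = np.minimum(g[at_lo], 0.0)
        g[at_hi] = np.maximum(g[at_hi], 0.0)
        grad_norm = float(np.max(np.abs(g)))
    converged = grad_norm <= tol
    log.info(
        "minimize: E=%.6g grad_inf=%.3g iters=%d converged=%s (%s)",
        breakdown.total, grad_norm, nit, converged, res.message,
    )
    return MinimizationResult(state, breakdown, converged, nit, grad_norm)


def _close(e1: float, e2: float) -> bool:
    # absolute floor: near-zero energies (unloaded rest states) would make
    # a purely relative comparison separate numerically identical minima
    scale = max(abs(e1), abs(e2), 1e-6)
    return abs(e1 - e2) < MERGE_RTOL * scale


def enumerate_minima(params: ModelParams, seed: int = 0,
                     tol: float = 1e-6,
                     max_iter: int = 20000) -> list[tuple[MinimizationResult, str]]:
    """Minimize from all four archetypal seeds and classify the results.

    The undeformed seed receives the small stability-probe perturbation
    (fixed seed): the exact zero state is a stationary point by symmetry
    even when unstable, so probing is required to detect loss of stability.
    Results sharing a label with energies within 1% are merged; remaining
    entries are sorted by energy (distinct labels within 1% of the lowest
    are the co-minimal, bistable cases).
    """
    rng = np.random.default_rng(seed)
    results: list[tuple[MinimizationResult, str]] = []
    failures = 0
    straight_stable: bool | None = None  # lazily computed, shared by seeds
    for kind in SEED_KINDS:
        start = seed_state(kind, params)
        if kind == "undeformed":
            start.theta = start.theta + rng.normal(
                0.0, PROBE_AMPLITUDE, start.theta.shape
            )
        try:
            res = minimize_energy(params, start, tol=tol, max_iter=max_iter)
        except ValueError:
            failures += 1
            continue
        label = classify_state(params, res.state).label
        if (label == "undeformed" and params.Np == 0
                and params.lateral_loads is None):
            # beyond the critical load the straight state is a stationary
            # plateau, not a minimum: a probe that fails to escape it must
            # not be reported as an undeformed minimum
            if straight_stable is None:
                from .criterion import straight_state_stable as _stable

                straight_stable = _stable(params)
            if not straight_stable:
                continue
        merged = False
        for prev, prev_label in results:
            if prev_label == label and _close(prev.energy.total,
                                              res.energy.total):
                if res.energy.total < prev.energy.total:
                    results[results.index((prev, prev_label))] = (res, label)
                merged = True
                break
        if not merged:
            results.append((res, label))
    if not results:
        raise RuntimeError("all archetypal seeds failed to minimize")
    if failures:
        log.warning("enumerate_minima: %d seed(s) failed", failures)
    results.sort(key=lambda item: item[0].energy.total)
    return results


def save_result(result: MinimizationResult, params: ModelParams, path) -> None:
    """Write a minimization result as the JSON state container + sidecar."""
    obj = result.state.to_json(params)
    obj["energies"] = result.energy.as_dict()
    obj["converged"] = result.converged
    obj["iterations"] = result.iterations
    obj["grad_norm"] = result.grad_norm
    with open(path, "w") as fh:
        json.dump(obj, fh)
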
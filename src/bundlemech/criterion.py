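"""Analytic internal-buckling criterion and its triangular-kink energy model.

A stiff outer sheath (large bending ratio ``B_r``) suppresses global Euler
buckling; under sufficient axial load the interior filaments instead collapse
into a multi-arch ("internal") mode.  The reduced model treats a buckled
interior filament as ``2n`` triangular kinks of amplitude ``D`` between two
rigid neighbours: axial end displacement ``Delta`` fixes the kink geometry
exactly (the zig-zag path length equals ``L`` identically), the stretched
matrix contributes a closed-form spring energy, and the kink angles a bending
energy.  Balancing the two at ``Delta = 0`` gives the excess load

    N_e(n) = K L / n^2  +  16 n^2 B_in / L^2,

whose minimum over the wavemode ``n`` is ``N_e* = 8 sqrt(K B_in / L)`` at
``n* = K^(1/4) L^(3/4) / (2 B_in^(1/4))``.  Because the kink shape is only an
approximation the prefactor is treated as a fitted constant ``alpha``
(default 10.61), and the boundary-condition Euler load is added back:

    N_c* = alpha sqrt(K B_in / L) + n_e^2 pi^2 B_in / L^2,

with ``n_e = 1`` (pinned) or ``2`` (clamped).  The lateral decay of the kink
amplitude across the bundle enters only through a factor that cancels in the
strain ratio d*/d0, so the criterion is independent of it (tested).

The module also locates critical loads numerically by bisecting the axial
load on full energy minimizations, and fits ``alpha`` from such records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .model import ModelParams

__all__ = [
    "KinkModel",
    "CriterionParams",
    "kink_geometry",
    "kink_spring_energy",
    "kink_spring_energy_quadrature",
    "kink_bending_energy",
    "excess_load",
    "optimal_mode",
    "analytic_critical_load",
    "numerical_critical_load",
    "straight_state_hessian",
    "straight_state_stable",
    "minimized_excess_prefactor",
    "fit_alpha",
    "euler_mode",
]

ALPHA_DEFAULT = 10.61


def euler_mode(boundary: str) -> int:
    """Minimum Euler buckling mode: 1 for pinned ends, 2 for clamped."""
    return 2 if boundary == "clamped" else 1


@dataclass
class CriterionParams:
    alpha: float = ALPHA_DEFAULT
    n_e: int = 2   # Euler mode: 1 pinned, 2 clamped

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.n_e not in (1, 2):
            raise ValueError("n_e must be 1 (pinned) or 2 (clamped)")


@dataclass
class KinkModel:
    """Triangular-kink description of one internally buckled filament."""

    Delta: float
    n_kinks: int
    K: float = 2.0
    B_in: float = 1.0
    L: float = 5.0
    D: float = field(init=False)
    theta_t: float = field(init=False)
    l_t: float = field(init=False)
    N_e: float = field(init=False)

    def __post_init__(self):
        self.D, self.theta_t, self.l_t = kink_geometry(
            self.Delta, self.n_kinks, self.L
        )
        self.N_e = excess_load(self.n_kinks, self.K, self.B_in, self.L)


def kink_geometry(Delta: float, n: int, L: float):
    """Kink amplitude D, kink angle theta_t and base half-length l_t.

    D = sqrt(Delta (2L - Delta)) / (2n) makes the 2n-segment zig-zag length
    exactly L, so inextensibility is preserved for every Delta in [0, L).
    """
    if not 0 <= Delta < L:
        raise ValueError("Delta must satisfy 0 <= Delta < L")
    if n < 1:
        raise ValueError("n must be >= 1")
    D = math.sqrt(Delta * (2.0 * L - Delta)) / (2.0 * n)
    l_t = (L - Delta) / (2.0 * n)
    theta_t = math.atan2(2.0 * n * D, L - Delta)
    return D, theta_t, l_t


def kink_spring_energy(Delta: float, K: float, L: float, n: int) -> float:
    """Closed-form matrix stretching energy of the kinked filament.

    Ee(Delta) = K Delta (L - Delta)(2L - Delta) / (2 L n^2); its slope at
    Delta = 0 is K L / n^2, the spring term of the excess load.
    """
    if not 0 <= Delta < L:
        raise ValueError("Delta must satisfy 0 <= Delta < L")
    return K * Delta * (L - Delta) * (2.0 * L - Delta) / (2.0 * L * n ** 2)


def kink_spring_energy_quadrature(Delta: float, K: float, L: float, n: int,
                                  d0: float = 0.5,
                                  decay: float = 1.0) -> float:
    """Spring energy by numerical quadrature over one kink triangle.

    Integrates the Hookean strain density along the kink base and scales by
    the 6n spring families (2n triangles, direct + both diagonals per node):

        Ee = 6n * int_0^{l_t} (K/2) ((d(x) - d0)/d0)^2 (1/L) dx,
        d(x) = decay * 2nD/(L - Delta) * x + d0.

    ``decay`` models the lateral fall-off of buckling amplitude towards the
    neighbours; together with ``d0`` it enters only through decay*x/d0, so
    choosing decay proportional to d0 (as for a bundle with rest separation
    1/(m-1)) leaves the energy unchanged — the criterion is insensitive to
    the neighbour-decay factor.
    """
    D, _, l_t = kink_geometry(Delta, n, L)
    slope = decay * 2.0 * n * D / (L - Delta) if Delta > 0 else 0.0

    def strain_density(x):
        return 0.5 * K * (slope * x / d0) ** 2 / L

    val, _ = integrate.quad(strain_density, 0.0, l_t, epsabs=1e-14,
                            epsrel=1e-12)
    return 6.0 * n * val


def kink_bending_energy(Delta: float, B_in: float, L: float, n: int) -> float:
    """Bending energy of the 2n kink joints.

    Eb = (2 n^2 B_in / (L - Delta)) tan^2(2 arctan(2nD/(L - Delta))); its
    slope at Delta = 0 is 16 n^2 B_in / L^2, the bending term of the excess
    load.
    """
    D, _, _ = kink_geometry(Delta, n, L)
    arg = 2.0 * math.atan2(2.0 * n * D, L - Delta)
    if abs(math.cos(arg)) < 1e-12:
        raise ValueError("kink angle too large: tan singular")
    return 2.0 * n ** 2 * B_in / (L - Delta) * math.tan(arg) ** 2


def excess_load(n: float, K: float, B_in: float, L: float) -> float:
    """Critical excess load of the wavemode-n kink pattern.

    N_e(n) = K L / n^2 + 16 n^2 B_in / L^2: matrix stretching favours high
    wavemodes (lower amplitude), bending favours low ones.
    """
    return K * L / n ** 2 + 16.0 * n ** 2 * B_in / L ** 2


def optimal_mode(K: float, B_in: float, L: float):
    """Continuous optimal wavemode and its excess load, plus best integer mode.

    Returns (n_star, N_e_star, n_int) with n* = K^(1/4) L^(3/4)/(2 B^(1/4)),
    N_e* = 8 sqrt(K B_in / L), and n_int the brute-force best integer mode.
    """
    if min(K, B_in, L) <= 0:
        raise ValueError("K, B_in, L must all be > 0")
    n_star = K ** 0.25 * L ** 0.75 / (2.0 * B_in ** 0.25)
    N_e_star = 8.0 * math.sqrt(K * B_in / L)
    cand = np.arange(1, max(3, int(math.ceil(n_star)) + 3))
    n_int = int(cand[np.argmin(excess_load(cand.astype(float), K, B_in, L))])
    return n_star, N_e_star, n_int


def analytic_critical_load(K: float, B_in: float, L: float,
                           crit: CriterionParams | None = None) -> float:
    """N_c* = alpha sqrt(K B_in / L) + n_e^2 pi^2 B_in / L^2."""
    crit = crit or CriterionParams()
    return (crit.alpha * math.sqrt(K * B_in / L)
            + crit.n_e ** 2 * math.pi ** 2 * B_in / L ** 2)


def minimized_excess_prefactor(K: float = 2.0, B_in: float = 1.0,
                               L: float = 5.0) -> float:
    """Numerically minimize N_e(n) over real n and return the prefactor c
    in min N_e = c sqrt(K B_in / L) (8 for the triangular-kink shape)."""
    res = optimize.minimize_scalar(
        lambda n: excess_load(n, K, B_in, L),
        bounds=(1e-3, 1e3), method="bounded",
        options={"xatol": 1e-12},
    )
    return res.fun / math.sqrt(K * B_in / L)


# ---------------------------------------------------------------------------
# numerical critical loads and alpha fitting
# ---------------------------------------------------------------------------

def straight_state_hessian(params: ModelParams, step: float = 1e-5,
                           Nc: float | None = None) -> np.ndarray:
    """Hessian of the energy at the straight state, by central differences
    of the analytic gradient (column j from perturbing angle j by ±step)."""
    from .energy import energy_and_gradient
    from .model import BundleState

    p = params if Nc is None else params.replace(Nc=Nc)
    m, n = p.m, p.n
    N = m * n
    H = np.empty((N, N))
    x = np.zeros(N)
    for j in range(N):
        x[j] = step
        _, gp = energy_and_gradient(p, BundleState(x.reshape(m, n)))
        x[j] = -step
        _, gm = energy_and_gradient(p, BundleState(x.reshape(m, n)))
        x[j] = 0.0
        H[:, j] = (gp.ravel() - gm.ravel()) / (2.0 * step)
    return 0.5 * (H + H.T)


def straight_state_stable(params: ModelParams, Nc: float | None = None) -> bool:
    """Linear stability of the straight bundle: is the Hessian positive
    definite (Cholesky succeeds)?"""
    H = straight_state_hessian(params, Nc=Nc)
    try:
        np.linalg.cholesky(H)
        return True
    except np.linalg.LinAlgError:
        return False


def numerical_critical_load(params: ModelParams,
                            bracket: tuple[float, float] | None = None,
                            tol: float = 0.05,
                            perturb_amplitude: float = 1e-3,
                            seed: int = 0,
                            return_details: bool = False):
    """Bisect the axial load at which the straight bundle loses stability.

    Each trial asks whether a perturbation about the undistorted state
    grows, i.e. whether the straight-state Hessian is still positive
    definite at that load (finite differences of the analytic gradient +
    Cholesky).  The second-order test is used because the event is the
    loss of *local* stability: an unbounded minimization from a tiny
    perturbation can be carried by one large accepted line-search step into
    a remote basin (e.g. a non-locally folded state, which the local
    overlap penalty does not forbid) and misreport the transition, while
    near the critical load the unstable mode's energy scale is too small
    for a first-order convergence test to resolve.

    For the internal-buckling criterion the caller supplies a large ``B_r``
    (default setup: B_r = 1e4, Np = 0) so global buckling is excluded; at
    B_r = 1 with small ``K`` the same routine brackets the global Euler
    transition.

    Returns the bracket midpoint once its width is below ``tol``; with
    ``return_details`` also a dict carrying the final bracket and the label
    of the buckled state reached from the unstable endpoint (classified
    after a minimization started from the straight state plus a fixed-seed
    random perturbation of amplitude ``perturb_amplitude``, inside a
    generous 1-rad box).
    """
    from .classify import classify_state
    from .minimize import minimize_energy, seed_state

    ne = euler_mode(params.boundary)
    euler = ne ** 2 * math.pi ** 2 * params.B_in / params.L ** 2
    if bracket is None:
        lo = 0.5 * euler
        hi = euler + 3.0 * 8.0 * math.sqrt(params.K * params.B_in / params.L)
        hi = max(hi, 2.0 * euler)
    else:
        lo, hi = bracket

    def trial(Nc: float) -> bool:
        """True when the straight state has buckled (lost stability)."""
        return not straight_state_stable(params, Nc=Nc)

    expand = 0
    while trial(lo):
        if expand >= 8:
            raise RuntimeError("lower bracket endpoint is already unstable")
        lo *= 0.5
        expand += 1
    expand = 0
    while not trial(hi):
        if expand >= 8:
            raise RuntimeError("upper bracket endpoint never buckles")
        hi += (hi - lo)
        expand += 1

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if trial(mid):
            hi = mid
        else:
            lo = mid
    result = 0.5 * (lo + hi)
    if return_details:
        # descend along the unstable eigenvector at the supercritical
        # endpoint to reach (and classify) the buckled branch; a plain tiny
        # random perturbation can fail to leave the stationary plateau
        p_hi = params.replace(Nc=hi)
        H = straight_state_hessian(p_hi)
        _, vecs = np.linalg.eigh(H)
        mode = vecs[:, 0].reshape(params.m, params.n)
        mode = 0.05 * mode / np.max(np.abs(mode))
        rng = np.random.default_rng(seed)
        start = seed_state("undeformed", params)
        start.theta = start.theta + mode + rng.normal(
            0.0, perturb_amplitude, start.theta.shape
        )
        res = minimize_energy(p_hi, start, bound=1.0)
        label = classify_state(p_hi, res.state).label
        return result, {"bracket": (lo, hi), "label": label}
    return result


@dataclass
class AlphaFit:
    """Per-record and pooled prefactor estimates from critical-load records."""

    alphas: list
    pooled: float
    excluded: list


def fit_alpha(records) -> AlphaFit:
    """Back out alpha from (K, B_in, L, m, n_e, N_c*) records.

    Per record: alpha_i = (Nc* - n_e^2 pi^2 B/L^2) / sqrt(K B / L).  The
    pooled value is the least-squares slope of the excess load against
    sqrt(K B / L) through the origin.  Records whose excess load is not
    positive (below their Euler load) are flagged and excluded.
    """
    xs, ys, alphas, excluded = [], [], [], []
    for rec in records:
        K, B, L, m, ne, Nc_star = (
            rec["K"], rec["B"], rec["L"], rec.get("m", 10),
            rec["ne"], rec["Ncstar"],
        )
        excess = Nc_star - ne ** 2 * math.pi ** 2 * B / L ** 2
        x = math.sqrt(K * B / L)
        if excess <= 0:
            excluded.append(rec)
            continue
        xs.append(x)
        ys.append(excess)
        alphas.append(excess / x)
    if not xs:
        raise ValueError("no usable records (all below their Euler load)")
    xs_arr, ys_arr = np.asarray(xs), np.asarray(ys)
    pooled = float((xs_arr @ ys_arr) / (xs_arr @ xs_arr))
    return AlphaFit(alphas=alphas, pooled=pooled, excluded=excluded)
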
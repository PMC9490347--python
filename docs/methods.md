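# Methods

## Model and assumptions

The bundle is two-dimensional: `m` inextensible planar rods of equal arc
length, anchored at their left ends (`x_i0 = 0`, fixed heights spaced
`d_0 = W/(m−1)` apart, with the width `W` the reference length, so `W = 1`
after non-dimensionalization). The only degrees of freedom are the `m × n`
segment angles; node positions follow by cumulative summation, so segment
lengths are exactly `l = L/n` for every configuration — inextensibility is
built into the parametrization rather than imposed by constraint. Torsion
and out-of-plane deformation are outside the model, as is any non-local
self-contact force: the overlap penalty acts only on the triangles of
adjacent node quads, so deeply post-buckled states at low sheath stiffness
can self-intersect non-locally. All quantities are non-dimensional
(lengths by the bundle width `W`, stiffnesses by a reference bending
stiffness `B_s = 0.01`, loads and `K` by `B_s W²`).

Bending uses the circumscribed-circle discrete curvature
`κ_j = (2/l) tan(Δθ_j/2)`, giving `(B/2) κ² l = (2B/l) tan²(Δθ/2)` per
interior joint. The small-angle limit `B Δθ²/(2l)` is the standard
discrete-rod value; this normalization is what makes a pinned rod of unit
stiffness lose stability at the classical `π²B/L²` (verified numerically
to 0.2% at `n = 200`). A quarter-stiffness variant of the same measure —
prefactor `B/(2l)` on `tan²(Δθ/2)` — appears in some formulations; it
shifts every Euler load down fourfold and halves the fitted
internal-buckling prefactor α (see "Known limitations"). We use the full
normalization throughout.

The matrix consists of three Hookean spring families per neighbouring
filament pair — vertical at every node (rest `d_0`), and both diagonals of
every quad (rest `√(d_0² + l²)`) — each an energy density per unit length
(factor `l` per spring) with strain relative to the rest length. Both
diagonals of each quad are included symmetrically, so the mirror image of
a configuration swaps the two families and leaves their sum invariant.
A side effect of diagonal springs is a small shear-like stiffness
`O(K l²)` resisting uniform tilt; it vanishes as `n → ∞` but shifts the
global buckling onset of a coupled bundle noticeably at coarse
discretizations (for `K = 2`, `m = 10`, `L = 5`, pinned: onset 0.56 at
`n = 200` but 0.69 at `n = 100`, against the bare Euler 0.395). Tests of
discretization-sensitive global-buckling properties therefore run at
`n = 200`.

The overlap penalty `g(A) = C_1 e^{−C_2 A/A_0}` (defaults `C_1 = 10⁶`,
`C_2 = 100`) is negligible (`∼e^{−100}`) at rest and becomes order-one
when a triangle shrinks to ~10% of its rest area; `C_2 = 40` (the
`fig7` preset) emulates a strain-hardening matrix. Boundary conditions are
penalties with `C_3 = 10⁵`: pinned (end heights) always, plus end tangents
when clamped. Joint angle differences reaching ±π make the bending tangent
singular; such states report non-finite energy (the line search backtracks)
rather than being clamped, which would silently corrupt the landscape.

## Energy minimization

Gradients are assembled analytically: coordinate-dependent terms produce
nodal forces, and the chain rule through the cumulative-sum geometry
reduces to a reversed cumulative sum (node `j` moves with angle `k` iff
`j ≥ k`); bending and the clamping penalty act on angles directly. A
single-pass numba kernel evaluates energy + gradient (~0.08 ms at
`m = 10`, `n = 100`); the vectorized numpy assembly is the readable
reference, agrees with the kernel to round-off in tests, and serves as the
fallback when numba is absent. Central finite differences are the
authority for gradient correctness (contract: max relative error < 1e−5
on random states; observed ~1e−10).

Minimization is L-BFGS-B (memory 10) with convergence declared at
gradient infinity-norm ≤ 1e−6 (default), restarting with fresh curvature
memory up to twice when the line search plateaus early; iteration cap
20000. Archetypal seeds use amplitude 1e−2 rad; the undeformed seed gets
an additional 1e−3 stability probe perturbation (fixed RNG seed) because
the exact zero state is a stationary point by symmetry even when unstable.
Minima from different seeds merge when they share a label and energies
agree within 1% (with a 1e−6 absolute floor for near-zero energies);
distinct labels within 1% of the lowest energy are reported as co-minimal
(bistable phase cells). A result labelled undeformed at `N_p = 0` is
discarded when the straight state's Hessian is indefinite — beyond the
critical load the straight configuration is a plateau, not a minimum, and
an optimizer parked there must not be reported as one.

## Classification

Three diagnostics, thresholds as fixed constants: mean absolute moment
`B_r ⟨tan²(Δθ/2)⟩` (averaged per joint, per filament — deliberately
without the `1/2l` energy weighting; the 1e−5 undeformed threshold is tied
to this convention and is therefore resolution-dependent: smooth
small-amplitude pinched states at `n ≥ 100` can legitimately classify as
undeformed); inner/outer moment ratio > 5 ⇒ internal (outer moment exactly
zero counts as an infinite ratio when the inner moment clears the
threshold); pinching parameter `P > 0.75` ⇒ pinched, else global. `P`
averages the normalized antisymmetry `|θ_ij − θ_(m+1−i)j| /
(|θ_ij| + |θ_(m+1−i)j|)` over the `⌊m/2⌋` mirror pairs and all segments;
zero-denominator (straight) pairs contribute nothing. Two-filament bundles
have no interior, so the internal rule is skipped.

## Critical loads and the kink model

The reduced model treats an internally buckling filament as `2n`
triangular kinks whose geometry is fixed exactly by the end displacement
Δ (the zig-zag length equals `L` identically, not just to second order).
Spring energy in closed form `E_e = K Δ (L−Δ)(2L−Δ)/(2 L n²)` — chosen so
its slope at Δ = 0 is the `K L/n²` spring term of the excess load, and
verified against quadrature of the per-triangle strain integral (6n spring
families, `d_0 = 1/2` for the three-rod geometry) to 1e−8. Bending
`E_b = (2n² B_in/(L−Δ)) tan²(2 arctan(2nD/(L−Δ)))`, slope `16 n² B_in/L²`.
The lateral decay of buckling amplitude across a wider bundle enters the
strain only through a factor proportional to the rest separation, which
cancels in the strain ratio — tested, and the reason the criterion carries
a single fitted prefactor rather than an `m`-dependence.

`numerical_critical_load` bisects the load at which the straight state's
Hessian (finite differences of the analytic gradient, step 1e−5, then
Cholesky) loses positive definiteness. A second-order test is used rather
than minimization from a perturbed state for two numerical reasons
established during development: just above onset the unstable mode's
energy scale (`∼10⁻¹⁰` against totals of order 10²) is below what a
first-order convergence test can resolve, biasing detection upward by up
to ~25%; and an unbounded search can be carried by one large accepted
line-search step into a remote basin (e.g. a non-locally folded state the
local overlap penalty cannot forbid), biasing it downward. Default
bracket: half the Euler load up to Euler + 3×8√(KB/L), expanded
geometrically if needed; bisection tolerance 0.05 (0.005 for the pinned
Euler check, matching its 5% verification band). The transition's mode
label is obtained by descending along the unstable eigenvector (amplitude
0.05, plus the 1e−3 probe noise) inside a 1-rad box. α is fitted per
record as `(N_c* − n_e²π²B/L²)/√(KB/L)` and pooled as the least-squares
slope of excess load against `√(KB/L)` through the origin; records below
their Euler load are flagged and excluded.

## Phase sweeps

`run_sweep` classifies the four-seed minima on a `(N_c, N_p, B_r)` grid
(default 20 × 9 × 7 over `[0.5,10] × [0,0.4] × [1,10⁴]`), caches cells by
a content hash of the full parameter set, records failures per cell, and
round-trips through a CSV with up to two co-minimal labels per cell.
Presets (`fig3e`, `fig5a`–`fig5d`, `fig7`) encode the surveyed variants:
pinned-only boundaries, twenty rods, halved/doubled `K`, `C_2 = 40`.

## Problem sizes in tests and the acceptance script

Tests and the acceptance script use reduced sizes chosen for accuracy, not
fidelity loss: gradient checks at `n = 50`; α fitting and stiff-sheath
sweeps at `n = 100` (the internal mode has ~4 arches over `L = 5`, well
resolved); pinned-layer and Euler-limit checks at `n = 200`, where the
diagonal-spring shear artifact is small; phase grids 5 × 3 per layer.
Everything is deterministic given the `--seed` argument (the Hessian
bisection itself is seed-free; seeds enter probe perturbations and
labelling only).

## Known limitations

* With the full bending normalization the fitted internal-buckling
  prefactor is `α ≈ 20.8` (pooled over `(K,B,L) ∈ {(1,1,5), (2,1,5),
  (4,1,5), (2,1,3)}`, `m = 10`, `B_r = 10⁴`, clamped). Under the
  quarter-stiffness curvature variant the same pipeline yields half this
  value (α ≈ 10.4) while placing the pinned Euler load at 0.099 instead
  of 0.395 — the two conventions cannot both reproduce classical Euler
  loads and an α near 10.6. The internal transition here is not
  subcritical: interior-mode seeds up to amplitude 0.3 relax back to
  straight below the linear-stability load, so no alternative operational
  definition of the critical load (branch existence, energy crossing)
  changes this. Consequently, at `K = 2` the internal onset (≈15.6 at
  `n = 100`) lies above the default surveyed load range, and the
  stiff-sheath layer of the default phase grid contains no internal
  cells; internal-mode studies should extend `N_c` beyond the onset
  (e.g. the worked example's `N_c = 17`).
* The pinned `B_r = 1` layer's global-buckling onset is 0.56 at `n = 200`
  (`K = 2`), so the lowest surveyed load `N_c = 0.5` sits marginally below
  it and classifies undeformed.
* The classifier's absolute moment threshold makes small-amplitude smooth
  deformations (gentle pinching) classify as undeformed at fine
  discretizations; comparisons across different `n` should use the same
  `n` on both sides, as the tests do.
* Energies, not forces, are the primitive: reported "pressures" are
  magnitudes of interaction-energy gradients per node, a per-node force
  scale rather than a true stress.
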
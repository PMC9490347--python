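"""Energy terms against hand evaluations, and the gradient against finite
differences (the module's master oracle)."""

import numpy as np
import pytest

import bundlemech as bm
from bundlemech.energy import _energy_and_gradient_numpy
from bundlemech.model import BundleGeometry

from .conftest import fd_gradient, random_state


class TestBendingEnergy:
    def test_rest_state_zero(self, small_params):
        _, total = bm.bending_energy(small_params, bm.rest_state(small_params))
        assert total == 0.0

    def test_single_right_angle_joint(self):
        # one interior joint turning by pi/2: (2B/l) tan^2(pi/4) = 2/l
        p = bm.ModelParams(m=2, n=2, L=1.0, B_in=1.0, B_r=1.0, K=0.0)
        theta = np.zeros((2, 2))
        theta[0, 1] = np.pi / 2
        per, _ = bm.bending_energy(p, bm.BundleState(theta))
        assert per[0] == pytest.approx(2.0 / p.l)

    def test_outer_filament_scales_with_stiffness_ratio(self, rng):
        p = bm.ModelParams(m=3, n=10, B_r=10.0)
        profile = rng.normal(0, 0.2, p.n)
        theta = np.tile(profile, (3, 1))
        per, _ = bm.bending_energy(p, bm.BundleState(theta))
        assert per[0] == pytest.approx(10.0 * per[1])
        assert per[2] == pytest.approx(10.0 * per[1])

    def test_near_pi_difference_reports_nonfinite(self):
        p = bm.ModelParams(m=2, n=2, L=1.0)
        theta = np.zeros((2, 2))
        theta[0, 1] = np.pi
        _, total = bm.bending_energy(p, bm.BundleState(theta))
        assert not np.isfinite(total)
        assert not np.isfinite(bm.total_energy(p, bm.BundleState(theta)).total)


def _translated_geometry(p, dy_row=None):
    """Geometry of the rest state with one filament rigidly shifted."""
    coords = bm.coordinates_from_angles(p, bm.rest_state(p))
    if dy_row is not None:
        row, dy = dy_row
        coords[row, :, 1] += dy
    d, dp, dm = bm.pair_distances(coords)
    return BundleGeometry(coords, d, dp, dm, bm.triangle_areas(coords))


class TestSpringEnergy:
    def test_rest_state_zero(self, small_params):
        g = bm.build_geometry(small_params, bm.rest_state(small_params))
        assert all(t < 1e-20 for t in bm.spring_energy(small_params, g))

    def test_doubled_separation_hand_value(self):
        # shifting the top filament of a pair up by d0 doubles every vertical
        # distance: Ee1 = (n+1) * l * (K/2) * 1^2; diagonals from the norms
        p = bm.ModelParams(m=2, n=6, L=2.0, K=3.0)
        g = _translated_geometry(p, dy_row=(1, p.d0))
        Ee1, Ee1p, Ee1m = bm.spring_energy(p, g)
        assert Ee1 == pytest.approx((p.n + 1) * p.l * p.K / 2.0)
        diag = np.hypot(2.0 * p.d0, p.l)
        expected_family = p.n * p.l * (p.K / 2.0) * (
            (diag - p.d0_diag) / p.d0_diag
        ) ** 2
        assert Ee1p == pytest.approx(expected_family)
        assert Ee1m == pytest.approx(expected_family)

    def test_linear_in_stiffness(self, small_params, rng):
        st = random_state(small_params, rng)
        g1 = bm.build_geometry(small_params, st)
        terms1 = bm.spring_energy(small_params, g1)
        p2 = small_params.replace(K=2 * small_params.K)
        terms2 = bm.spring_energy(p2, g1)
        assert terms2 == pytest.approx(tuple(2 * t for t in terms1))


class TestOverlapPenalty:
    def test_contact_value_is_amplitude(self):
        p = bm.ModelParams()
        assert bm.overlap_penalty(0.0, p) == pytest.approx(1e6)

    def test_rest_area_value_negligible(self):
        p = bm.ModelParams()
        assert bm.overlap_penalty(p.A0, p) == pytest.approx(
            1e6 * np.exp(-100.0)
        )

    def test_onset_at_ten_percent_area(self):
        # at C2=100 the penalty becomes order-one when the triangle shrinks
        # to 10% of its rest size
        p = bm.ModelParams()
        assert bm.overlap_penalty(0.1 * p.A0, p) == pytest.approx(
            1e6 * np.exp(-10.0)
        )

    def test_overlap_energy_counts_both_triangles(self):
        p = bm.ModelParams(m=3, n=4)
        g = bm.build_geometry(p, bm.rest_state(p))
        expected = 2 * (p.m - 1) * p.n * 1e6 * np.exp(-100.0)
        assert bm.overlap_energy(p, g) == pytest.approx(expected)


class TestLoadingAndConstraints:
    def test_rest_state_load_values(self):
        p = bm.ModelParams(m=10, n=20, L=5.0, Nc=2.0, Np=0.3)
        g = bm.build_geometry(p, bm.rest_state(p))
        El1, El2 = bm.loading_energy(p, g)
        assert El1 == pytest.approx(10 * 2.0 * 5.0)
        assert El2 == pytest.approx(0.0)

    def test_lateral_energy_tracks_outer_filament_shift(self):
        # shift the movable nodes (j >= 1) of the top filament down by delta
        # (node 0 is anchored): El2 decreases by Np * n * delta
        p = bm.ModelParams(m=4, n=6, Np=0.2)
        delta = 0.01
        g0 = _translated_geometry(p)
        g1 = _translated_geometry(p)
        g1.coords[p.m - 1, 1:, 1] -= delta
        El2_0 = bm.loading_energy(p, g0)[1]
        El2_1 = bm.loading_energy(p, g1)[1]
        assert El2_1 - El2_0 == pytest.approx(-p.Np * p.n * delta)

    def test_no_pinching_load_no_lateral_energy(self, rng):
        p = bm.ModelParams(m=4, n=6, Np=0.0)
        g = bm.build_geometry(p, random_state(p, rng, 0.3))
        assert bm.loading_energy(p, g)[1] == 0.0

    def test_rest_state_constraints_zero(self, small_params):
        p = small_params
        g = bm.build_geometry(p, bm.rest_state(p))
        assert bm.constraint_energy(p, g, bm.rest_state(p)) == (0.0, 0.0)

    def test_pinned_mode_drops_tangent_penalty(self):
        p = bm.ModelParams(m=2, n=4, boundary="pinned")
        theta = np.zeros((2, 4))
        theta[:, 0] = 0.3
        st = bm.BundleState(theta)
        g = bm.build_geometry(p, st)
        Ec1, Ec2 = bm.constraint_energy(p, g, st)
        assert Ec2 == 0.0
        breakdown = bm.total_energy(p, st)
        assert breakdown.Ec2 == 0.0

    def test_end_deflection_penalty_hand_value(self):
        # y_in - y_i0 = 0.01 on one filament -> Ec1 = C3 * 1e-4 = 10
        p = bm.ModelParams(m=2, n=4)
        g = _translated_geometry(p)
        g.coords[0, -1, 1] += 0.01
        Ec1, _ = bm.constraint_energy(p, g, bm.rest_state(p))
        assert Ec1 == pytest.approx(10.0)


class TestTotalEnergy:
    def test_rest_with_loads_is_pure_load_energy(self):
        p = bm.ModelParams(m=10, n=50, L=5.0, Nc=1.5, Np=0.2)
        total = bm.total_energy(p, bm.rest_state(p)).total
        assert total == pytest.approx(10 * 1.5 * 5.0, rel=1e-12)

    def test_mirror_symmetry_without_pinching(self, rng):
        # the bundle's mirror about its mid-line maps theta_ij to
        # -theta_(m+1-i)j (sign flip AND row reversal); for
        # non-overlapping states (negligible Ee2, whose triangulation is
        # tied to the forward diagonal) the energy is invariant and the
        # two diagonal spring families swap exactly
        p = bm.ModelParams(m=4, n=10, Nc=0.8, Np=0.0)
        st = random_state(p, rng, 0.05)
        mirrored = bm.BundleState(-st.theta[::-1])
        b1 = bm.total_energy(p, st)
        b2 = bm.total_energy(p, mirrored)
        assert b1.total == pytest.approx(b2.total, rel=1e-12)
        assert b1.Ee1_plus == pytest.approx(b2.Ee1_minus, rel=1e-12)
        assert b1.Ee1_minus == pytest.approx(b2.Ee1_plus, rel=1e-12)

    def test_mirror_symmetry_preserves_pinching_load(self, rng):
        # the default pinching pattern (+Np top, -Np bottom) is itself
        # mirror-antisymmetric, so E is invariant with Np kept
        p = bm.ModelParams(m=4, n=10, Nc=0.5, Np=0.2)
        st = random_state(p, rng, 0.05)
        mirrored = bm.BundleState(-st.theta[::-1])
        e1 = bm.total_energy(p, st).total
        e2 = bm.total_energy(p, mirrored).total
        assert e1 == pytest.approx(e2, rel=1e-12)

    def test_breakdown_sums_to_total(self, small_params, rng):
        b = bm.total_energy(small_params, random_state(small_params, rng))
        parts = (b.Eb + b.Ee1 + b.Ee1_plus + b.Ee1_minus + b.Ee2
                 + b.El1 + b.El2 + b.Ec1 + b.Ec2)
        assert b.total == pytest.approx(parts, rel=1e-12)


class TestGradient:
    def test_zero_at_unloaded_rest(self):
        p = bm.ModelParams(m=4, n=10, Nc=0.0, Np=0.0)
        g = bm.energy_gradient(p, bm.rest_state(p))
        assert np.max(np.abs(g)) < 1e-12

    def test_axial_load_exerts_no_first_order_force_on_straight_state(self):
        # d x_in / d theta = -l sin(theta) = 0 at rest: buckling is an
        # instability, not a tilt
        p = bm.ModelParams(m=4, n=10, Nc=2.0, Np=0.0)
        g = bm.energy_gradient(p, bm.rest_state(p))
        assert np.max(np.abs(g)) < 1e-12

    def test_matches_finite_differences(self, small_params, rng):
        for _ in range(3):
            st = random_state(small_params, rng)
            g = bm.energy_gradient(small_params, st)
            fd = fd_gradient(small_params, st)
            scale = max(1.0, np.max(np.abs(fd)))
            assert np.max(np.abs(g - fd)) / scale < 1e-6

    def test_matches_finite_differences_pinned(self, rng):
        p = bm.ModelParams(m=3, n=6, Nc=0.4, Np=0.2, boundary="pinned")
        st = random_state(p, rng)
        fd = fd_gradient(p, st)
        g = bm.energy_gradient(p, st)
        scale = max(1.0, np.max(np.abs(fd)))
        assert np.max(np.abs(g - fd)) / scale < 1e-6

    def test_kernel_and_reference_paths_agree(self, small_params, rng):
        st = random_state(small_params, rng)
        e_ref, g_ref = _energy_and_gradient_numpy(small_params, st)
        e_k, g_k = bm.energy_and_gradient(small_params, st)
        assert e_k == pytest.approx(e_ref, rel=1e-12)
        assert np.allclose(g_k, g_ref, rtol=1e-9, atol=1e-9)

    def test_singular_state_flags_nonfinite(self):
        p = bm.ModelParams(m=2, n=2, L=1.0)
        theta = np.zeros((2, 2))
        theta[0, 1] = np.pi
        e, g = bm.energy_and_gradient(p, bm.BundleState(theta))
        assert not np.isfinite(e)
        assert np.all(g == 0.0)


class TestInteractionPressure:
    def test_rest_state_pressureless(self, small_params):
        p = bm.interaction_pressure(small_params,
                                    bm.rest_state(small_params))
        assert np.allclose(p, 0.0, atol=1e-12)

    def test_matches_coordinate_finite_differences(self, rng):
        p = bm.ModelParams(m=3, n=5, K=2.0)
        st = random_state(p, rng, 0.1)
        field = bm.interaction_pressure(p, st)

        def interaction(coords):
            d, dp, dm = bm.pair_distances(coords)
            areas = bm.triangle_areas(coords)
            g = BundleGeometry(coords, d, dp, dm, areas)
            e = bm.spring_energy(p, g)
            return e[0] + e[1] + e[2] + bm.overlap_energy(p, g)

        coords0 = bm.coordinates_from_angles(p, st)
        h = 1e-6
        for i in range(p.m):
            for j in range(p.n + 1):
                grad = np.zeros(2)
                for axis in range(2):
                    cp = coords0.copy()
                    cp[i, j, axis] += h
                    cm = coords0.copy()
                    cm[i, j, axis] -= h
                    grad[axis] = (interaction(cp) - interaction(cm)) / (2 * h)
                assert field[i, j] == pytest.approx(
                    np.linalg.norm(grad), rel=1e-5, abs=1e-8
                )

    def test_pressure_csv_export(self, small_params, rng, tmp_path):
        import pandas as pd

        from bundlemech.energy import pressure_to_csv

        st = random_state(small_params, rng)
        path = tmp_path / "pressure.csv"
        pressure_to_csv(small_params, st, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["filament", "index", "x", "y", "pressure"]
        assert len(df) == small_params.m * (small_params.n + 1)
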
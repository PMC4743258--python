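"""Frame algebra: step transforms, chain building, closure geometry."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dnacyc.geometry import (
    ChainConfiguration,
    Frame,
    build_chain,
    canonical_frame,
    closure_geometry,
    residual_twist,
    step_transform,
)
from dnacyc.params import StepParameters, builtin_curved, builtin_straight, curved_sequence, equilibrium_profile

angles = st.floats(-30.0, 30.0)
twists = st.floats(20.0, 45.0)
disps = st.floats(-2.0, 2.0)
rises = st.floats(2.5, 4.5)
steps = st.builds(
    StepParameters, tilt=angles, roll=angles, twist=twists, shift=disps, slide=disps, rise=rises
)


def _rotation_angle(R):
    return math.acos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0))


class TestStepTransform:
    def test_zero_angles_translate_along_normal(self):
        R, t = step_transform(StepParameters(twist=0.0, rise=3.40))
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, [0.0, 0.0, 3.40], atol=1e-12)

    def test_ten_36_degree_twists_return_to_identity(self):
        R, _ = step_transform(StepParameters(twist=36.00, rise=3.40))
        M = np.eye(3)
        for _ in range(10):
            M = M @ R
        assert np.abs(M - np.eye(3)).max() < 1e-9

    def test_pure_roll_rotates_by_the_roll_angle(self):
        R, _ = step_transform(StepParameters(roll=7.41, twist=0.0, rise=3.40))
        assert _rotation_angle(R) == pytest.approx(math.radians(7.41), abs=1e-9)
        # bend about the long (y) axis leaves e_y fixed
        assert np.allclose(R @ [0, 1, 0], [0, 1, 0], atol=1e-12)

    def test_pure_tilt_rotates_about_short_axis(self):
        R, _ = step_transform(StepParameters(tilt=5.0, twist=0.0, rise=3.40))
        assert _rotation_angle(R) == pytest.approx(math.radians(5.0), abs=1e-9)
        assert np.allclose(R @ [1, 0, 0], [1, 0, 0], atol=1e-12)

    @given(steps)
    def test_rotation_is_special_orthogonal(self, step):
        R, _ = step_transform(step)
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-12)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    @given(steps)
    def test_composing_with_inverse_gives_identity(self, step):
        R, t = step_transform(step)
        Rinv, tinv = R.T, -R.T @ t
        assert np.abs(R @ Rinv - np.eye(3)).max() < 1e-12
        assert np.abs(R @ tinv + t).max() < 1e-12

    @given(st.floats(1.0, 44.0))
    def test_single_angle_equals_axis_angle(self, angle):
        for name in ("tilt", "roll", "twist"):
            kwargs = {"tilt": 0.0, "roll": 0.0, "twist": 0.0, name: angle}
            R, _ = step_transform(StepParameters(rise=3.4, **kwargs))
            assert _rotation_angle(R) == pytest.approx(math.radians(angle), abs=1e-9)


class TestBuildChain:
    def test_straight_150bp_is_collinear(self, straight):
        chain = build_chain(equilibrium_profile("A" * 150, straight))
        assert chain.n_bp == 150
        assert chain.end_to_end() == pytest.approx(149 * 3.40, abs=1e-9)
        # pure twist: all origins on the z axis
        assert np.abs(chain.origins[:, :2]).max() < 1e-9

    @given(st.lists(rises, min_size=1, max_size=20), twists)
    def test_pure_twist_r_equals_sum_of_rises(self, rise_list, twist):
        profile = [StepParameters(twist=twist, rise=r) for r in rise_list]
        chain = build_chain(profile)
        assert chain.end_to_end() == pytest.approx(sum(rise_list), rel=1e-12)

    def test_deterministic_and_repeatable(self, curved):
        profile = equilibrium_profile(curved_sequence(60), curved)
        a, b = build_chain(profile), build_chain(profile)
        assert np.array_equal(a.origins, b.origins)
        assert np.array_equal(a.triads, b.triads)

    def test_equivariance_under_rigid_start_transform(self, curved):
        profile = equilibrium_profile(curved_sequence(40), curved)
        base = build_chain(profile)
        from dnacyc.geometry import _rot_y, _rot_z

        R0 = _rot_z(0.7) @ _rot_y(0.3)
        o0 = np.array([5.0, -2.0, 11.0])
        moved = build_chain(profile, start=Frame(o0, R0))
        assert np.allclose(moved.origins, o0 + base.origins @ R0.T, atol=1e-9)
        assert np.allclose(moved.triads, np.einsum("ij,njk->nik", R0, base.triads), atol=1e-9)

    def test_curved_minimum_energy_150bp_nearly_closes(self, curved):
        """The 5X/5Z repeat bends 150 bp into a near-circle: the end-to-end
        distance is a tiny fraction of the contour length (regression value
        3.65 Å from the deterministic construction)."""
        chain = build_chain(equilibrium_profile(curved_sequence(150), curved))
        geo = closure_geometry(chain)
        assert geo.r / chain.contour_length() < 0.02
        assert geo.r == pytest.approx(3.653, abs=0.01)
        assert geo.cos_gamma > 0.98

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            build_chain([])


class TestClosureGeometry:
    def test_identity_closure(self):
        chain = ChainConfiguration(np.zeros((2, 3)), np.stack([np.eye(3)] * 2))
        geo = closure_geometry(chain)
        assert (geo.r, geo.cos_gamma, geo.phi) == (0.0, 1.0, 0.0)

    def test_half_turn_about_normal_gives_phi_pi(self):
        from dnacyc.geometry import _rot_z

        chain = ChainConfiguration(
            np.zeros((2, 3)), np.stack([np.eye(3), _rot_z(math.pi)])
        )
        assert abs(closure_geometry(chain).phi) == pytest.approx(math.pi, abs=1e-12)

    @given(st.floats(-3.0, 3.0))
    def test_phi_recovers_twist_about_shared_normal(self, angle):
        from dnacyc.geometry import _rot_z

        chain = ChainConfiguration(np.zeros((2, 3)), np.stack([np.eye(3), _rot_z(angle)]))
        assert closure_geometry(chain).phi == pytest.approx(angle, abs=1e-9)

    def test_straight_chain_normals_stay_parallel(self, straight):
        chain = build_chain(equilibrium_profile("A" * 150, straight))
        geo = closure_geometry(chain)
        assert geo.cos_gamma == pytest.approx(1.0, abs=1e-12)
        assert geo.r == pytest.approx(506.6, abs=1e-9)

    def test_residual_twist_antiparallel_fallback(self):
        phi = residual_twist(
            np.array([0.0, 0, 1]), np.array([1.0, 0, 0]),
            np.array([0.0, 0, -1]), np.array([1.0, 0, 0]),
        )
        assert math.isfinite(phi)


class TestFrameValidation:
    def test_rejects_non_orthonormal_triad(self):
        with pytest.raises(ValueError, match="orthonormal"):
            Frame(np.zeros(3), np.eye(3) * 1.01)

    def test_rejects_left_handed_triad(self):
        t = np.eye(3)
        t[2, 2] = -1.0
        with pytest.raises(ValueError, match="right-handed"):
            Frame(np.zeros(3), t)

    def test_chain_needs_two_frames(self):
        with pytest.raises(ValueError):
            ChainConfiguration(np.zeros((1, 3)), np.eye(3)[np.newaxis])


def test_kernel_end_frames_match_reference_geometry(rng):
    """The numba batch kernel and the plain-numpy chain builder are
    independent implementations of the same algebra; they must agree to
    near machine precision on random profiles."""
    from dnacyc import _kernels

    B, n = 6, 30
    params = np.empty((B, n, 6))
    params[:, :, 0] = rng.uniform(-0.3, 0.3, (B, n))
    params[:, :, 1] = rng.uniform(-0.3, 0.3, (B, n))
    params[:, :, 2] = rng.uniform(0.3, 0.9, (B, n))
    params[:, :, 3:5] = rng.uniform(-1.5, 1.5, (B, n, 2))
    params[:, :, 5] = rng.uniform(2.5, 4.5, (B, n))
    origins = np.empty((B, 3))
    triads = np.empty((B, 3, 3))
    _kernels.end_frames(params, origins, triads)
    for c in range(B):
        profile = [
            StepParameters(
                tilt=math.degrees(params[c, k, 0]),
                roll=math.degrees(params[c, k, 1]),
                twist=math.degrees(params[c, k, 2]),
                shift=params[c, k, 3],
                slide=params[c, k, 4],
                rise=params[c, k, 5],
            )
            for k in range(n)
        ]
        chain = build_chain(profile)
        assert np.abs(chain.origins[-1] - origins[c]).max() < 1e-10
        assert np.abs(chain.triads[-1] - triads[c]).max() < 1e-10


def test_chain_export_round_trip(tmp_path, straight):
    from dnacyc.geometry import chain_to_dataframe, write_chain_tsv, write_pdb_trace

    chain = build_chain(equilibrium_profile("ACGTACGT", straight))
    df = chain_to_dataframe(chain)
    assert len(df) == 8
    write_chain_tsv(chain, tmp_path / "chain.tsv")
    write_pdb_trace(chain, tmp_path / "chain.pdb")
    assert (tmp_path / "chain.tsv").exists()
    assert (tmp_path / "chain.pdb").read_text().startswith("ATOM")
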
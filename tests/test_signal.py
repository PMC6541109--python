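"""Forward model: ball + sticks synthesis, noise, scenarios."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ballstick as bs
from ballstick.sphere import DWIProtocol


def matrix_form_signal(truth, protocol):
    """Independent oracle: the stick term via the explicit rotation-matrix
    quadratic form r^T R_k A R_k^T r instead of the dot-product shortcut."""
    A = np.diag([1.0, 0.0, 0.0])
    out = np.empty(len(protocol))
    F = truth.total_fraction
    for i, (r, b) in enumerate(zip(protocol.bvecs, protocol.bvals)):
        s = (1.0 - F) * np.exp(-b * truth.d)
        for fb in truth.fibers:
            th, ph = bs.angles_from_direction(fb.orientation, degrees=False)
            Rk = np.array([
                [np.cos(th) * np.cos(ph), -np.sin(ph), np.sin(th) * np.cos(ph)],
                [np.cos(th) * np.sin(ph), np.cos(ph), np.sin(th) * np.sin(ph)],
                [np.sin(th), 0.0, -np.cos(th)],
            ])
            q = r @ Rk @ A @ Rk.T @ r
            s += fb.f * np.exp(-b * truth.d * q)
        out[i] = truth.S0 * s
    return out


class TestStickAttenuation:
    def test_perpendicular_is_one(self):
        assert bs.stick_attenuation([1, 0, 0], [0, 1, 0], 1500, 1 / 1500) == pytest.approx(1.0)

    def test_parallel(self):
        assert bs.stick_attenuation([1, 0, 0], [1, 0, 0], 1500, 1 / 1500) == \
            pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_45_degrees(self):
        r = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
        assert bs.stick_attenuation(r, [1, 0, 0], 1500, 1 / 1500) == \
            pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_negative_b_errors(self):
        with pytest.raises(ValueError):
            bs.stick_attenuation([1, 0, 0], [1, 0, 0], -1.0, 1e-3)


class TestPredictSignal:
    def test_pure_ball(self):
        truth = bs.VoxelGroundTruth(S0=400.0, d=1 / 1500, fibers=[], sigma=0.0)
        proto = DWIProtocol([[1, 0, 0]], [1500.0])
        assert bs.predict_signal(truth, proto)[0] == pytest.approx(400 * np.exp(-1.0))

    def test_b0_equals_S0(self, paper_scenario, clean_signal):
        truth, protocol = paper_scenario
        np.testing.assert_allclose(clean_signal[~protocol.dw_mask], truth.S0)

    def test_closed_form_maximum(self, paper_scenario):
        # gradient along Z is perpendicular to both in-plane sticks:
        # S = 400 (0.1 e^-1 + 0.9) ~ 374.715
        truth, _ = paper_scenario
        proto = DWIProtocol([[0, 0, 1.0]], [1500.0])
        assert bs.predict_signal(truth, proto)[0] == pytest.approx(374.7151, abs=1e-3)

    def test_matches_matrix_oracle(self, rng):
        truth = bs.VoxelGroundTruth(fibers=[
            bs.FiberComponent.from_angles(0.3, 25.0, 140.0),
            bs.FiberComponent.from_angles(0.45, -40.0, 310.0)])
        proto = bs.make_protocol(24, n_b0=2, with_hypothetical=False)
        np.testing.assert_allclose(bs.predict_signal(truth, proto),
                                   matrix_form_signal(truth, proto), atol=1e-10)

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError):
            bs.VoxelGroundTruth(fibers=[bs.FiberComponent.from_angles(0.6, 0, 0),
                                        bs.FiberComponent.from_angles(0.6, 0, 90)])


class TestSimplifiedEquivalence:
    def test_matches_full_model_on_random_draws(self, rng):
        # with nuisance set to truth, the rotated-frame 2-stick formula equals
        # the full model for fibers lying in the plane perpendicular to r_l
        proto = bs.make_protocol(32, n_b0=2, with_hypothetical=False)
        for _ in range(100):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            R = bs.rotation_to_z(axis)
            f1, f2 = rng.uniform(0.05, 0.45, 2)
            p1, p2 = rng.uniform(0, np.pi, 2)
            # sticks in the original frame: back-rotated in-plane axes
            t1 = R.T @ [np.cos(p1), np.sin(p1), 0.0]
            t2 = R.T @ [np.cos(p2), np.sin(p2), 0.0]
            truth = bs.VoxelGroundTruth(fibers=[bs.FiberComponent(f1, t1),
                                                bs.FiberComponent(f2, t2)])
            full = bs.predict_signal(truth, proto)
            simp = bs.predict_signal_simplified(f1, p1, p2, truth.S0, truth.d,
                                                f1 + f2, proto.rotated(R))
            np.testing.assert_allclose(simp, full, atol=1e-10)

    def test_degenerate_single_stick(self):
        proto = bs.make_protocol(16, n_b0=0, with_hypothetical=False)
        one = bs.predict_signal_simplified(0.9, 1.0, 2.0, 400, 1 / 1500, 0.9, proto)
        truth = bs.VoxelGroundTruth(fibers=[
            bs.FiberComponent(0.9, [np.cos(1.0), np.sin(1.0), 0.0])])
        np.testing.assert_allclose(one, bs.predict_signal(truth, proto), atol=1e-10)

    def test_coincident_sticks_ignore_split(self):
        proto = bs.make_protocol(16, n_b0=0, with_hypothetical=False)
        a = bs.predict_signal_simplified(0.2, 1.1, 1.1, 400, 1 / 1500, 0.9, proto)
        b = bs.predict_signal_simplified(0.7, 1.1, 1.1, 400, 1 / 1500, 0.9, proto)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_f1_out_of_range(self):
        proto = bs.make_protocol(16, n_b0=0, with_hypothetical=False)
        with pytest.raises(ValueError):
            bs.predict_signal_simplified(0.95, 1.0, 2.0, 400, 1 / 1500, 0.9, proto)


class TestAddNoise:
    def test_sigma_zero_identity(self, clean_signal):
        np.testing.assert_array_equal(bs.add_noise(clean_signal, 0.0, 1), clean_signal)

    def test_deterministic(self, clean_signal):
        np.testing.assert_array_equal(bs.add_noise(clean_signal, 20.0, 7),
                                      bs.add_noise(clean_signal, 20.0, 7))

    def test_moments(self):
        draws = np.array([bs.add_noise(np.zeros(1), 5.0, s)[0] for s in range(20000)])
        assert draws.mean() == pytest.approx(0.0, abs=0.15)
        assert draws.std() == pytest.approx(5.0, rel=0.02)


class TestInvariances:
    def test_antipodal_symmetry(self, paper_scenario, clean_signal):
        truth, protocol = paper_scenario
        flipped = DWIProtocol(-protocol.bvecs, protocol.bvals)
        np.testing.assert_allclose(bs.predict_signal(truth, flipped),
                                   clean_signal, atol=1e-12)

    def test_rotation_equivariance(self, rng):
        proto = bs.make_protocol(24, n_b0=1, with_hypothetical=False)
        truth = bs.VoxelGroundTruth(fibers=[
            bs.FiberComponent.from_angles(0.4, 0.0, 60.0),
            bs.FiberComponent.from_angles(0.5, 0.0, 120.0)])
        base = bs.predict_signal(truth, proto)
        for rot in Rotation.random(10, random_state=rng):
            rt = bs.VoxelGroundTruth(fibers=[
                bs.FiberComponent(fb.f, rot.apply(fb.orientation))
                for fb in truth.fibers])
            rp = DWIProtocol(rot.apply(proto.bvecs), proto.bvals)
            np.testing.assert_allclose(bs.predict_signal(rt, rp), base, atol=1e-10)

    def test_maximum_along_common_perpendicular(self, paper_scenario):
        truth, _ = paper_scenario
        grid = bs.generate_uniform_directions(500)
        proto = DWIProtocol(grid, np.full(len(grid), 1500.0))
        sig = bs.predict_signal(truth, proto)
        best = grid[np.argmax(sig)]
        # both fibers are in the XY-plane; the max must sit near +-Z
        assert bs.angular_separation(best, [0, 0, 1]) < 6.0


class TestScenarios:
    def test_paper_default(self, paper_scenario):
        truth, protocol = paper_scenario
        assert truth.sigma == 20.0 and truth.S0 == 400.0
        assert int(protocol.dw_mask.sum()) == 64
        np.testing.assert_allclose(truth.fractions, [0.4, 0.5])
        th, ph = bs.angles_from_direction(truth.orientations)
        np.testing.assert_allclose(th, [0.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(ph, [60.0, 120.0], atol=1e-12)

    def test_threefiber_3(self):
        truth, _ = bs.make_scenario("threefiber-3-64")
        np.testing.assert_allclose(truth.fractions, [0.25, 0.25, 0.25])
        expect = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        np.testing.assert_allclose(np.abs(truth.orientations), expect, atol=1e-12)

    def test_unknown_name_lists_known(self):
        with pytest.raises(KeyError, match="paper-default-64"):
            bs.make_scenario("nope-64")
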
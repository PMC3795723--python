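"""Angular-error protocols, fraction recovery, and the FA / fiber-fraction maps."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import diffdecomp as dd
from diffdecomp.evaluation import (
    matched_angular_error,
    fraction_recovery_correlation,
    quantitative_anisotropy,
    tensor_fa,
    total_fiber_fraction_map,
    two_peak_angular_error,
)
from diffdecomp.model import DiffusionDecomposition

MD = 1.0e-3
X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])


class TestTwoPeakAngularError:
    def test_exact_and_penalty_cases(self):
        truth = np.vstack([X, Y])
        assert two_peak_angular_error(truth, truth) == pytest.approx(0.0)
        assert two_peak_angular_error(np.empty((0, 3)), truth) == 45.0

    def test_single_resolved_at_bisector_scores_45(self):
        bis = (X + Y) / np.linalg.norm(X + Y)
        assert two_peak_angular_error(bis[None, :], np.vstack([X, Y])) == pytest.approx(45.0)

    def test_spurious_third_peak_is_discarded(self):
        truth = np.vstack([X, Y])
        with_spur = np.vstack([X, Y, Z])
        assert two_peak_angular_error(with_spur, truth) == two_peak_angular_error(
            truth, truth
        )

    def test_symmetry_and_rotation_invariance(self):
        rng = np.random.default_rng(8)
        resolved = rng.standard_normal((2, 3))
        resolved /= np.linalg.norm(resolved, axis=1, keepdims=True)
        truth = np.vstack([X, Y])
        e = two_peak_angular_error(resolved, truth)
        assert e == pytest.approx(two_peak_angular_error(resolved, truth[::-1]))
        R = Rotation.random(random_state=1).as_matrix()
        assert e == pytest.approx(
            two_peak_angular_error(resolved @ R.T, truth @ R.T), abs=1e-9
        )

    def test_requires_two_truth_axes(self):
        with pytest.raises(ValueError):
            two_peak_angular_error(np.vstack([X]), np.vstack([X]))


class TestMatchedAngularError:
    def test_examples(self):
        assert np.allclose(matched_angular_error([X, Y], [X, Y]), 0.0)
        assert np.allclose(matched_angular_error([X, Y], []), 45.0)
        ref = np.vstack(
            [Rotation.from_euler("z", 10, degrees=True).apply(X),
             Rotation.from_euler("z", 30, degrees=True).apply(X)]
        )
        assert matched_angular_error([X], ref)[0] == pytest.approx(10.0, abs=1e-9)

    def test_never_exceeds_penalty(self):
        rng = np.random.default_rng(2)
        q = rng.standard_normal((5, 3))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        r = rng.standard_normal((3, 3))
        r /= np.linalg.norm(r, axis=1, keepdims=True)
        assert matched_angular_error(q, r).max() <= 45.0


class TestFractionCorrelation:
    def test_identity_permutation_and_groups(self):
        rng = np.random.default_rng(3)
        truth = rng.uniform(0.1, 0.7, 4000)
        assert fraction_recovery_correlation(truth, truth) == pytest.approx(1.0)
        shuffled = rng.permutation(truth)
        assert abs(fraction_recovery_correlation(shuffled, truth)) < 3 / np.sqrt(4000)
        fa = np.repeat([0.4, 0.7], 2000)
        per_fa = fraction_recovery_correlation(truth, truth, group_by_fa=fa)
        assert set(per_fa) == {0.4, 0.7}

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            fraction_recovery_correlation(np.ones(10), np.linspace(0, 1, 10))


def test_total_fiber_fraction_examples():
    fractions = np.zeros((2, 321))
    fractions[0, [5, 9]] = [0.3, 0.2]  # f0 = 0.5 voxel
    out = total_fiber_fraction_map(fractions)
    assert out[0] == pytest.approx(0.5)
    assert out[1] == 0.0  # purely isotropic voxel
    assert total_fiber_fraction_map(fractions, normalize=True).max() == 1.0


class TestTensorFA:
    def test_isotropic_stick_and_round_trip(self, btable):
        iso = dd.crossing_voxel(1.0, 0.0, 90.0, 0.5, MD)
        assert tensor_fa(dd.simulate_signal(iso, btable), btable) < 1e-9

        stick = np.diag([3 * MD, 0.0, 0.0])
        vox = dd.VoxelModel(
            s0=1.0, f0=0.0, fibers=(dd.Fiber(1.0, X, stick),), iso_diffusivity=MD
        )
        assert tensor_fa(dd.simulate_signal(vox, btable), btable) == pytest.approx(
            1.0, abs=1e-6
        )

        vox = dd.VoxelModel(
            s0=1.0,
            f0=0.0,
            fibers=(dd.Fiber(1.0, Z, dd.make_axisymmetric_tensor(0.6, MD, Z)),),
            iso_diffusivity=MD,
        )
        assert tensor_fa(dd.simulate_signal(vox, btable), btable) == pytest.approx(
            0.6, abs=1e-6
        )

    def test_rank_deficient_design_rejected(self):
        # all gradients along one axis cannot determine a tensor
        bvecs = np.vstack([np.zeros(3)] + [Z] * 8)
        bt = dd.BTable(np.array([0.0] + [1000.0] * 8), bvecs)
        with pytest.raises(ValueError):
            tensor_fa(np.ones(9), bt)


def test_crossing_slab_fraction_map_flatter_than_fa(btable, dirs, basis):
    """On a synthetic slab of constant fiber content, the total-fraction map
    varies less across crossing and single-fiber voxels than the FA map."""
    voxels = [dd.crossing_voxel(0.2, 0.8, 0.0, 0.7, MD) for _ in range(10)]
    voxels += [dd.crossing_voxel(0.2, 0.4, 90.0, 0.7, MD) for _ in range(10)]
    rng = np.random.default_rng(12)
    signals = np.array(
        [
            dd.add_rician_noise(dd.simulate_signal(v, btable), 1 / 80.0, seed=rng)
            for v in voxels
        ]
    )
    results = DiffusionDecomposition(signals, btable, basis=basis).fit()
    total = total_fiber_fraction_map(results)
    fa_map = np.array([tensor_fa(s, btable) for s in signals])
    cv = lambda x: x.std() / x.mean()
    assert cv(total) < cv(fa_map)
    # the slab is all white-matter-like: the QA mask keeps every voxel
    dodfs = dd.reconstruct_dodfs(signals, btable, dirs)
    qa = np.array([quantitative_anisotropy(row) for row in dodfs])
    assert np.all(qa > 0.5 * np.median(qa))
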
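"""The selection-decomposition recursion and the pruned OLS fraction estimate."""

import numpy as np
import pytest

import diffdecomp as dd
from diffdecomp.decomposition import (
    DecompositionParams,
    DegenerateODFError,
    adaptive_first_fraction,
    diffusion_decomposition,
    estimate_fractions,
    normalize_dodf,
    select_component,
    selection_decomposition,
)
from diffdecomp.geometry import axis_angle_matrix, find_peaks
from diffdecomp.model import _batch_selection
from diffdecomp.reconstruction import ODF, reconstruct_dodf

MD = 1.0e-3


def crossing_signal(btable, f1, angle, fa, f0=0.2, noise=None, rng=None):
    vox = dd.crossing_voxel(f0, f1, angle, fa, MD)
    sig = dd.simulate_signal(vox, btable)
    if noise:
        sig = dd.add_rician_noise(sig, noise, seed=rng)
    return sig, vox


class TestNormalize:
    def test_contract_and_idempotence(self):
        rng = np.random.default_rng(0)
        v = rng.random(321)
        n = normalize_dodf(v)
        assert abs(n.mean()) < 1e-12
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(normalize_dodf(n), n, atol=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateODFError):
            normalize_dodf(np.full(321, 3.7))


class TestSelect:
    def test_self_correlation_and_nonpositive_case(self, basis, dirs):
        assert select_component(basis.normalized[:, 57], basis) == 57
        # the nonpositive-correlation branch: on a small synthetic basis with
        # orthonormal columns, the negated column sum correlates with nothing
        from diffdecomp.geometry import reduce_antipodal, tessellate_icosahedron
        from diffdecomp.reconstruction import ComponentBasis

        six = reduce_antipodal(tessellate_icosahedron(1))
        eye = np.eye(6)
        tiny = ComponentBasis(
            components=eye, normalized=eye, directions=six, sigma_deg=9.0
        )
        assert select_component(-np.ones(6), tiny) is None

    def test_matches_bruteforce_argmax(self, basis):
        rng = np.random.default_rng(2)
        for _ in range(20):
            psi = normalize_dodf(rng.random(basis.n_components))
            c = basis.normalized.T @ psi
            expected = int(np.argmax(c)) if c.max() > 0 else None
            assert select_component(psi, basis) == expected


class TestAdaptiveFirstFraction:
    def test_already_tied_competitor_gives_zero(self, basis):
        """Once the adaptive step has tied two components, the next least step is zero."""
        psi = basis.normalized[:, 100]
        eps1 = adaptive_first_fraction(psi, basis, 100)
        tied = psi - eps1 * basis.normalized[:, 100]
        k = int(np.argmax(basis.normalized.T @ tied))
        assert adaptive_first_fraction(tied, basis, k) == pytest.approx(0.0, abs=1e-9)

    def test_matches_fine_grid_scan(self, basis):
        """The adaptive fraction equals the first grid step where the argmax moves."""
        rng = np.random.default_rng(5)
        psi = normalize_dodf(
            0.8 * basis.components[:, 30] + 0.3 * basis.components[:, 290]
            + 0.01 * rng.random(basis.n_components)
        )
        k = select_component(psi, basis)
        eps1 = adaptive_first_fraction(psi, basis, k)
        c0 = basis.normalized.T @ psi
        grid = np.arange(0.0, 1.0, 1e-4)
        corr = c0[None, :] - grid[:, None] * basis.gram[:, k][None, :]
        moved = np.flatnonzero(np.argmax(corr, axis=1) != k)
        assert moved.size > 0
        assert eps1 == pytest.approx(grid[moved[0]], abs=2e-4)

    def test_pure_component_ties_a_neighbour_after_the_step(self, basis):
        psi = basis.normalized[:, 160]
        eps1 = adaptive_first_fraction(psi, basis, 160)
        assert 0.0 < eps1 < 1.0
        c = basis.normalized.T @ psi - eps1 * basis.gram[:, 160]
        others = np.delete(c, 160)
        assert others.max() == pytest.approx(c[160], abs=1e-9)


class TestSelectionDecomposition:
    def test_single_component_voxel_selects_it_first(self, basis):
        y = 0.3 / 321 + 0.7 * basis.components[:, 42]
        active, _, n_iter = selection_decomposition(ODF(y), basis)
        assert active[0] == 42
        assert n_iter >= 1

    def test_equal_ninety_degree_crossing_selects_both_axes(self, dirs, btable, basis):
        sig, vox = crossing_signal(btable, 0.4, 90.0, 0.7)
        dodf = reconstruct_dodf(sig, btable, dirs)
        active, _, _ = selection_decomposition(dodf, basis)
        assert len(active) >= 2
        top2 = dirs.vectors[list(active[:2])]
        err = axis_angle_matrix(top2, vox.axes).min(axis=1)
        assert err.max() <= 8.0

    def test_active_set_bounded_and_degenerate_empty(self, btable, dirs, basis):
        rng = np.random.default_rng(9)
        for _ in range(10):
            sig, _ = crossing_signal(
                btable, rng.uniform(0.2, 0.7), rng.uniform(18, 90),
                rng.choice([0.4, 0.7]), noise=0.025, rng=rng,
            )
            dodf = reconstruct_dodf(sig, btable, dirs)
            active, _, _ = selection_decomposition(dodf, basis)
            assert len(active) <= 10
        assert selection_decomposition(np.ones(321), basis)[0] == ()

    def test_correlation_trace_descends_and_terminates(self, btable, dirs, basis):
        """The max correlation ends at or below zero and never exceeds its
        starting level by more than one decomposition step.

        Strict per-step monotonicity does not hold for this recursion: when
        two components are anticorrelated, peeling one raises the other's
        correlation by epsilon times the (negative) Gram entry.
        """
        params = DecompositionParams(adaptive_first=False)
        sig, _ = crossing_signal(btable, 0.45, 60.0, 0.7)
        w = normalize_dodf(reconstruct_dodf(sig, btable, dirs))
        c = basis.normalized.T @ w
        trace = [c.max()]
        active: set[int] = set()
        for _ in range(params.max_iterations):
            k = int(np.argmax(c))
            if c[k] <= 0 or len(active) >= params.m:
                break
            c = c - params.epsilon * basis.gram[:, k]
            active.add(k)
            trace.append(c.max())
        assert len(trace) < params.max_iterations  # the recursion terminates
        assert trace[-1] < trace[0]
        assert max(trace[1:]) <= trace[0] + params.epsilon

    def test_batch_path_matches_reference(self, btable, dirs, basis):
        """The vectorised multi-voxel recursion replays the per-voxel one."""
        rng = np.random.default_rng(3)
        sigs = []
        for _ in range(12):
            s, _ = crossing_signal(
                btable, rng.uniform(0.3, 0.7), rng.uniform(18, 90),
                rng.choice([0.4, 0.7]), noise=0.025, rng=rng,
            )
            sigs.append(s)
        dodfs = dd.reconstruct_dodfs(np.array(sigs), btable, dirs)
        params = DecompositionParams()
        stamps, iters = _batch_selection(dodfs, basis, params)
        for v in range(len(sigs)):
            active, _, n_iter = selection_decomposition(dodfs[v], basis, params)
            sel = np.flatnonzero(stamps[v] >= 0)
            order = tuple(sel[np.argsort(stamps[v, sel])])
            assert order == active
            assert n_iter == iters[v]


class TestEstimateFractions:
    def test_exact_mixture_recovered(self, basis):
        y = 0.3 / 321 + 0.7 * basis.components[:, 42]
        f0, fr, resid = estimate_fractions(y, basis, [42], return_residual=True)
        assert f0 == pytest.approx(0.3, abs=1e-6)
        assert fr[42] == pytest.approx(0.7, abs=1e-6)
        assert np.count_nonzero(fr) == 1
        assert resid < 1e-9

    def test_constant_dodf_is_pure_isotropy(self, basis):
        # the isotropic regressor is the unit-sum uniform ODF e/321, so a
        # constant dODF of value 2 carries coefficient 2 * 321
        f0, fr = estimate_fractions(np.full(321, 2.0), basis, [])
        assert fr.sum() == 0.0
        assert f0 == pytest.approx(2.0 * 321)

    def test_pruning_enforces_nonnegativity(self, basis):
        """Deliberately over-complete active sets still return nonnegative fits."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            A = rng.choice(basis.n_components, size=10, replace=False)
            y = np.clip(
                0.2 / 321
                + basis.components[:, rng.choice(basis.n_components, 3)] @ rng.random(3)
                + 0.02 * rng.standard_normal(basis.n_components),
                0, None,
            )
            f0, fr = estimate_fractions(y, basis, list(A))
            assert f0 >= 0.0
            assert fr.min() >= 0.0
            assert np.all(fr[np.setdiff1d(np.arange(321), A)] == 0.0)


class TestDiffusionDecomposition:
    def test_constant_dodf_yields_no_fibers(self, basis):
        res = diffusion_decomposition(np.full(321, 1.0), basis)
        assert res.fractions.sum() == 0.0
        assert res.active_set == ()

    def test_sparsity_and_nonnegativity_on_noisy_voxels(self, btable, basis):
        rng = np.random.default_rng(6)
        for _ in range(25):
            sig, _ = crossing_signal(
                btable, rng.uniform(0.2, 0.7), rng.uniform(18, 90),
                rng.choice([0.4, 0.5, 0.6, 0.7]), noise=0.025, rng=rng,
            )
            res = diffusion_decomposition(sig, basis, btable=btable)
            assert np.count_nonzero(res.fractions) <= 10
            assert res.f0 >= 0 and res.fractions.min() >= 0

    def test_spin_density_scaling(self, btable, basis):
        sig, _ = crossing_signal(btable, 0.4, 90.0, 0.7)
        sig = 3.0 * sig  # baseline of 3
        res = diffusion_decomposition(sig, basis, btable=btable)
        assert res.spin_scale == pytest.approx(3.0)
        assert res.f0 + res.fractions.sum() == pytest.approx(3.0, rel=1e-9)
        assert res.normalized_f0 + res.normalized_fractions.sum() == pytest.approx(1.0)

    def test_peak_orientations_insensitive_to_epsilon(self, btable, dirs, basis):
        """Noise-free two-fiber peaks agree across decomposition fractions."""
        sig, _ = crossing_signal(btable, 0.4, 75.0, 0.7)
        tops = []
        for eps in (0.01, 0.05, 0.2):
            res = diffusion_decomposition(
                sig, basis, DecompositionParams(epsilon=eps), btable=btable
            )
            pk = find_peaks(res.normalized_fractions, dirs, min_fraction=0.05)
            tops.append(frozenset(p.index for p in pk[:2]))
        assert tops[0] == tops[1] == tops[2]
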
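"""FC construction, affinity kernel, diffusion embedding, alignment, dispersion."""

import numpy as np
import pytest
from scipy import linalg

from psychspeech.gradients import (
    DiffusionGradients,
    affinity,
    align_gradients,
    compute_fc,
    diffusion_gradients,
    dispersion_between,
    dispersion_within,
    fit_cohort_gradients,
    sparsify_rows,
)


class TestComputeFC:
    def test_matches_brute_force_pearson_arctanh(self):
        # tiny printed dataset, oracle = per-pair Pearson + arctanh by hand
        ts = np.array([
            [1.0, 2.0, 0.5],
            [2.0, 1.5, 0.8],
            [3.0, 3.5, 0.2],
            [4.0, 2.5, 0.9],
            [5.0, 4.0, 0.1],
        ])
        fc = compute_fc(ts, ["a", "b", "c"])
        for i in range(3):
            for j in range(3):
                if i == j:
                    assert fc.values[i, j] == 0.0
                else:
                    x, y = ts[:, i], ts[:, j]
                    r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                    assert fc.values[i, j] == pytest.approx(np.arctanh(r), abs=1e-10)

    def test_perfect_anticorrelation_is_clipped(self):
        x = np.linspace(0, 1, 10)
        fc = compute_fc(np.column_stack([x, -x]))
        assert fc.values[0, 1] == pytest.approx(np.arctanh(-0.999999))

    def test_constant_column_raises_with_roi_name(self):
        ts = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="roiB"):
            compute_fc(ts, ["roiA", "roiB"])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        ts = rng.standard_normal((30, 5))
        perm = [3, 0, 4, 1, 2]
        fc = compute_fc(ts)
        fc_p = compute_fc(ts[:, perm])
        assert np.allclose(fc_p.values, fc.values[np.ix_(perm, perm)])


class TestSparsifyRows:
    def test_all_negative_row_becomes_zero(self):
        a = -np.ones((4, 4))
        out = sparsify_rows(a, 0.5)
        assert np.all(out == 0)

    def test_keeps_ceil_fraction_per_row(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.1, 1.0, size=(11, 11))
        np.fill_diagonal(a, 0.0)
        out = sparsify_rows(a, 0.10)  # ceil(0.1 * 10) = 1 survivor per row
        assert all(np.count_nonzero(out[i]) == 1 for i in range(11))

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((20, 20))
        once = sparsify_rows(a, 0.2)
        assert np.array_equal(sparsify_rows(once, 0.2), once)

    def test_ties_prefer_lower_column_index(self):
        a = np.array([[0.0, 0.5, 0.5, 0.5],
                      [0.5, 0.0, 0.1, 0.1],
                      [0.5, 0.1, 0.0, 0.1],
                      [0.5, 0.1, 0.1, 0.0]])
        out = sparsify_rows(a, 1 / 3)  # keep ceil(1) = 1
        assert out[0, 1] == 0.5 and out[0, 2] == 0.0 and out[0, 3] == 0.0


class TestAffinity:
    def test_identical_orthogonal_antipodal_rows(self):
        a = np.array([[1.0, 0.0, 0.0],
                      [1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0],
                      [-1.0, 0.0, 0.0]])
        out = affinity(a)
        assert out[0, 1] == pytest.approx(1.0)
        assert out[0, 2] == pytest.approx(0.5)
        assert out[0, 3] == pytest.approx(0.0, abs=1e-7)

    def test_zero_row_raises_with_name(self):
        a = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="r2"):
            affinity(a, roi_labels=["r1", "r2"])


class TestDiffusionGradients:
    @staticmethod
    def _two_block_affinity():
        a = np.full((10, 10), 0.1)
        a[:5, :5] = 1.0
        a[5:, 5:] = 1.0
        np.fill_diagonal(a, 1.0)
        return a

    def test_g1_separates_two_blocks(self):
        g = diffusion_gradients(self._two_block_affinity(), k=3)
        g1 = g.coords[:, 0]
        assert len(set(np.sign(g1[:5]))) == 1
        assert len(set(np.sign(g1[5:]))) == 1
        assert np.sign(g1[0]) != np.sign(g1[5])

    def test_matches_direct_eigendecomposition(self):
        # independent oracle: eigendecompose the Markov operator directly
        a = self._two_block_affinity()
        alpha = 0.5
        d = a.sum(1)
        w = a / np.outer(d**alpha, d**alpha)
        p = w / w.sum(1, keepdims=True)
        evals, evecs = linalg.eig(p)
        order = np.argsort(-evals.real)
        lam1 = evals.real[order[1]]
        v1 = evecs[:, order[1]].real
        v1 = v1 if v1[np.argmax(np.abs(v1))] > 0 else -v1
        g = diffusion_gradients(a, k=3)
        got = g.coords[:, 0]
        # same direction up to scale
        cos = got @ v1 / (np.linalg.norm(got) * np.linalg.norm(v1))
        assert cos == pytest.approx(1.0, abs=1e-8)
        assert g.lambdas[0] == pytest.approx(lam1, abs=1e-10)

    def test_uniform_affinity_gives_zero_gradients(self):
        a = np.full((8, 8), 0.7)
        np.fill_diagonal(a, 1.0)
        g = diffusion_gradients(a, k=3)
        # rank-1-plus-diagonal kernel: non-trivial structure collapses
        assert np.all(np.abs(g.coords) < 1e-10) or np.all(g.lambdas < 0.3)

    def test_variance_explained_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            b = rng.uniform(0.05, 1.0, size=(12, 12))
            a = (b + b.T) / 2
            np.fill_diagonal(a, 1.0)
            g = diffusion_gradients(a, k=5)
            ve = g.variance_explained
            assert np.all(np.diff(ve) <= 1e-12)
            assert np.all((ve >= 0) & (ve <= 1))
            assert ve.sum() <= 1 + 1e-12

    def test_disconnected_graph_raises(self):
        a = np.zeros((6, 6))
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            diffusion_gradients(a, k=2)


class TestAlignment:
    @staticmethod
    def _gradients(seed=0, r=20, k=5):
        rng = np.random.default_rng(seed)
        b = rng.uniform(0.05, 1.0, size=(r, r))
        a = (b + b.T) / 2
        np.fill_diagonal(a, 1.0)
        return diffusion_gradients(a, k=k)

    def test_self_alignment_is_identity(self):
        g = self._gradients()
        aligned = align_gradients(g, g)
        assert np.allclose(aligned.coords, g.coords, atol=1e-10)

    def test_column_sign_flips_recovered(self):
        g = self._gradients()
        flipped = self._gradients()
        flipped.coords = flipped.coords * np.array([1, -1, 1, -1, 1.0])
        aligned = align_gradients(flipped, g)
        assert np.allclose(aligned.coords, g.coords, atol=1e-8)

    def test_random_rotation_recovered(self):
        g = self._gradients(seed=4)
        q, _ = np.linalg.qr(np.random.default_rng(5).standard_normal((5, 5)))
        rotated = self._gradients(seed=4)
        rotated.coords = rotated.coords @ q
        aligned = align_gradients(rotated, g)
        assert np.allclose(aligned.coords, g.coords, atol=1e-8)

    def test_alignment_preserves_pairwise_distances(self):
        g = self._gradients(seed=6)
        template = self._gradients(seed=7)
        aligned = align_gradients(g, template)
        d_before = np.linalg.norm(g.coords[:, None] - g.coords[None], axis=2)
        d_after = np.linalg.norm(aligned.coords[:, None] - aligned.coords[None], axis=2)
        assert np.allclose(d_before, d_after, atol=1e-8)


class TestDispersion:
    @staticmethod
    def _gset(values):
        from psychspeech.gradients import GradientSet

        coords = np.asarray(values, dtype=float)[:, None]
        return GradientSet(coords=coords, lambdas=np.ones(1),
                           variance_explained=np.ones(1),
                           roi_labels=[f"r{i}" for i in range(len(values))])

    def test_between_hand_value_and_antisymmetry(self):
        g = self._gset([1.0, 3.0, 0.0])
        part = {"r0": "A", "r1": "A", "r2": "B"}
        assert dispersion_between(g, part, "A", "B", 0) == pytest.approx(2.0)
        assert dispersion_between(g, part, "B", "A", 0) == pytest.approx(-2.0)
        assert dispersion_between(g, part, "A", "A", 0) == 0.0

    def test_empty_network_raises(self):
        g = self._gset([1.0, 2.0])
        with pytest.raises(ValueError, match="no ROIs"):
            dispersion_between(g, {"r0": "A", "r1": "A"}, "A", "B", 0)

    def test_within_hand_value_and_homogeneity(self):
        g = self._gset([1.0, 2.0, 3.0])
        assert dispersion_within(g, ["r0", "r1", "r2"], 0) == pytest.approx(2.0)
        g2 = self._gset([3.0, 6.0, 9.0])
        assert dispersion_within(g2, ["r0", "r1", "r2"], 0) == pytest.approx(18.0)
        with pytest.raises(ValueError):
            dispersion_within(g, ["r0"], 0)

    def test_constant_coords_zero(self):
        g = self._gset([2.0, 2.0, 2.0])
        assert dispersion_within(g, ["r0", "r1", "r2"], 0) == 0.0


def test_pipeline_relabeling_equivariance():
    """Relabeling ROIs permutes the gradient/dispersion outputs consistently."""
    rng = np.random.default_rng(11)
    # a shared signal keeps every row's connectivity profile non-negative
    ts = [rng.standard_normal((60, 8)) + 0.8 * rng.standard_normal((60, 1))
          for _ in range(3)]
    labels = [f"r{i}" for i in range(8)]
    perm = [5, 2, 7, 0, 1, 3, 6, 4]
    tmpl, subs, _ = fit_cohort_gradients(ts, labels, k=3, keep_fraction=0.5)
    tmpl_p, subs_p, _ = fit_cohort_gradients(
        [t[:, perm] for t in ts], [labels[i] for i in perm], k=3,
        keep_fraction=0.5)
    # eigenvector sign/rotation is resolved by the deterministic sign rule,
    # so template coords must match up to the permutation exactly
    assert np.allclose(tmpl_p.coords, tmpl.coords[perm], atol=1e-8)
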
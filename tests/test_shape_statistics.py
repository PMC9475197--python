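"""Geodesics, Karcher means, shape PCA, scores, and reconstruction."""

import numpy as np
import pytest

import srnfshape as ss
from srnfshape.shape_statistics import KarcherMean
from srnfshape.synthetic_data import (
    base_surface,
    make_mode_fields,
    random_diffeomorphism,
)


@pytest.fixture(scope="module")
def bent_pair(grid32):
    """A bent tube and a reparameterized copy (same shape, new labels)."""
    mu = ss.center_and_scale(
        base_surface(grid32, kind="bent-tube", axes=(1.0, 0.45, 0.45))
    )
    gam = random_diffeomorphism(grid32, amplitude=0.3, seed=42)
    f2 = ss.center_and_scale(ss.apply_reparam(mu, gam))
    return mu, f2


@pytest.fixture(scope="module")
def aligned_family(grid32):
    spec = ss.SurfaceFamilySpec(
        n=30, n_modes=2, mode_sds=(0.04, 0.02), noise_sd=0.0, seed=9, grid=grid32
    )
    surfaces, planted, modes = ss.generate_family(spec)
    mu = ss.GridSurface(grid32, np.mean([s.f for s in surfaces], axis=0))
    mean = KarcherMean(mu=mu, registered=surfaces, variance_trace=[])
    return mean, planted, modes


def test_geodesic_endpoints_exact(bent_pair):
    f1, f2 = bent_pair
    path = ss.geodesic_path(f1, f2, m=5)
    assert np.allclose(path.steps[0].f, f1.f)
    assert path.times[0] == 0.0 and path.times[-1] == 1.0
    # last step is the registered version of f2, not f2 itself
    assert len(path.steps) == 5


def test_geodesic_identical_surfaces_constant(bent_pair):
    f1 = bent_pair[0]
    path = ss.geodesic_path(f1, f1, m=4)
    for s in path.steps:
        assert np.allclose(s.f, f1.f, atol=1e-6)


def test_registered_geodesic_preserves_local_features(bent_pair):
    """The midpoint of the registered path moves nodes far less than the
    unregistered path (parameterization mismatch shows up as spurious
    within-shape motion), and never pinches degenerate."""
    f1, f2 = bent_pair
    reg_path = ss.geodesic_path(f1, f2, m=3, register=True)
    unreg_path = ss.geodesic_path(f1, f2, m=3, register=False)

    def max_disp(path):
        return max(
            np.linalg.norm(path.steps[1].f - e.f, axis=-1).max()
            for e in (path.steps[0], path.steps[2])
        )

    assert max_disp(reg_path) < max_disp(unreg_path)
    mid_area = ss.surface_area(reg_path.steps[1])
    ends = [ss.surface_area(reg_path.steps[0]), ss.surface_area(reg_path.steps[2])]
    assert 0.5 * min(ends) < mid_area < 2.0 * max(ends)


def test_karcher_mean_of_identical_surfaces(grid32):
    mu = ss.center_and_scale(base_surface(grid32))
    km = ss.karcher_mean([mu.copy(), mu.copy(), mu.copy()])
    assert np.allclose(km.mu.f, mu.f, atol=1e-8)
    assert km.variance_trace[-1] < 1e-10
    assert len(km.registered) == 3


def test_karcher_mean_single_surface(grid32):
    mu = ss.center_and_scale(base_surface(grid32))
    km = ss.karcher_mean([mu])
    assert np.allclose(km.mu.f, mu.f, atol=1e-8)


def test_karcher_mean_removes_parameterization_variance(bent_pair):
    """Same shape under two parameterizations: the registered Karcher
    variance collapses far below the naive Euclidean variance."""
    f1, f2 = bent_pair
    km = ss.karcher_mean([f1, f2])
    assert all(
        a >= b - 1e-15 for a, b in zip(km.variance_trace, km.variance_trace[1:])
    )
    fbar = 0.5 * (f1.f + f2.f)
    g = f1.grid
    var_unreg = ss.norm_l2(f1.f - fbar, g) ** 2 + ss.norm_l2(f2.f - fbar, g) ** 2
    assert km.variance_trace[-1] < 0.01 * var_unreg


def test_pca_identical_surfaces_degenerate(grid32):
    mu = ss.center_and_scale(base_surface(grid32))
    mean = KarcherMean(mu=mu, registered=[mu.copy(), mu.copy()], variance_trace=[])
    basis = ss.shape_pca(mean)
    assert basis.singular_values.size == 0
    assert basis.directions.shape[1] == 0


def test_pca_recovers_planted_single_mode(grid32):
    spec = ss.SurfaceFamilySpec(
        n=30, n_modes=1, mode_sds=(0.04,), noise_sd=0.0, seed=3, grid=grid32
    )
    surfaces, _, modes = ss.generate_family(spec)
    mu = ss.GridSurface(grid32, np.mean([s.f for s in surfaces], axis=0))
    basis = ss.shape_pca(KarcherMean(mu=mu, registered=surfaces, variance_trace=[]))
    cosine = abs(basis.directions[:, 0] @ modes[0].reshape(-1))
    assert cosine > 0.999
    if basis.singular_values.size > 1:
        assert basis.singular_values[1] < 1e-3 * basis.singular_values[0]


def test_pca_directions_orthonormal(aligned_family):
    mean, _, _ = aligned_family
    basis = ss.shape_pca(mean)
    gram = basis.directions.T @ basis.directions
    assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8
    assert np.all(np.diff(basis.singular_values) <= 1e-12)
    assert basis.directions.shape[1] <= mean.mu.f.size


def test_cumulative_variance_arithmetic():
    basis = ss.PCABasis(
        mu=None, directions=np.eye(2), singular_values=np.array([3.0, 1.0]), n_train=2
    )
    assert np.allclose(ss.cumulative_variance(basis), [0.75, 1.0])


def test_cumulative_variance_monotone_ends_at_one(aligned_family):
    mean, _, _ = aligned_family
    cum = ss.cumulative_variance(ss.shape_pca(mean))
    assert np.all(np.diff(cum) >= -1e-12)
    assert np.isclose(cum[-1], 1.0)


def test_scores_of_mean_are_zero(aligned_family):
    mean, _, _ = aligned_family
    basis = ss.shape_pca(mean)
    z = ss.principal_scores(mean.mu, basis)
    assert np.abs(z.scores).max() < 1e-10


def test_scores_recover_planted_coefficient(aligned_family):
    mean, _, _ = aligned_family
    basis = ss.shape_pca(mean)
    u1 = basis.directions[:, 0].reshape(mean.mu.f.shape)
    f = ss.GridSurface(mean.mu.grid, mean.mu.f + 2.0 * u1)
    z = ss.principal_scores(f, basis, k=3)
    assert np.isclose(z.scores[0], 2.0, atol=1e-8)
    assert np.abs(z.scores[1:]).max() < 1e-8


def test_training_scores_have_zero_mean(aligned_family):
    mean, _, _ = aligned_family
    basis = ss.shape_pca(mean)
    all_scores = np.stack(
        [ss.principal_scores(s, basis).scores for s in mean.registered]
    )
    assert np.abs(all_scores.mean(axis=0)).max() < 1e-8


def test_reconstruction_round_trip_and_monotone_error(aligned_family):
    mean, _, _ = aligned_family
    basis = ss.shape_pca(mean)
    k_full = basis.directions.shape[1]
    for s in mean.registered[:5]:
        z = ss.principal_scores(s, basis)
        full = ss.reconstruct(basis, z)
        assert np.linalg.norm(full.f - s.f) < 1e-6
        # monotone in the Euclidean norm the projection is orthogonal in
        errs = []
        for k in range(k_full + 1):
            zk = ss.ScoreVector(scores=z.scores[:k])
            rec = ss.reconstruct(basis, zk)
            errs.append(np.linalg.norm(rec.f - s.f))
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


def test_reconstruct_zero_scores_is_mean(aligned_family):
    mean, _, _ = aligned_family
    basis = ss.shape_pca(mean)
    rec = ss.reconstruct(basis, ss.ScoreVector(scores=np.zeros(0)))
    assert np.allclose(rec.f, mean.mu.f)


def test_train_test_split_protocol(grid32):
    """Fit the basis on 80% of the family, score and reconstruct the rest."""
    spec = ss.SurfaceFamilySpec(
        n=20, n_modes=2, mode_sds=(0.04, 0.02), noise_sd=1e-4, seed=21, grid=grid32
    )
    surfaces, _, _ = ss.generate_family(spec)
    train, test = surfaces[:16], surfaces[16:]
    mu = ss.GridSurface(grid32, np.mean([s.f for s in train], axis=0))
    basis = ss.shape_pca(KarcherMean(mu=mu, registered=train, variance_trace=[]))
    for s in test:
        z = ss.principal_scores(s, basis)
        errs = [
            np.linalg.norm(ss.reconstruct(basis, ss.ScoreVector(z.scores[:k])).f - s.f)
            for k in (0, 1, basis.directions.shape[1])
        ]
        assert errs[0] >= errs[1] >= errs[2]


def test_area_weighted_pca_round_trip(aligned_family):
    """The area-weighted PCA variant stays self-consistent: orthonormal
    in its inner product and exact on the full-rank round trip."""
    mean, _, _ = aligned_family
    basis = ss.shape_pca(mean, area_weighted=True)
    gram = basis.directions.T @ basis.directions
    assert np.abs(gram - np.eye(gram.shape[0])).max() < 1e-8
    s = mean.registered[0]
    z = ss.principal_scores(s, basis)
    rec = ss.reconstruct(basis, z)
    assert np.linalg.norm(rec.f - s.f) < 1e-6


def test_deformation_colormap_properties(aligned_family):
    mean, _, _ = aligned_family
    ref = mean.mu
    surfaces = mean.registered[:6]
    maps = [ss.deformation_colormap(s, ref, surfaces) for s in surfaces]
    peak = max(m.max() for m in maps)
    assert np.isclose(peak, 1.0)
    self_map = ss.deformation_colormap(ref, ref, surfaces)
    assert np.all(self_map == 0.0)


def test_deformation_colormap_localizes_bump(grid32):
    mu = ss.center_and_scale(base_surface(grid32))
    bumped = mu.copy()
    bumped.f[10:13, 5:8] += 0.05
    cmap = ss.deformation_colormap(bumped, mu, [bumped])
    i, j = np.unravel_index(np.argmax(cmap), cmap.shape)
    assert 10 <= i < 13 and 5 <= j < 8
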
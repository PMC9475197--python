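"""Population shape statistics: geodesics, Karcher mean, and shape PCA.

The Karcher (Frechet) mean minimizes the sum of squared elastic shape
distances to the sample.  It is computed by alternating two steps:
register every surface to the current mean estimate, then replace the
mean by the nodewise Euclidean average of the registered surfaces.  PCA
is performed on vectorized registered surfaces about the mean; principal
scores are plain Euclidean inner products with the principal directions
and invert exactly to reconstructions when all components are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere_grid import GridSurface, norm_l2
from .srnf_registration import RegistrationConfig, register_pair

__all__ = [
    "GeodesicPath",
    "KarcherMean",
    "PCABasis",
    "ScoreVector",
    "geodesic_path",
    "karcher_mean",
    "shape_pca",
    "cumulative_variance",
    "principal_scores",
    "reconstruct",
    "deformation_colormap",
]


@dataclass
class GeodesicPath:
    """Linear-interpolation geodesic between f1 and the registered f2*."""

    steps: list
    times: np.ndarray


@dataclass
class KarcherMean:
    mu: GridSurface
    registered: list
    variance_trace: list = field(default_factory=list)


@dataclass
class PCABasis:
    """Shape PCA about a Karcher mean.

    ``directions`` has one orthonormal column per retained component in
    vectorized surface space (length 3 * n_theta * n_phi);
    ``singular_values`` are the eigenvalues of the scatter matrix
    ``C = sum_i V_i V_i^T``, ``V_i = vec(f_i* - mu)``, sorted descending.
    """

    mu: GridSurface
    directions: np.ndarray
    singular_values: np.ndarray
    n_train: int
    #: sqrt quadrature weights per vectorized entry when the PCA was run
    #: in the area-weighted inner product; None for the plain Euclidean one
    node_weights: np.ndarray | None = None


@dataclass
class ScoreVector:
    scores: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.size


def geodesic_path(
    f1: GridSurface,
    f2: GridSurface,
    m: int = 7,
    config: RegistrationConfig | None = None,
    register: bool = True,
) -> GeodesicPath:
    """Straight-line path ``alpha_tau = (1 - tau) f1 + tau f2*``.

    With ``register=True`` (the default) ``f2`` is first elastically
    registered to ``f1``; the unregistered path is available for
    comparison with ``register=False``.
    """
    if m < 2:
        raise ValueError("a geodesic needs at least its two endpoints")
    if register:
        f2_star = register_pair(f1, f2, config=config).registered_surface
    else:
        f2_star = f2
    times = np.linspace(0.0, 1.0, m)
    steps = [
        GridSurface(f1.grid, (1.0 - t) * f1.f + t * f2_star.f, f"geodesic tau={t:.3f}")
        for t in times
    ]
    return GeodesicPath(steps=steps, times=times)


def karcher_mean(
    surfaces: list,
    config: RegistrationConfig | None = None,
    tol: float = 1e-4,
    max_iter: int = 20,
) -> KarcherMean:
    """Iterative Karcher mean of a set of normalized surfaces.

    Initialization is the first surface in input order.  Each outer
    iteration registers every surface to the current mean, averages the
    registered surfaces nodewise, and records the Karcher variance
    ``sum_i d_s(mu, f_i)^2``.  Iteration stops when the relative L2
    change of the mean drops below ``tol``.
    """
    if not surfaces:
        raise ValueError("karcher_mean requires at least one surface")
    grid = surfaces[0].grid
    for s in surfaces:
        if not s.grid.same_as(grid):
            raise ValueError("all surfaces must share one grid")

    mu = surfaces[0].copy(provenance="karcher-mean")
    registered = list(surfaces)
    prev_registered = registered
    variance_trace: list[float] = []
    for _ in range(max_iter):
        results = []
        for s in surfaces:
            try:
                results.append(register_pair(mu, s, config=config))
            except Exception:
                # keep the surface with identity registration rather than drop it
                import warnings

                warnings.warn(
                    f"registration of {s.provenance!r} failed; using identity"
                )
                from .srnf_registration import RegistrationResult, identity_diffeo
                from .srnf_registration import preshape_distance, srnf

                results.append(
                    RegistrationResult(
                        rotation=np.eye(3),
                        diffeo=identity_diffeo(grid),
                        registered_surface=s,
                        distance=preshape_distance(srnf(mu), srnf(s)),
                    )
                )
        registered = [r.registered_surface for r in results]
        variance = float(sum(r.distance**2 for r in results))
        if variance_trace and variance > variance_trace[-1]:
            # registration noise bumped the variance: keep the previous
            # round (mu is already the average of prev_registered)
            registered = prev_registered
            break
        variance_trace.append(variance)
        prev_registered = registered
        mu_new = GridSurface(
            grid,
            np.mean([r.f for r in registered], axis=0),
            "karcher-mean",
        )
        rel_change = norm_l2(mu_new.f - mu.f, grid) / max(norm_l2(mu.f, grid), 1e-300)
        mu = mu_new
        if rel_change < tol:
            break
    return KarcherMean(mu=mu, registered=registered, variance_trace=variance_trace)


def _vec(f: np.ndarray) -> np.ndarray:
    return f.reshape(-1)


def shape_pca(
    mean: KarcherMean, rank_tol: float = 1e-10, area_weighted: bool = False
) -> PCABasis:
    """SVD-based PCA of the registered surfaces about the Karcher mean.

    The thin SVD of the stacked data matrix (one row per ``vec(f_i* -
    mu)``) gives the same directions and eigenvalues as an
    eigendecomposition of the scatter matrix ``C`` without ever forming
    it.  Null directions (singular value below ``rank_tol`` times the
    largest) are dropped; each direction's sign is fixed so its
    largest-magnitude entry is positive.

    ``area_weighted=True`` runs the decomposition in the area-weighted
    L2 inner product (rows scaled by the square root of the quadrature
    weights) instead of the plain Euclidean one; scores and
    reconstructions stay mutually consistent either way.
    """
    if not mean.registered:
        raise ValueError("empty registered set")
    mu_vec = _vec(mean.mu.f)
    node_weights = None
    if area_weighted:
        w = np.sqrt(mean.mu.grid.quad_weights)
        node_weights = _vec(np.repeat(w[..., None], 3, axis=-1))
    data = np.stack([_vec(s.f) - mu_vec for s in mean.registered])
    if node_weights is not None:
        data = data * node_weights
    _, svals, vt = np.linalg.svd(data, full_matrices=False)
    if svals.size == 0 or svals[0] <= 0:
        return PCABasis(
            mu=mean.mu,
            directions=np.empty((mu_vec.size, 0)),
            singular_values=np.empty(0),
            n_train=len(mean.registered),
            node_weights=node_weights,
        )
    keep = svals > rank_tol * svals[0]
    svals = svals[keep]
    directions = vt[keep].T
    for d in range(directions.shape[1]):
        j = np.argmax(np.abs(directions[:, d]))
        if directions[j, d] < 0:
            directions[:, d] = -directions[:, d]
    return PCABasis(
        mu=mean.mu,
        directions=directions,
        singular_values=svals**2,
        n_train=len(mean.registered),
        node_weights=node_weights,
    )


def cumulative_variance(basis: PCABasis) -> np.ndarray:
    """Cumulative proportion of the total singular values, ending at 1."""
    sv = basis.singular_values
    total = sv.sum()
    if sv.size == 0 or total <= 0:
        raise ValueError("no positive singular values")
    return np.cumsum(sv) / total


def principal_scores(
    f: GridSurface,
    basis: PCABasis,
    k: int | None = None,
    register: bool = False,
    config: RegistrationConfig | None = None,
) -> ScoreVector:
    """Scores ``z_d = <vec(f - mu), U(:, d)>`` for d = 1..k.

    The caller is expected to have registered ``f`` to ``basis.mu``;
    ``register=True`` runs the elastic registration first.
    """
    if k is None:
        k = basis.directions.shape[1]
    if not 0 <= k <= basis.directions.shape[1]:
        raise ValueError(f"k={k} out of range (have {basis.directions.shape[1]})")
    if register:
        f = register_pair(basis.mu, f, config=config).registered_surface
    v = _vec(f.f) - _vec(basis.mu.f)
    if basis.node_weights is not None:
        v = v * basis.node_weights
    return ScoreVector(scores=basis.directions[:, :k].T @ v)


def reconstruct(basis: PCABasis, scores: ScoreVector) -> GridSurface:
    """Invert the score map: ``f_hat = mu + sum_d z_d U(:, d)``."""
    k = scores.k
    if k > basis.directions.shape[1]:
        raise ValueError("more scores than available directions")
    v = basis.directions[:, :k] @ scores.scores
    if basis.node_weights is not None:
        v = v / basis.node_weights
    f_hat = basis.mu.f + v.reshape(basis.mu.f.shape)
    return GridSurface(basis.mu.grid, f_hat, "reconstruction")


def deformation_colormap(
    f: GridSurface,
    ref: GridSurface,
    normalize_over: list,
) -> np.ndarray:
    """Patch-wise relative deformation of ``f`` against ``ref`` in [0, 1].

    Each grid node is a patch; its raw value is the area-weighted
    displacement magnitude ``sqrt(w_s) |f(s) - ref(s)|``.  Values are
    normalized by the maximum raw value over every surface in
    ``normalize_over``, so 1 marks the largest patch-wise difference in
    the collection and 0 marks no difference.
    """
    if not normalize_over:
        raise ValueError("normalize_over must contain at least one surface")
    grid = f.grid

    def raw(surface):
        disp = np.linalg.norm(surface.f - ref.f, axis=-1)
        return np.sqrt(grid.quad_weights) * disp

    peak = max(float(raw(s).max()) for s in normalize_over)
    if peak == 0.0:
        return np.zeros(grid.shape)
    return raw(f) / peak
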
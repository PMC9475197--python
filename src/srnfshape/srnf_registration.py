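"""Square-root normal fields and elastic registration of spherical surfaces.

The SRNF of a surface ``f`` is ``q(s) = n(s) / |n(s)|^(1/2)`` with
``n = f_u x f_v``.  Its key property is that the L2 distance between two
SRNFs is unchanged when both surfaces are rotated by the same ``O`` in
SO(3) and reparameterized by the same sphere diffeomorphism ``gamma``
(the SRNF of ``f o gamma`` being ``(q o gamma) sqrt(J_gamma)``).  The
elastic shape distance is then

    d_s([q1], [q2]) = inf_{O, gamma} || q1 - O (q2 o gamma) sqrt(J_gamma) ||

optimized here by a Procrustes solve for ``O`` interleaved with a coarse
search over the 60 rotations of the icosahedral group acting on the
domain, followed by gradient descent over ``gamma`` in a basis of smooth
tangent vector fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sphere_grid import (
    GridSurface,
    SphereGrid,
    _dphi,
    _dtheta,
    grid_nodes_xyz,
    interpolate_field,
    norm_l2,
    surface_area,
    tangent_frame,
)

__all__ = [
    "SRNFField",
    "SphereDiffeo",
    "RegistrationConfig",
    "RegistrationResult",
    "srnf",
    "apply_reparam",
    "apply_reparam_srnf",
    "preshape_distance",
    "optimal_rotation",
    "rotate_field",
    "coarse_domain_search",
    "reparam_gradient_descent",
    "register_pair",
    "icosahedral_rotations",
    "identity_diffeo",
    "diffeo_from_points",
    "rotation_diffeo",
]


@dataclass
class SRNFField:
    """The field ``q = n / |n|^(1/2)`` on a sphere grid."""

    grid: SphereGrid
    q: np.ndarray
    source: str = ""


@dataclass
class SphereDiffeo:
    """A sphere reparameterization stored as target angles per grid node.

    ``gamma_theta``/``gamma_phi`` give ``gamma(s)`` for every node ``s``;
    ``jac_det`` is the area-distortion Jacobian determinant ``J_gamma``,
    positive everywhere for an orientation-preserving map.
    """

    grid: SphereGrid
    gamma_theta: np.ndarray
    gamma_phi: np.ndarray
    jac_det: np.ndarray

    def points_xyz(self) -> np.ndarray:
        st = np.sin(self.gamma_theta)
        return np.stack(
            [
                st * np.cos(self.gamma_phi),
                st * np.sin(self.gamma_phi),
                np.cos(self.gamma_theta),
            ],
            axis=-1,
        )


@dataclass
class RegistrationConfig:
    """Knobs for the elastic registration optimizer."""

    coarse_search: bool = True
    n_starts: int = 3
    basis_degree: int = 3
    max_iter: int = 60
    tol: float = 1e-5
    step0: float = 0.1
    max_halvings: int = 20
    fd_step: float = 1e-4


@dataclass
class RegistrationResult:
    rotation: np.ndarray
    diffeo: SphereDiffeo
    registered_surface: GridSurface
    distance: float
    energy_trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# SRNF transform and group actions


def srnf(surface: GridSurface) -> SRNFField:
    """Compute ``q = n / sqrt(|n|)``; ``||q||^2`` equals the surface area."""
    frame = tangent_frame(surface)
    q = frame.n / np.sqrt(frame.n_mag)[..., None]
    if not np.all(np.isfinite(q)):
        bad = np.argwhere(~np.isfinite(q).all(axis=-1))
        raise ValueError(f"non-finite SRNF at nodes {bad[:5].tolist()}...")
    return SRNFField(grid=surface.grid, q=q, source=surface.provenance)


def identity_diffeo(grid: SphereGrid) -> SphereDiffeo:
    th, ph = np.meshgrid(grid.theta, grid.phi, indexing="ij")
    return SphereDiffeo(grid, th.copy(), ph.copy(), np.ones(grid.shape))


def _angles_from_xyz(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    z = np.clip(pts[..., 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.mod(np.arctan2(pts[..., 1], pts[..., 0]), 2.0 * np.pi)
    return theta, phi


def _jacobian_from_points(pts: np.ndarray, grid: SphereGrid) -> np.ndarray:
    """J_gamma from finite differences of the composed unit-vector map.

    The map gamma sends the area element sin(theta) dtheta dphi to
    |gamma_u x gamma_v| dtheta dphi, so J = |gamma_u x gamma_v| / sin(theta).
    """
    g_u = _dtheta(pts, grid.theta)
    g_v = _dphi(pts, grid.phi)
    num = np.linalg.norm(np.cross(g_u, g_v), axis=-1)
    return num / np.sin(grid.theta)[:, None]


def diffeo_from_points(pts: np.ndarray, grid: SphereGrid) -> SphereDiffeo:
    """Build a SphereDiffeo from a unit-vector image field on the grid."""
    pts = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
    theta, phi = _angles_from_xyz(pts)
    jac = _jacobian_from_points(pts, grid)
    return SphereDiffeo(grid, theta, phi, jac)


def rotation_diffeo(rotation: np.ndarray, grid: SphereGrid) -> SphereDiffeo:
    """Rigid domain rotation ``gamma(s) = R s``; J is identically one."""
    pts = grid_nodes_xyz(grid) @ rotation.T
    theta, phi = _angles_from_xyz(pts)
    return SphereDiffeo(grid, theta, phi, np.ones(grid.shape))


def apply_reparam(surface: GridSurface, diffeo: SphereDiffeo) -> GridSurface:
    """Reparameterized surface ``f o gamma`` by bilinear interpolation."""
    if np.any(diffeo.jac_det <= 0):
        raise ValueError("diffeomorphism has non-positive Jacobian determinant")
    f_new = interpolate_field(
        surface.f, surface.grid, diffeo.gamma_theta, diffeo.gamma_phi
    )
    return GridSurface(surface.grid, f_new, surface.provenance)


def apply_reparam_srnf(q: SRNFField, diffeo: SphereDiffeo) -> SRNFField:
    """SRNF action ``(q o gamma) sqrt(J_gamma)`` (L2-norm preserving)."""
    if np.any(diffeo.jac_det <= 0):
        raise ValueError("diffeomorphism has non-positive Jacobian determinant")
    q_new = interpolate_field(q.q, q.grid, diffeo.gamma_theta, diffeo.gamma_phi)
    q_new = q_new * np.sqrt(diffeo.jac_det)[..., None]
    return SRNFField(grid=q.grid, q=q_new, source=q.source)


def preshape_distance(q1: SRNFField, q2: SRNFField) -> float:
    """L2 distance between two SRNFs on a common grid."""
    if not q1.grid.same_as(q2.grid):
        raise ValueError("SRNF fields live on different grids")
    return norm_l2(q1.q - q2.q, q1.grid)


def rotate_field(h: np.ndarray, rotation: np.ndarray) -> np.ndarray:
    return h @ rotation.T


def optimal_rotation(q1: SRNFField, q2: SRNFField) -> np.ndarray:
    """Procrustes rotation minimizing ``||q1 - O q2||`` over SO(3).

    Solved by SVD of the weighted cross-covariance ``A = sum_s w(s)
    q1(s) q2(s)^T``; the determinant of ``U V^T`` is corrected to +1 so
    the result is always a proper rotation.
    """
    if not q1.grid.same_as(q2.grid):
        raise ValueError("SRNF fields live on different grids")
    w = q1.grid.quad_weights[..., None]
    a = np.einsum("ijk,ijl->kl", q1.q * w, q2.q)
    if np.linalg.matrix_rank(a, tol=1e-12 * max(np.abs(a).max(), 1e-300)) < 2:
        return np.eye(3)
    u, _, vt = np.linalg.svd(a)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


# ---------------------------------------------------------------------------
# icosahedral rotation group (order 60)


def _closure(generators: list[np.ndarray]) -> list[np.ndarray]:
    elems: list[np.ndarray] = [np.eye(3)]

    def key(m: np.ndarray) -> tuple:
        return tuple(np.round(m, 6).ravel())

    seen = {key(np.eye(3))}
    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for m in frontier:
            for g in generators:
                c = g @ m
                k = key(c)
                if k not in seen:
                    seen.add(k)
                    elems.append(c)
                    nxt.append(c)
        frontier = nxt
        if len(elems) > 120:
            raise RuntimeError("group closure exceeded expected order")
    return elems


def icosahedral_rotations() -> list[np.ndarray]:
    """The 60 rotations of the icosahedral (dodecahedral) group.

    Generated by a 5-fold rotation about an icosahedron vertex axis and a
    2-fold rotation about an edge-midpoint axis; the identity is element 0.
    """
    tau = (1.0 + np.sqrt(5.0)) / 2.0
    v1 = np.array([0.0, 1.0, tau])
    v2 = np.array([0.0, -1.0, tau])
    axis5 = v1 / np.linalg.norm(v1)
    mid = 0.5 * (v1 + v2)
    axis2 = mid / np.linalg.norm(mid)

    def rot(axis, angle):
        k = np.array(
            [
                [0, -axis[2], axis[1]],
                [axis[2], 0, -axis[0]],
                [-axis[1], axis[0], 0],
            ]
        )
        return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)

    elems = _closure([rot(axis5, 2 * np.pi / 5), rot(axis2, np.pi)])
    if len(elems) != 60:
        raise RuntimeError(f"icosahedral closure produced {len(elems)} elements")
    # identity first, then a deterministic order for tie-breaking
    elems.sort(key=lambda m: (round(3.0 - np.trace(m), 9), tuple(np.round(m, 6).ravel())))
    return elems


# ---------------------------------------------------------------------------
# registration energy and optimizers


def _registration_energy(
    q1: SRNFField, q2: SRNFField, pts: np.ndarray, jac: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """E = min_O ||q1 - O (q2 o gamma) sqrt(J)||^2 for gamma given by pts."""
    grid = q1.grid
    if jac is None:
        jac = _jacobian_from_points(pts, grid)
        if np.any(jac <= 0):
            return np.inf, np.eye(3)
    theta, phi = _angles_from_xyz(pts)
    qg = interpolate_field(q2.q, grid, theta, phi) * np.sqrt(jac)[..., None]
    o = optimal_rotation(q1, SRNFField(grid, qg))
    diff = q1.q - qg @ o.T
    e = float(np.sum(np.sum(diff * diff, axis=-1) * grid.quad_weights))
    return e, o


def _coarse_candidates(f1: GridSurface, f2: GridSurface) -> list[tuple[float, int, np.ndarray]]:
    """All 60 icosahedral pole placements, sorted by registration energy."""
    q1 = srnf(f1)
    q2 = srnf(f2)
    grid = f1.grid
    nodes = grid_nodes_xyz(grid)
    scored = []
    for idx, r in enumerate(icosahedral_rotations()):
        pts = nodes @ r.T
        e, _ = _registration_energy(q1, q2, pts, jac=np.ones(grid.shape))
        scored.append((e, idx, r))
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored


def coarse_domain_search(
    f1: GridSurface, f2: GridSurface
) -> tuple[SphereDiffeo, float]:
    """Best of 60 icosahedral pole placements for the domain of ``f2``.

    Each group rotation acts as a rigid reparameterization (J = 1); the
    Procrustes rotation is re-solved for each candidate.  Ties are broken
    by the lowest group-element index.
    """
    e, _, r = _coarse_candidates(f1, f2)[0]
    return rotation_diffeo(r, f1.grid), e


def _tangent_basis(degree: int):
    """Smooth tangent vector fields on S^2 used as the descent basis.

    Tangential gradients of the Cartesian monomials of total degree up to
    ``degree`` (their restrictions to the sphere span the spherical
    harmonics of the same degrees) plus the three rotational Killing
    fields.  Each entry is a callable mapping unit points to vectors.
    """
    fields = []
    exps = [
        (a, b, c)
        for d in range(1, degree + 1)
        for a in range(d + 1)
        for b in range(d - a + 1)
        for c in [d - a - b]
    ]

    def grad_field(a, b, c):
        def fn(p):
            x, y, z = p[..., 0], p[..., 1], p[..., 2]
            gx = a * np.power(x, max(a - 1, 0)) * np.power(y, b) * np.power(z, c)
            gy = b * np.power(x, a) * np.power(y, max(b - 1, 0)) * np.power(z, c)
            gz = c * np.power(x, a) * np.power(y, b) * np.power(z, max(c - 1, 0))
            g = np.stack([gx, gy, gz], axis=-1)
            return g - np.sum(g * p, axis=-1, keepdims=True) * p

        return fn

    for a, b, c in exps:
        fields.append(grad_field(a, b, c))

    def killing(axis):
        e = np.zeros(3)
        e[axis] = 1.0

        def fn(p):
            return np.cross(np.broadcast_to(e, p.shape), p)

        return fn

    for axis in range(3):
        fields.append(killing(axis))
    return fields


def reparam_gradient_descent(
    f1: GridSurface,
    f2: GridSurface,
    init: SphereDiffeo | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[SphereDiffeo, list[float]]:
    """Minimize the registration energy over sphere diffeomorphisms.

    The current map is updated by composing with small diffeomorphisms
    ``p -> normalize(p + step * b(p))`` where ``b`` is a descent direction
    in the span of the tangent basis; the coefficient gradient is obtained
    by forward differences of the energy and the step chosen by a
    backtracking line search that also enforces ``J_gamma > 0``.  The
    energy trace is non-increasing by construction.
    """
    cfg = config or RegistrationConfig()
    grid = f1.grid
    q1 = srnf(f1)
    q2 = srnf(f2)
    basis = _tangent_basis(cfg.basis_degree)

    if init is None:
        pts = grid_nodes_xyz(grid)
    else:
        pts = init.points_xyz()
    e_cur, _ = _registration_energy(q1, q2, pts)
    trace = [e_cur]
    scale = max(e_cur, 1e-12)

    for _ in range(cfg.max_iter):
        # forward-difference gradient in basis coefficients
        bvals = [b(pts) for b in basis]
        grads = np.empty(len(basis))
        h = cfg.fd_step
        for m, bv in enumerate(bvals):
            pp = pts + h * bv
            pp = pp / np.linalg.norm(pp, axis=-1, keepdims=True)
            e_m, _ = _registration_energy(q1, q2, pp)
            grads[m] = (e_m - e_cur) / h
        gnorm = np.linalg.norm(grads)
        if gnorm == 0 or not np.isfinite(gnorm):
            break
        direction = sum(-g * bv for g, bv in zip(grads, bvals)) / gnorm

        step = cfg.step0
        accepted = False
        for _ in range(cfg.max_halvings):
            pp = pts + step * direction
            pp = pp / np.linalg.norm(pp, axis=-1, keepdims=True)
            e_new, _ = _registration_energy(q1, q2, pp)
            if e_new < e_cur:
                pts = pp
                e_cur = e_new
                accepted = True
                break
            step *= 0.5
        trace.append(e_cur)
        if not accepted:
            break
        if len(trace) > 1 and (trace[-2] - trace[-1]) < cfg.tol * scale:
            break
    return diffeo_from_points(pts, grid), trace


def register_pair(
    f1: GridSurface,
    f2: GridSurface,
    config: RegistrationConfig | None = None,
) -> RegistrationResult:
    """Full elastic registration of ``f2`` onto ``f1``.

    Pipeline: coarse icosahedral pole search, then gradient descent over
    reparameterizations (started from the ``n_starts`` best pole
    placements, keeping the lowest-energy result) with the Procrustes
    rotation refreshed at every energy evaluation.  Returns the
    registered surface ``f2* = O* (f2 o gamma*)`` and the shape distance
    ``d_s = sqrt(E*)``.  Both inputs should be normalized with
    ``center_and_scale`` first.
    """
    cfg = config or RegistrationConfig()
    q1 = srnf(f1)
    q2 = srnf(f2)
    d_unreg = preshape_distance(q1, q2)
    if d_unreg < 1e-9 * max(norm_l2(q1.q, f1.grid), 1e-300):
        # identical SRNFs: the identity is exactly optimal
        return RegistrationResult(
            rotation=np.eye(3),
            diffeo=identity_diffeo(f1.grid),
            registered_surface=f2.copy(),
            distance=d_unreg,
            energy_trace=[d_unreg**2],
        )

    if cfg.coarse_search:
        inits = [
            rotation_diffeo(r, f1.grid)
            for _, _, r in _coarse_candidates(f1, f2)[: max(cfg.n_starts, 1)]
        ]
    else:
        inits = [None]
    diffeo, trace = None, None
    for init in inits:
        d_try, t_try = reparam_gradient_descent(f1, f2, init=init, config=cfg)
        if trace is None or t_try[-1] < trace[-1]:
            diffeo, trace = d_try, t_try

    pts = diffeo.points_xyz()
    e_final, o = _registration_energy(q1, q2, pts, jac=diffeo.jac_det)
    f2_warp = apply_reparam(f2, diffeo)
    f2_star = GridSurface(f1.grid, f2_warp.f @ o.T, f2.provenance)
    distance = float(np.sqrt(max(e_final, 0.0)))
    # the identity is always in the search set
    distance = min(distance, d_unreg)
    return RegistrationResult(
        rotation=o,
        diffeo=diffeo,
        registered_surface=f2_star,
        distance=distance,
        energy_trace=trace,
    )
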
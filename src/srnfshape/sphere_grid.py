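"""Discrete differential geometry on the unit sphere.

Surfaces are closed genus-zero embeddings ``f : S^2 -> R^3`` sampled on a
regular colatitude/longitude grid.  The grid is staggered in colatitude so
that the poles (where the area element ``sin(theta)`` vanishes) are never
node points: ``theta_j = (j + 1/2) * pi / n_theta``, ``phi_k = 2*pi*k /
n_phi``.  Quadrature uses the product rule with weights ``sin(theta_j) *
d_theta * d_phi``, which converges to the sphere area ``4*pi`` under
refinement.

All angles are radians; colatitude ``theta`` runs over (0, pi) and
longitude ``phi`` over [0, 2*pi) with periodic wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np

__all__ = [
    "SphereGrid",
    "GridSurface",
    "TangentFrame",
    "make_grid",
    "tangent_frame",
    "surface_area",
    "inner_product_l2",
    "norm_l2",
    "center_and_scale",
    "interpolate_field",
    "grid_nodes_xyz",
    "save_surface",
    "load_surface",
]

#: relative threshold below which a normal magnitude counts as degenerate
DEGENERACY_REL_EPS = 1e-12


@dataclass(frozen=True)
class SphereGrid:
    """Regular (theta, phi) sampling of the unit sphere.

    Attributes
    ----------
    theta : (n_theta,) strictly increasing colatitudes in (0, pi).
    phi : (n_phi,) strictly increasing longitudes in [0, 2*pi).
    quad_weights : (n_theta, n_phi) per-node quadrature weights.
    """

    theta: np.ndarray
    phi: np.ndarray
    quad_weights: np.ndarray = field(repr=False)

    @property
    def n_theta(self) -> int:
        return self.theta.size

    @property
    def n_phi(self) -> int:
        return self.phi.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_theta, self.n_phi)

    def same_as(self, other: "SphereGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.theta, other.theta)
            and np.allclose(self.phi, other.phi)
        )


@dataclass
class GridSurface:
    """A closed surface ``f : S^2 -> R^3`` on a :class:`SphereGrid`.

    ``f`` has shape ``(n_theta, n_phi, 3)``.
    """

    grid: SphereGrid
    f: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (*self.grid.shape, 3):
            raise ValueError(
                f"f has shape {self.f.shape}, expected {(*self.grid.shape, 3)}"
            )
        if not np.all(np.isfinite(self.f)):
            raise ValueError("surface contains non-finite values")

    def copy(self, provenance: str | None = None) -> "GridSurface":
        return GridSurface(
            self.grid,
            self.f.copy(),
            self.provenance if provenance is None else provenance,
        )


@dataclass
class TangentFrame:
    """Partial derivatives and normal field of a surface.

    ``n = f_u x f_v`` is the unnormalized outward normal, ``n_mag = |n|``
    its magnitude (the local area element).  ``degenerate`` flags nodes
    whose normal collapsed below the degeneracy threshold; at those nodes
    ``n_mag`` is clamped so downstream divisions stay finite.
    """

    f_u: np.ndarray
    f_v: np.ndarray
    n: np.ndarray
    n_mag: np.ndarray
    degenerate: np.ndarray


def make_grid(n_theta: int, n_phi: int) -> SphereGrid:
    """Build the staggered spherical grid with product quadrature weights."""
    if n_theta < 3 or n_phi < 3:
        raise ValueError("grid requires n_theta >= 3 and n_phi >= 3")
    d_theta = np.pi / n_theta
    d_phi = 2.0 * np.pi / n_phi
    theta = (np.arange(n_theta) + 0.5) * d_theta
    phi = np.arange(n_phi) * d_phi
    w = np.sin(theta)[:, None] * np.full((1, n_phi), d_theta * d_phi)
    return SphereGrid(theta=theta, phi=phi, quad_weights=w)


def grid_nodes_xyz(grid: SphereGrid) -> np.ndarray:
    """Unit direction of every grid node, shape (n_theta, n_phi, 3)."""
    th = grid.theta[:, None]
    ph = grid.phi[None, :]
    st = np.sin(th)
    return np.stack(
        np.broadcast_arrays(st * np.cos(ph), st * np.sin(ph), np.cos(th) + 0.0 * ph),
        axis=-1,
    )


def _dtheta(values: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Colatitude derivative: central interior, 2nd-order one-sided at rows 0/-1."""
    h = theta[1] - theta[0]
    out = np.empty_like(values)
    out[1:-1] = (values[2:] - values[:-2]) / (2.0 * h)
    out[0] = (-3.0 * values[0] + 4.0 * values[1] - values[2]) / (2.0 * h)
    out[-1] = (3.0 * values[-1] - 4.0 * values[-2] + values[-3]) / (2.0 * h)
    return out


def _dphi(values: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Longitude derivative: central differences with periodic wrap."""
    h = phi[1] - phi[0]
    return (np.roll(values, -1, axis=1) - np.roll(values, 1, axis=1)) / (2.0 * h)


def tangent_frame(surface: GridSurface) -> TangentFrame:
    """Finite-difference tangent vectors and the normal field ``n = f_u x f_v``.

    The longitude derivative is taken per unit arc length of the
    parameter sphere (``f_v = (1/sin theta) df/dphi``), so that
    ``|n| dA`` with the round area measure ``dA = sin theta dtheta dphi``
    is the surface area element.  On the unit sphere ``n(s) = f(s)``.
    """
    f = surface.f
    f_u = _dtheta(f, surface.grid.theta)
    f_v = _dphi(f, surface.grid.phi) / np.sin(surface.grid.theta)[:, None, None]
    n = np.cross(f_u, f_v)
    n_mag = np.linalg.norm(n, axis=-1)
    eps = DEGENERACY_REL_EPS * max(float(n_mag.mean()), np.finfo(float).tiny)
    degenerate = n_mag < eps
    n_mag = np.maximum(n_mag, eps)
    return TangentFrame(f_u=f_u, f_v=f_v, n=n, n_mag=n_mag, degenerate=degenerate)


def surface_area(surface: GridSurface) -> float:
    """Total area ``alpha_f = integral |n(s)| ds`` by quadrature."""
    frame = tangent_frame(surface)
    area = float(np.sum(frame.n_mag * surface.grid.quad_weights))
    if not np.isfinite(area) or area <= 0.0:
        raise ValueError(f"non-positive or non-finite surface area: {area}")
    return area


def inner_product_l2(h1: np.ndarray, h2: np.ndarray, grid: SphereGrid) -> float:
    """L2 inner product of two R^3-valued fields over the grid."""
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if h1.shape != (*grid.shape, 3) or h2.shape != (*grid.shape, 3):
        raise ValueError("field shape does not match the grid")
    return float(np.sum(np.sum(h1 * h2, axis=-1) * grid.quad_weights))


def norm_l2(h: np.ndarray, grid: SphereGrid) -> float:
    return float(np.sqrt(max(inner_product_l2(h, h, grid), 0.0)))


def center_and_scale(surface: GridSurface) -> GridSurface:
    """Remove translation and global scale: centroid to 0, area to 1.

    The centroid is area-weighted (weights ``|n| w``), so the operation
    commutes with rigid motions.  Scaling divides coordinates by the square
    root of the area, which makes the area of the result exactly one up to
    quadrature tolerance; it is idempotent.
    """
    frame = tangent_frame(surface)
    w = frame.n_mag * surface.grid.quad_weights
    area = float(w.sum())
    if area <= 0.0:
        raise ValueError("degenerate surface: zero area")
    centroid = (surface.f * w[..., None]).sum(axis=(0, 1)) / area
    f_new = (surface.f - centroid) / np.sqrt(area)
    return GridSurface(surface.grid, f_new, surface.provenance)


# ---------------------------------------------------------------------------
# interpolation


def interpolate_field(
    values: np.ndarray,
    grid: SphereGrid,
    theta_q: np.ndarray,
    phi_q: np.ndarray,
) -> np.ndarray:
    """Cubic-spline interpolation of a grid field at arbitrary sphere points.

    Periodic in phi.  Across the poles the staggered grid is extended
    exactly: a scalar field on the sphere satisfies ``F(-theta, phi) =
    F(theta, phi + pi)``, so (for even ``n_phi``) the ghost rows above
    and below the poles are the mirrored rows rolled by half a period.
    For odd ``n_phi`` the ghost rows fall back to the phi-mean of the
    nearest row (first-order accurate at the poles only).
    """
    from scipy.ndimage import map_coordinates

    values = np.asarray(values, dtype=float)
    ncomp = values.shape[-1] if values.ndim == 3 else 1
    vals = values.reshape(*grid.shape, ncomp)
    n_theta, n_phi = grid.shape
    d_theta = np.pi / n_theta
    d_phi = 2.0 * np.pi / n_phi
    pad = 3

    # phi: periodic wrap padding
    vp = np.concatenate([vals[:, -pad:], vals, vals[:, :pad]], axis=1)
    # theta: cross-pole ghost rows
    if n_phi % 2 == 0:
        roll = n_phi // 2
        top = np.roll(vals[:pad][::-1], roll, axis=1)
        bot = np.roll(vals[-pad:][::-1], roll, axis=1)
        top = np.concatenate([top[:, -pad:], top, top[:, :pad]], axis=1)
        bot = np.concatenate([bot[:, -pad:], bot, bot[:, :pad]], axis=1)
    else:
        top = np.repeat(vp[:1].mean(axis=1, keepdims=True), vp.shape[1], axis=1)
        top = np.repeat(top, pad, axis=0)
        bot = np.repeat(vp[-1:].mean(axis=1, keepdims=True), vp.shape[1], axis=1)
        bot = np.repeat(bot, pad, axis=0)
    vp = np.concatenate([top, vp, bot], axis=0)

    tq = np.clip(np.asarray(theta_q, dtype=float), 0.0, np.pi)
    pq = np.mod(np.asarray(phi_q, dtype=float), 2.0 * np.pi)
    # fractional indices into the padded array
    ti = tq / d_theta - 0.5 + pad
    pi_ = pq / d_phi + pad
    coords = np.stack([ti.ravel(), pi_.ravel()])

    out = np.empty((tq.size, ncomp))
    for c in range(ncomp):
        out[:, c] = map_coordinates(
            vp[..., c], coords, order=3, mode="nearest", prefilter=True
        )
    out = out.reshape(*np.shape(tq), ncomp)
    if values.ndim == 2:
        return out[..., 0]
    return out


# ---------------------------------------------------------------------------
# HDF5 container
#
# Layout: datasets /f (3 x n_theta x n_phi, float64), /theta (n_theta,),
# /phi (n_phi,); root attribute "provenance" (UTF-8 string).


def save_surface(surface: GridSurface, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("f", data=np.moveaxis(surface.f, -1, 0))
        h5.create_dataset("theta", data=surface.grid.theta)
        h5.create_dataset("phi", data=surface.grid.phi)
        h5.attrs["provenance"] = surface.provenance


def load_surface(path) -> GridSurface:
    with h5py.File(path, "r") as h5:
        f = np.moveaxis(h5["f"][()], 0, -1)
        theta = h5["theta"][()]
        phi = h5["phi"][()]
        provenance = str(h5.attrs.get("provenance", ""))
    grid = make_grid(theta.size, phi.size)
    if not (np.allclose(grid.theta, theta) and np.allclose(grid.phi, phi)):
        # non-canonical grid: rebuild weights from the stored coordinates
        d_theta = float(np.diff(theta).mean())
        d_phi = float(np.diff(phi).mean())
        w = np.sin(theta)[:, None] * np.full((1, phi.size), d_theta * d_phi)
        grid = SphereGrid(theta=theta, phi=phi, quad_weights=w)
    return GridSurface(grid, f, provenance)
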
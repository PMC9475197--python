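"""Synthetic surfaces, sphere diffeomorphisms, and clinical covariates.

The shape generators emulate populations of smooth genus-zero subcortical
structures: an analytic base shape (ellipsoid, optionally bent into a
banana-like tube) perturbed along a small number of smooth, mutually
orthogonal deformation modes, with optional nodewise noise.  Because the
bases are analytic, areas and collinearity relations have closed forms
that serve as oracles in tests.

The clinical generator plants a known linear model: outcomes (a PTSD
symptom scale, range 0-42, and a childhood-trauma total, range 25-125)
are linear in principal scores, age, and depression index (BDI), with
optional score-by-age and score-by-BDI interaction terms, plus Gaussian
noise, clipped to the instrument ranges afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sphere_grid import (
    GridSurface,
    SphereGrid,
    center_and_scale,
    grid_nodes_xyz,
    make_grid,
)
from .srnf_registration import (
    SphereDiffeo,
    _tangent_basis,
    diffeo_from_points,
    icosahedral_rotations,
)

__all__ = [
    "SurfaceFamilySpec",
    "SimulatedLine",
    "base_surface",
    "make_mode_fields",
    "generate_family",
    "simulate_pc_line",
    "random_diffeomorphism",
    "simulate_clinical",
]

# instrument ranges: age in years, BDI, PSS, CTQTOT per the questionnaires
AGE_RANGE = (18.0, 61.0)
BDI_RANGE = (0.0, 63.0)
PSS_RANGE = (0.0, 42.0)
CTQTOT_RANGE = (25.0, 125.0)


@dataclass
class SurfaceFamilySpec:
    """Recipe for a synthetic surface population.

    ``mode_sds`` are the standard deviations of the per-mode coefficients
    (one smooth deformation mode each); ``noise_sd`` is nodewise isotropic
    Gaussian noise added on top.
    """

    base: str = "ellipsoid"
    base_params: dict = field(default_factory=dict)
    n: int = 20
    n_modes: int = 3
    mode_sds: tuple = (0.03, 0.02, 0.01)
    noise_sd: float = 0.0
    seed: int = 0
    grid: SphereGrid | None = None


@dataclass
class SimulatedLine:
    """Forty surfaces on a line through the mean along one principal mode."""

    surfaces: list
    x: np.ndarray
    labels: np.ndarray
    mu: GridSurface
    v1: np.ndarray


def base_surface(
    grid: SphereGrid,
    kind: str = "ellipsoid",
    axes: tuple = (1.0, 0.7, 0.5),
    bend: float = 0.0,
    provenance: str = "synthetic-base",
) -> GridSurface:
    """Analytic base shape: an ellipsoid, optionally bent in the x-z plane.

    ``bend`` tilts the z-offset quadratically in x, turning the ellipsoid
    into a banana-like tube reminiscent of a hippocampus.
    """
    if kind not in ("ellipsoid", "bent-tube"):
        raise ValueError(f"unknown base shape {kind!r}")
    a, b, c = axes
    nodes = grid_nodes_xyz(grid)
    f = nodes * np.array([a, b, c])
    if kind == "bent-tube" or bend != 0.0:
        amount = bend if bend != 0.0 else 0.6
        f = f.copy()
        f[..., 2] = f[..., 2] + amount * (f[..., 0] / a) ** 2
    return GridSurface(grid, f, provenance)


def make_mode_fields(
    grid: SphereGrid,
    n_modes: int,
    seed: int = 0,
    base: GridSurface | None = None,
) -> np.ndarray:
    """Smooth, mutually orthogonal deformation modes on the grid.

    Each mode is a random smooth scalar field (a combination of low-order
    polynomial bumps) times the unit normal of ``base`` (the round sphere
    when no base is given), orthonormalized in the Euclidean sense on
    vectorized fields.  Normal-direction modes change shape in a way that
    reparameterization cannot absorb, mimicking principal directions
    recovered from registered surface populations.  When a base is given
    the modes are additionally made area- and centroid-neutral to first
    order, so the per-sample unit-area normalization does not fold a
    score-correlated scaling or translation component into the family.
    Shape: (n_modes, n_theta, n_phi, 3).
    """
    from .sphere_grid import surface_area, tangent_frame

    rng = np.random.default_rng(seed)
    nodes = grid_nodes_xyz(grid)
    if base is None:
        normals = nodes
    else:
        frame = tangent_frame(base)
        normals = frame.n / frame.n_mag[..., None]
    x, y, z = nodes[..., 0], nodes[..., 1], nodes[..., 2]
    scalars = [x, y, z, x * y, y * z, x * z, x * x - y * y, 3 * z * z - 1]
    raw = []
    for _ in range(n_modes):
        coeffs = rng.normal(size=len(scalars))
        fld = np.zeros(grid.shape)
        for s, cf in zip(scalars, coeffs):
            fld += cf * s
        raw.append((fld[..., None] * normals).reshape(-1))

    if base is not None:
        h = 1e-5

        def d_area(direction):
            fp = GridSurface(grid, base.f + h * direction.reshape(base.f.shape))
            fm = GridSurface(grid, base.f - h * direction.reshape(base.f.shape))
            return (surface_area(fp) - surface_area(fm)) / (2.0 * h)

        def centroid(f):
            fr = tangent_frame(GridSurface(grid, f))
            w = (fr.n_mag * grid.quad_weights)[..., None]
            return (f * w).sum(axis=(0, 1)) / w.sum()

        def d_centroid(direction):
            d = direction.reshape(base.f.shape)
            return (centroid(base.f + h * d) - centroid(base.f - h * d)) / (2.0 * h)

        radial = base.f.reshape(-1)
        d_area_radial = d_area(radial)  # = 2 * area by homogeneity
        ones = np.ones(grid.shape)
        neutral = []
        for v in raw:
            v = v - (d_area(v) / d_area_radial) * radial
            # translations move the centroid one-for-one, so subtracting the
            # centroid derivative as constant fields kills the first-order
            # shift without touching the area
            dc = d_centroid(v)
            vf = v.reshape(base.f.shape) - dc[None, None, :] * ones[..., None]
            neutral.append(vf.reshape(-1))
        raw = neutral
    # Gram-Schmidt, then unit Euclidean norm
    basis = []
    for v in raw:
        for u in basis:
            v = v - (v @ u) * u
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            raise RuntimeError("mode fields degenerate; change the seed")
        basis.append(v / nv)
    return np.stack(basis).reshape(n_modes, *grid.shape, 3)


def generate_family(spec: SurfaceFamilySpec) -> tuple[list, np.ndarray, np.ndarray]:
    """Sample a surface population with planted deformation modes.

    Returns ``(surfaces, planted_scores, modes)`` where ``planted_scores``
    has shape (n, n_modes).  Each surface is ``normalize(base + sum_m
    z_m mode_m + noise)``; the same seed reproduces the family bitwise.
    """
    grid = spec.grid if spec.grid is not None else make_grid(32, 32)
    if len(spec.mode_sds) < spec.n_modes:
        raise ValueError("mode_sds shorter than n_modes")
    rng = np.random.default_rng(spec.seed)
    base = base_surface(grid, kind=spec.base, **spec.base_params)
    base = center_and_scale(base)
    modes = make_mode_fields(grid, spec.n_modes, seed=spec.seed + 1, base=base)
    sds = np.asarray(spec.mode_sds[: spec.n_modes])
    scores = rng.normal(size=(spec.n, spec.n_modes)) * sds
    surfaces = []
    for i in range(spec.n):
        f = base.f + np.tensordot(scores[i], modes, axes=1)
        if spec.noise_sd > 0:
            f = f + rng.normal(scale=spec.noise_sd, size=f.shape)
        s = GridSurface(grid, f, f"synthetic-{spec.base}-{i:03d}")
        surfaces.append(center_and_scale(s))
    return surfaces, scores, modes


def simulate_pc_line(
    mu: GridSurface, v1: np.ndarray, seed: int = 0
) -> SimulatedLine:
    """Forty surfaces ``f_i = mu + x_i v1`` straddling the mean.

    ``x_i`` is uniform in (0, 1] for the first twenty surfaces and in
    [-1, 0) for the last twenty, mirroring a two-class design along the
    first principal direction.  ``v1`` must have unit Euclidean norm.
    """
    v1 = np.asarray(v1, dtype=float)
    if abs(np.linalg.norm(v1) - 1.0) > 1e-8:
        raise ValueError("v1 must have unit norm")
    rng = np.random.default_rng(seed)
    x_pos = 1.0 - rng.uniform(0.0, 1.0, size=20)  # in (0, 1]
    x_neg = -(1.0 - rng.uniform(0.0, 1.0, size=20))  # in [-1, 0)
    x = np.concatenate([x_pos, x_neg])
    labels = np.concatenate([np.zeros(20, dtype=int), np.ones(20, dtype=int)])
    vfield = v1.reshape(mu.f.shape)
    surfaces = [
        GridSurface(mu.grid, mu.f + xi * vfield, f"line-{i:02d}")
        for i, xi in enumerate(x)
    ]
    return SimulatedLine(surfaces=surfaces, x=x, labels=labels, mu=mu, v1=v1)


def random_diffeomorphism(
    grid: SphereGrid,
    amplitude: float,
    seed: int = 0,
    n_steps: int = 10,
    include_rotation: bool = True,
    degree: int = 3,
) -> SphereDiffeo:
    """Random orientation-preserving sphere diffeomorphism.

    Composes an optional random icosahedral rotation with the flow of a
    random tangent vector field (random coefficients over the smooth
    tangent basis), integrated in ``n_steps`` small normalized Euler
    steps of total size ``amplitude``.  If the resulting Jacobian is not
    positive everywhere, the amplitude is halved until it is.
    """
    rng = np.random.default_rng(seed)
    basis = _tangent_basis(degree)
    coeffs = rng.normal(size=len(basis))
    coeffs /= np.linalg.norm(coeffs)

    pts0 = grid_nodes_xyz(grid)
    if include_rotation:
        rots = icosahedral_rotations()
        r = rots[rng.integers(len(rots))]
        pts0 = pts0 @ r.T

    amp = float(amplitude)
    while True:
        pts = pts0.copy()
        if amp > 0:
            dt = amp / n_steps
            for _ in range(n_steps):
                v = sum(c * b(pts) for c, b in zip(coeffs, basis))
                pts = pts + dt * v
                pts = pts / np.linalg.norm(pts, axis=-1, keepdims=True)
        diffeo = diffeo_from_points(pts, grid)
        if np.all(diffeo.jac_det > 0):
            return diffeo
        amp *= 0.5
        if amp < 1e-8:
            return diffeo_from_points(pts0, grid)


def simulate_clinical(
    scores: dict,
    coefficients: dict,
    noise_sd: float = 3.0,
    seed: int = 0,
    icv_mean: float = 1.4e6,
    icv_sd: float = 1.2e5,
) -> tuple[pd.DataFrame, dict]:
    """Clinical covariate table with a planted linear outcome model.

    Parameters
    ----------
    scores : mapping of structure name to (n, k) principal-score arrays.
    coefficients : mapping of outcome name ("PSS" or "CTQTOT") to a term
        dict.  Term keys: "intercept", "age", "BDI", main effects like
        ("PS", structure, d), and interactions like ("PSxage", structure,
        d) or ("PSxBDI", structure, d); d is the 1-based score index.
    noise_sd : standard deviation of additive Gaussian outcome noise.

    Age is uniform on 18-61 years; BDI is drawn from a right-skewed Beta
    scaled to 0-63; ICV is Gaussian in mm^3.  Outcomes are clipped to the
    instrument ranges after noise (clipping mildly biases boundary
    coefficients; keep planted outcomes interior to avoid it).

    Returns the table and a record of the planted coefficients.
    """
    structures = sorted(scores)
    n = next(iter(scores.values())).shape[0]
    for name, arr in scores.items():
        if arr.shape[0] != n:
            raise ValueError("score arrays disagree on subject count")
    rng = np.random.default_rng(seed)
    age = rng.uniform(*AGE_RANGE, size=n)
    bdi = rng.beta(1.5, 4.0, size=n) * BDI_RANGE[1]
    icv = rng.normal(icv_mean, icv_sd, size=n)

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": age,
            "BDI": bdi,
            "ICV": icv,
        }
    )
    for name in structures:
        arr = scores[name]
        for d in range(arr.shape[1]):
            table[f"{name}_PS{d + 1}"] = arr[:, d]

    def column(term):
        if term == "intercept":
            return np.ones(n)
        if term == "age":
            return age
        if term == "BDI":
            return bdi
        kind, struct, d = term
        if struct not in scores or d > scores[struct].shape[1]:
            raise KeyError(f"term {term} references a missing score")
        ps = scores[struct][:, d - 1]
        if kind == "PS":
            return ps
        if kind == "PSxage":
            return ps * age
        if kind == "PSxBDI":
            return ps * bdi
        raise KeyError(f"unknown term kind {kind!r}")

    ranges = {"PSS": PSS_RANGE, "CTQTOT": CTQTOT_RANGE}
    for outcome, terms in coefficients.items():
        lin = np.zeros(n)
        for term, beta in terms.items():
            lin = lin + beta * column(term)
        if noise_sd > 0:
            lin = lin + rng.normal(scale=noise_sd, size=n)
        lo, hi = ranges[outcome]
        table[outcome] = np.clip(lin, lo, hi)
    return table, dict(coefficients)
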
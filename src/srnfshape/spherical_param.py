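"""Spherical parameterization of genus-zero triangle meshes.

Segmentation tools emit subcortical structures as closed triangle
meshes.  To analyze them as maps ``f : S^2 -> R^3`` the mesh is first
embedded on the unit sphere, in two stages: a Tuette-energy minimization
(uniform edge weights), whose minimizer is unique up to rotation and
provides a bijective initialization, followed by harmonic-energy
relaxation with cotangent weights and center-of-mass normalization to
prevent the well-known collapse of spherical harmonic maps.  The mesh is
then resampled on a regular (theta, phi) grid by barycentric
interpolation inside the spherical triangle containing each grid
direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .sphere_grid import GridSurface, SphereGrid, grid_nodes_xyz

__all__ = [
    "TriMesh",
    "SphericalMap",
    "read_mesh",
    "mesh_from_arrays",
    "tuette_map",
    "conformal_relax",
    "resample_to_grid",
    "mesh_area",
]


@dataclass
class TriMesh:
    vertices: np.ndarray
    faces: np.ndarray
    format_tag: str = ""

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def edges(self) -> np.ndarray:
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)


@dataclass
class SphericalMap:
    sphere_vertices: np.ndarray
    energy_trace: list = field(default_factory=list)
    flipped_triangles: int = 0


def subdivide(mesh: TriMesh, levels: int = 1) -> TriMesh:
    """1-to-4 midpoint subdivision (each level quadruples the faces)."""
    v = mesh.vertices
    f = mesh.faces
    for _ in range(levels):
        edge_mid: dict[tuple[int, int], int] = {}
        verts = list(v)

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in edge_mid:
                edge_mid[key] = len(verts)
                verts.append(0.5 * (v[a] + v[b]))
            return edge_mid[key]

        new_faces = []
        for a, b, c in f:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)])
        v = np.array(verts)
        f = np.array(new_faces, dtype=int)
    return TriMesh(v, f, mesh.format_tag)


def mesh_area(mesh: TriMesh) -> float:
    """Total triangle area of the mesh (the brute-force area oracle)."""
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())


# ---------------------------------------------------------------------------
# reading and validation


def _parse_vtk_legacy(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Minimal ASCII VTK legacy polydata reader (POINTS + POLYGONS)."""
    tokens = path.read_text().split()
    up = [t.upper() for t in tokens]
    if "POINTS" not in up:
        raise ValueError("VTK file has no POINTS section")
    i = up.index("POINTS")
    n_pts = int(tokens[i + 1])
    coords = np.array(tokens[i + 3 : i + 3 + 3 * n_pts], dtype=float)
    vertices = coords.reshape(n_pts, 3)
    if "POLYGONS" in up:
        j = up.index("POLYGONS")
    elif "CELLS" in up:
        j = up.index("CELLS")
    else:
        raise ValueError("VTK file has no POLYGONS section")
    n_cells = int(tokens[j + 1])
    faces = []
    k = j + 3
    for _ in range(n_cells):
        cnt = int(tokens[k])
        if cnt != 3:
            raise ValueError("VTK polydata contains non-triangular cells")
        faces.append([int(tokens[k + 1]), int(tokens[k + 2]), int(tokens[k + 3])])
        k += cnt + 1
    return vertices, np.array(faces, dtype=int)


def mesh_from_arrays(
    vertices: np.ndarray, faces: np.ndarray, format_tag: str = "arrays"
) -> TriMesh:
    """Validate and orient a triangle soup as a closed genus-zero mesh."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=int)
    mesh = TriMesh(vertices, faces, format_tag)

    e_all = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e_sorted = np.sort(e_all, axis=1)
    uniq, counts = np.unique(e_sorted, axis=0, return_counts=True)
    if np.any(counts != 2):
        n_bad = int(np.sum(counts != 2))
        kind = "open surface" if np.any(counts == 1) else "non-manifold"
        raise ValueError(
            f"{kind}: {n_bad} edges not shared by exactly 2 faces"
        )
    # orientability: each undirected edge must appear once in each direction
    directed = {}
    for tri in faces:
        for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
            directed[(a, b)] = directed.get((a, b), 0) + 1
    for (a, b), cnt in directed.items():
        if cnt != 1 or directed.get((b, a), 0) != 1:
            raise ValueError("non-orientable or inconsistently oriented mesh")
    v, e, f = len(vertices), len(uniq), len(faces)
    chi = v - e + f
    if chi != 2:
        raise ValueError(f"genus != 0: Euler characteristic V-E+F = {chi}")

    # outward orientation by signed volume
    a, b, c = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0
    if vol < 0:
        mesh = TriMesh(vertices, faces[:, [0, 2, 1]], format_tag)
    return mesh


def read_mesh(path) -> TriMesh:
    """Read a closed triangle mesh from VTK legacy, OFF, or PLY."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".vtk":
        vertices, faces = _parse_vtk_legacy(path)
        tag = "vtk-legacy"
    elif suffix in (".off", ".ply"):
        import trimesh as _trimesh

        tm = _trimesh.load(str(path), process=False, force="mesh")
        vertices, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
        tag = suffix.lstrip(".")
    else:
        raise ValueError(f"unsupported mesh format: {suffix!r}")
    return mesh_from_arrays(vertices, faces, tag)


# ---------------------------------------------------------------------------
# spherical embeddings


def _adjacency(mesh: TriMesh):
    from scipy.sparse import coo_matrix

    e = mesh.edges()
    n = mesh.n_vertices
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    vals = np.ones(rows.size)
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _cotangent_weights(mesh: TriMesh):
    """Symmetric cotangent edge-weight matrix; negatives clamped to 0."""
    from scipy.sparse import coo_matrix

    v = mesh.vertices
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for k in range(3):
        i = mesh.faces[:, k]
        j = mesh.faces[:, (k + 1) % 3]
        o = mesh.faces[:, (k + 2) % 3]
        u = v[i] - v[o]
        w = v[j] - v[o]
        cos = np.einsum("ij,ij->i", u, w)
        sin = np.linalg.norm(np.cross(u, w), axis=1)
        cot = 0.5 * cos / np.maximum(sin, 1e-12)
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([cot, cot])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.maximum(np.concatenate(vals), 0.0)
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _count_flipped(sphere_vertices: np.ndarray, faces: np.ndarray) -> int:
    a = sphere_vertices[faces[:, 0]]
    b = sphere_vertices[faces[:, 1]]
    c = sphere_vertices[faces[:, 2]]
    centroid = (a + b + c) / 3.0
    orient = np.einsum("ij,ij->i", np.cross(b - a, c - a), centroid)
    return int(np.sum(orient <= 0))


def _weighted_descent(
    u0: np.ndarray,
    weights,
    faces: np.ndarray,
    max_iter: int,
    step: float,
    center: bool,
) -> SphericalMap:
    """Projected gradient descent on sum_ij w_ij ||u_i - u_j||^2.

    The gradient is projected onto sphere tangent planes, the step chosen
    by backtracking, and each accepted iterate renormalized to the
    sphere; the recorded energy trace is non-increasing.
    """
    deg = np.asarray(weights.sum(axis=1)).ravel()

    def energy(u):
        # sum_ij w_ij ||u_i-u_j||^2 = 2 (sum_i deg_i |u_i|^2 - sum_i u_i . (W u)_i)
        wu = weights @ u
        return float(2.0 * (np.sum(deg * np.einsum("ij,ij->i", u, u)) - np.sum(u * wu)))

    u = u0.copy()
    e_cur = energy(u)
    trace = [e_cur]
    dt = step
    for _ in range(max_iter):
        if center:
            centroid = u.mean(axis=0)
            if np.linalg.norm(centroid) > 0.99:
                raise RuntimeError("spherical map collapsed (centroid norm > 0.99)")
            if np.linalg.norm(centroid) > 0.01:
                u = u - centroid
                u = u / np.linalg.norm(u, axis=1, keepdims=True)
                # recorded trace stays monotone: the line search below must
                # still beat the last recorded energy to be accepted
                e_cur = min(e_cur, energy(u))
        grad = 4.0 * (deg[:, None] * u - weights @ u)
        grad = grad - np.einsum("ij,ij->i", grad, u)[:, None] * u
        gn = np.linalg.norm(grad)
        if gn < 1e-14:
            break
        accepted = False
        s = dt
        for _ in range(25):
            u_new = u - s * grad / max(gn, 1e-300)
            u_new = u_new / np.linalg.norm(u_new, axis=1, keepdims=True)
            e_new = energy(u_new)
            if e_new < e_cur:
                u = u_new
                e_cur = e_new
                accepted = True
                break
            s *= 0.5
        if not accepted:
            break
        trace.append(e_cur)
        if len(trace) > 2 and (trace[-2] - trace[-1]) < 1e-10 * max(trace[0], 1e-300):
            break
    return SphericalMap(
        sphere_vertices=u,
        energy_trace=trace,
        flipped_triangles=_count_flipped(u, faces),
    )


def tuette_map(mesh: TriMesh, max_iter: int = 500, step: float = 0.05) -> SphericalMap:
    """Tuette embedding: minimize uniform-weight edge energy on the sphere."""
    u0 = mesh.vertices - mesh.vertices.mean(axis=0)
    u0 = u0 / np.linalg.norm(u0, axis=1, keepdims=True)
    return _weighted_descent(
        u0, _adjacency(mesh), mesh.faces, max_iter, step, center=False
    )


def conformal_relax(
    mesh: TriMesh, init: SphericalMap, max_iter: int = 500, step: float = 0.05
) -> SphericalMap:
    """Harmonic relaxation with cotangent weights and Mobius centering."""
    return _weighted_descent(
        init.sphere_vertices.copy(),
        _cotangent_weights(mesh),
        mesh.faces,
        max_iter,
        step,
        center=True,
    )


# ---------------------------------------------------------------------------
# resampling


def resample_to_grid(
    mesh: TriMesh, smap: SphericalMap, grid: SphereGrid, provenance: str = ""
) -> GridSurface:
    """Evaluate the parameterized surface on a regular spherical grid.

    For each grid direction the containing spherical triangle is located
    (nearest face centroids first, brute force as fallback) and mesh
    vertex positions are interpolated with the barycentric coordinates of
    the gnomonic projection onto the triangle plane.
    """
    u = smap.sphere_vertices
    faces = mesh.faces
    dirs = grid_nodes_xyz(grid).reshape(-1, 3)

    a, b, c = u[faces[:, 0]], u[faces[:, 1]], u[faces[:, 2]]
    centroids = (a + b + c) / 3.0
    centroids /= np.linalg.norm(centroids, axis=1, keepdims=True)
    tree = cKDTree(centroids)
    k = min(32, len(faces))
    _, cand = tree.query(dirs, k=k)
    if k == 1:
        cand = cand[:, None]

    f_out = np.empty((dirs.shape[0], 3))
    basis = np.stack([a, b, c], axis=2)  # (F, 3, 3): columns are vertices
    for idx, p in enumerate(dirs):
        found = False
        for fi in cand[idx]:
            m = basis[fi]
            try:
                lam = np.linalg.solve(m, p)
            except np.linalg.LinAlgError:
                continue
            ssum = lam.sum()
            if ssum <= 0:
                continue
            lam = lam / ssum
            if np.all(lam >= -1e-9):
                tri = faces[fi]
                f_out[idx] = lam @ mesh.vertices[tri]
                found = True
                break
        if not found:
            # brute force over all faces
            for fi in range(len(faces)):
                m = basis[fi]
                det = np.linalg.det(m)
                if abs(det) < 1e-15:
                    continue
                lam = np.linalg.solve(m, p)
                ssum = lam.sum()
                if ssum <= 0:
                    continue
                lam = lam / ssum
                if np.all(lam >= -1e-9):
                    tri = faces[fi]
                    f_out[idx] = lam @ mesh.vertices[tri]
                    found = True
                    break
        if not found:
            raise RuntimeError(
                "grid direction not covered by any spherical triangle "
                "(flipped or degenerate map)"
            )
    return GridSurface(grid, f_out.reshape(*grid.shape, 3), provenance)
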
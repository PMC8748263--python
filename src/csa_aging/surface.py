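"""Left-right symmetric triangular surface meshes and their queries.

The analyses here run on a cortical surface sampled as a triangular mesh with
one-to-one vertex correspondence between hemispheres (the convention of
symmetric surface templates such as Conte69_LR32k, ~2 mm inter-vertex
spacing).  For desk-scale simulation we stand in a regular hexagonal lattice
duplicated into two mirrored "hemispheres": the local neighborhood structure
(6 neighbors per interior vertex, 1+3k(k+1) vertices within k edge steps)
matches the regular triangulation of a cortical template closely enough for
the neighborhood-based metrics.

Vertex indexing is 0-based.  Left-hemisphere vertices come first
(0 .. n_per_hemi-1), then right (n_per_hemi .. 2*n_per_hemi-1); the homotopic
pairing is the identity map across that offset, mirroring the built-in vertex
correspondence of symmetric templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

__all__ = [
    "SymmetricSurfaceMesh",
    "build_hex_mesh",
    "kring_neighbors",
    "all_kring_neighborhoods",
    "build_group_mask",
    "load_gifti_surface",
    "save_mask_tsv",
    "load_mask_tsv",
]


@dataclass
class SymmetricSurfaceMesh:
    """Two mirrored triangulated hemispheres with homotopic vertex pairing.

    Attributes
    ----------
    coordinates : (n_vertices, 3) float array, mm
    triangles : (n_triangles, 3) int array
        Vertex index triples; every triangle lies within one hemisphere.
    hemisphere : (n_vertices,) array of 'L'/'R'
    homotopic_pair : (n_vertices,) int array
        Bijection between hemispheres; an involution (pair[pair[v]] == v).
    """

    coordinates: np.ndarray
    triangles: np.ndarray
    hemisphere: np.ndarray
    homotopic_pair: np.ndarray
    _adjacency: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_vertices_per_hemi(self) -> int:
        return int(np.sum(self.hemisphere == "L"))

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        n = self.n_vertices
        p = self.homotopic_pair
        if not np.array_equal(np.sort(p), np.arange(n)):
            raise ValueError("homotopic_pair is not a bijection")
        if not np.array_equal(p[p], np.arange(n)):
            raise ValueError("homotopic_pair is not an involution")
        if np.any(self.hemisphere[p] == self.hemisphere):
            raise ValueError("homotopic_pair must map across hemispheres")
        if self.triangles.min() < 0 or self.triangles.max() >= n:
            raise ValueError("triangle indices out of range")
        tri_hemi = self.hemisphere[self.triangles]
        if np.any(tri_hemi != tri_hemi[:, :1]):
            raise ValueError("triangles must stay within one hemisphere")

    @property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric vertex adjacency over triangle edges (cached)."""
        if self._adjacency is None:
            t = self.triangles
            i = np.concatenate([t[:, 0], t[:, 1], t[:, 2]])
            j = np.concatenate([t[:, 1], t[:, 2], t[:, 0]])
            n = self.n_vertices
            a = sparse.coo_matrix(
                (np.ones_like(i, dtype=np.int8), (i, j)), shape=(n, n)
            )
            a = ((a + a.T) > 0).astype(np.int8).tocsr()
            self._adjacency = a
        return self._adjacency


def _hex_axial_coords(rings: int) -> list[tuple[int, int]]:
    """Axial coordinates (q, r) of all lattice sites within `rings` steps."""
    out = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if max(abs(q), abs(r), abs(q + r)) <= rings:
                out.append((q, r))
    return out


def build_hex_mesh(
    rings: int, spacing: float = 2.0, hemi_offset: float = 30.0
) -> SymmetricSurfaceMesh:
    """Build a regular triangular (hexagonal) lattice as two mirrored hemispheres.

    Each hemisphere has 1 + 3*rings*(rings+1) vertices (a center plus `rings`
    concentric hexagonal rings); interior vertices have the full 6-neighbor
    triangulated structure.  Default spacing is 2 mm, emulating the
    inter-vertex distance of the cortical surface template.

    Parameters
    ----------
    rings : int
        Number of hexagonal rings around the central vertex (>= 1).  Use
        rings >= 5 if the center must own a complete 4-step neighborhood.
    spacing : float
        Edge length in mm.
    hemi_offset : float
        Distance from the mirror (x = 0) plane to each hemisphere's center,
        so that pair(v) has the coordinates of v with the x-axis negated.
    """
    if rings < 1:
        raise ValueError(f"rings must be >= 1, got {rings}")
    axial = _hex_axial_coords(rings)
    index = {qr: i for i, qr in enumerate(axial)}
    n = len(axial)

    local = np.empty((n, 3))
    for i, (q, r) in enumerate(axial):
        local[i] = (spacing * (q + r / 2.0), spacing * (np.sqrt(3) / 2.0) * r, 0.0)

    tris = []
    for q, r in axial:
        # two triangles of the rhombus anchored at (q, r)
        a, b, c, d = (q, r), (q + 1, r), (q, r + 1), (q + 1, r + 1)
        if b in index and c in index:
            tris.append((index[(q, r)], index[b], index[c]))
            if d in index:
                tris.append((index[b], index[d], index[c]))
    tris = np.asarray(tris, dtype=np.intp)

    right = local + np.array([hemi_offset, 0.0, 0.0])
    left = right * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])
    triangles = np.vstack([tris, tris + n])
    hemisphere = np.array(["L"] * n + ["R"] * n)
    pair = np.concatenate([np.arange(n) + n, np.arange(n)])
    mesh = SymmetricSurfaceMesh(coords, triangles, hemisphere, pair)
    mesh.validate()
    return mesh


def kring_neighbors(mesh: SymmetricSurfaceMesh, vertex: int, k: int) -> np.ndarray:
    """Vertices within k edge steps of `vertex` (center included), same hemisphere.

    Breadth-first expansion over the triangle edge graph.  Because triangles
    never cross hemispheres, the result automatically stays within the
    hemisphere of `vertex`.
    """
    n = mesh.n_vertices
    if not (0 <= vertex < n):
        raise IndexError(f"vertex {vertex} out of range [0, {n})")
    if k < 0:
        raise ValueError("k must be >= 0")
    adj = mesh.adjacency
    visited = np.zeros(n, dtype=bool)
    visited[vertex] = True
    frontier = np.array([vertex], dtype=np.intp)
    for _ in range(k):
        nxt = np.unique(adj[frontier].indices)
        nxt = nxt[~visited[nxt]]
        if nxt.size == 0:
            break
        visited[nxt] = True
        frontier = nxt
    return np.flatnonzero(visited)


def all_kring_neighborhoods(mesh: SymmetricSurfaceMesh, k: int) -> sparse.csr_matrix:
    """Boolean (n_vertices x n_vertices) neighborhood indicator for k edge steps.

    Row v marks every vertex within k steps of v, v itself included.  Computed
    by powering the adjacency structure; used to vectorize ReHo.
    """
    n = mesh.n_vertices
    reach = sparse.identity(n, dtype=np.int8, format="csr")
    step = mesh.adjacency + sparse.identity(n, dtype=np.int8, format="csr")
    for _ in range(k):
        reach = (reach @ step > 0).astype(np.int8)
    return reach.tocsr()


def build_group_mask(scans, mesh: SymmetricSurfaceMesh) -> np.ndarray:
    """Group analysis mask: vertices carrying signal in every supplied scan.

    A vertex is included iff its time series has nonzero temporal variance in
    all scans (the operational reading of "showing rfMRI signals").  Order of
    the scans is immaterial.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one scan to build a group mask")
    mask = np.ones(mesh.n_vertices, dtype=bool)
    for scan in scans:
        data = np.asarray(scan.data)
        if data.shape[0] != mesh.n_vertices:
            raise ValueError(
                f"scan has {data.shape[0]} vertices, mesh has {mesh.n_vertices}"
            )
        # tolerance: a numerically constant series (variance at rounding level
        # relative to its mean) counts as signal-free
        tol = (1e-8 * (1.0 + np.abs(data.mean(axis=1)))) ** 2
        mask &= data.var(axis=1) > tol
    if not mask.any():
        warnings.warn("group mask is empty: no vertex has signal in every scan")
    return mask


def load_gifti_surface(path) -> tuple[np.ndarray, np.ndarray]:
    """Read vertex coordinates and triangles from a GIFTI .surf.gii file.

    Optional convenience for users with real surface templates; requires
    nibabel.  Returns (coordinates, triangles) for one hemisphere.
    """
    import nibabel as nib

    img = nib.load(str(path))
    coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return np.asarray(coords, float), np.asarray(tris, np.intp)


def save_mask_tsv(mask: np.ndarray, path) -> None:
    """Write a group mask as a one-column TSV of 0/1 vertex flags."""
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")


def load_mask_tsv(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int).astype(bool)
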
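"""Icosahedral direction sets and peak finding on discretised ODFs.

Every orientation distribution function (ODF) in this package — diffusion
ODF, fiber ODF, or single-fiber component ODF — is a vector of values
sampled on the vertices of a geodesic tessellation of the icosahedron.
The default tessellation frequency is 8, which gives ``10 * 8**2 + 2 = 642``
unit vectors on the sphere; because diffusion is antipodally symmetric the
ODF is stored on the 321 unique axes obtained by identifying each vertex
with its antipode.  The nearest-neighbour spacing of the 321 axes is about
8 degrees, which sets the angular resolution of everything downstream.

The module provides the tessellation itself, the antipodal reduction, axis
angles (antipodally invariant angles between orientations), and local-maximum
peak finding on the tessellation mesh.
"""

from __future__ import annotations

from functools import cached_property
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "DirectionSet",
    "TessellationError",
    "tessellate_icosahedron",
    "reduce_antipodal",
    "axis_angle",
    "axis_angle_matrix",
    "find_peaks",
    "Peak",
]

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0
#: tolerance below which two candidate vertices are considered the same point
_MERGE_TOL = 1e-6
#: tolerance for antipodal pairing and duplicate-axis detection
_PAIR_TOL = 1e-9


class TessellationError(ValueError):
    """Raised when a direction set violates the tessellation structure."""


def _icosahedron_vertices() -> np.ndarray:
    """The 12 vertices of a regular icosahedron, unit-normalised."""
    g = _GOLDEN
    verts = []
    for a in (-1.0, 1.0):
        for b in (-g, g):
            verts.extend([(0.0, a, b), (a, b, 0.0), (b, 0.0, a)])
    verts = np.asarray(verts, dtype=float)
    return verts / np.linalg.norm(verts, axis=1, keepdims=True)


def _canonical_axis(v: np.ndarray) -> np.ndarray:
    """Flip ``v`` so its first nonzero coordinate (x, then y, then z) is positive."""
    for c in v:
        if abs(c) > _PAIR_TOL:
            return v if c > 0 else -v
    raise ValueError("zero vector has no canonical axis")


def _lexsorted(vectors: np.ndarray) -> np.ndarray:
    """Sort rows lexicographically on rounded coordinates (z, y, x keys last-first)."""
    keys = np.round(vectors, 9)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    return vectors[order]


class DirectionSet:
    """An ordered set of unit vectors from an icosahedral tessellation.

    Parameters
    ----------
    vectors : (n, 3) array
        Unit vectors.  Renormalised on construction so norms hold to 1e-15.
    frequency : int
        Geodesic subdivision frequency of the underlying tessellation.
    reduced : bool
        True when antipodal duplicates have been removed (one axis per
        antipodal pair).
    """

    def __init__(self, vectors: np.ndarray, frequency: int, reduced: bool):
        vectors = np.ascontiguousarray(vectors, dtype=float)
        if vectors.ndim != 2 or vectors.shape[1] != 3:
            raise ValueError("vectors must be an (n, 3) array")
        norms = np.linalg.norm(vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("direction vectors must be unit norm")
        self.vectors = vectors / norms[:, None]
        self.frequency = int(frequency)
        self.reduced = bool(reduced)
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def __iter__(self) -> Iterable[np.ndarray]:
        return iter(self.vectors)

    def __repr__(self) -> str:
        kind = "reduced" if self.reduced else "full"
        return f"DirectionSet(n={len(self)}, frequency={self.frequency}, {kind})"

    # -- mesh structure ----------------------------------------------------

    @cached_property
    def full(self) -> "DirectionSet":
        """The full (unreduced) tessellation this set derives from."""
        if not self.reduced:
            return self
        return tessellate_icosahedron(self.frequency)

    @cached_property
    def neighbors(self) -> tuple[np.ndarray, ...]:
        """Adjacency lists on the tessellation mesh.

        For a reduced set, edges of the full tessellation are mapped onto the
        axis representatives, which wraps neighbours that fell in the
        discarded hemisphere back onto their antipodal representative.
        """
        full = self.full
        hull = ConvexHull(full.vectors)
        edges = set()
        for tri in hull.simplices:
            a, b, c = (int(x) for x in tri)
            edges.update({(a, b), (b, c), (a, c)})
        if not self.reduced:
            adj: list[set[int]] = [set() for _ in range(len(self))]
            for i, j in edges:
                adj[i].add(j)
                adj[j].add(i)
            return tuple(np.array(sorted(s), dtype=int) for s in adj)
        # map each full vertex to the index of its axis representative
        tree = cKDTree(self.vectors)
        canon = np.array([_canonical_axis(v) for v in full.vectors])
        dist, rep = tree.query(canon)
        if np.any(dist > 1e-6):
            raise TessellationError("reduced set does not match its tessellation")
        adj = [set() for _ in range(len(self))]
        for i, j in edges:
            ri, rj = int(rep[i]), int(rep[j])
            if ri != rj:
                adj[ri].add(rj)
                adj[rj].add(ri)
        return tuple(np.array(sorted(s), dtype=int) for s in adj)

    # -- plain-text round trip --------------------------------------------

    def save(self, path) -> None:
        """Write one direction per row (three whitespace-separated floats)."""
        kind = "reduced" if self.reduced else "full"
        header = f"icosahedral directions, frequency={self.frequency}, {kind}"
        np.savetxt(path, self.vectors, fmt="%.17g", header=header, comments="# ")

    @classmethod
    def load(cls, path) -> "DirectionSet":
        """Read a direction table; frequency and reduction are inferred from the count."""
        vectors = np.atleast_2d(np.loadtxt(path, comments="#"))
        n = vectors.shape[0]
        for f in range(1, 64):
            if n == 10 * f * f + 2:
                return cls(vectors, frequency=f, reduced=False)
            if n == 5 * f * f + 1:
                return cls(vectors, frequency=f, reduced=True)
        raise TessellationError(f"{n} rows do not match any icosahedral tessellation")


def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical linear interpolation between unit vectors."""
    ang = np.arccos(np.clip(float(a @ b), -1.0, 1.0))
    if ang < 1e-12:
        return a
    return (np.sin((1.0 - t) * ang) * a + np.sin(t * ang) * b) / np.sin(ang)


def tessellate_icosahedron(frequency: int) -> DirectionSet:
    """Geodesic subdivision of the icosahedron at the given frequency.

    Each of the 20 faces is subdivided into ``frequency**2`` triangles with
    vertices spaced along great-circle arcs (row-wise spherical
    interpolation), and vertices shared between faces are merged, giving
    ``10 * frequency**2 + 2`` unique vertices in a deterministic
    (lexicographic) order.  Face corners are taken in a canonical order that
    is invariant under the antipodal map, so the vertex set is exactly
    antipodally symmetric.
    """
    if int(frequency) != frequency or frequency < 1:
        raise ValueError("frequency must be an integer >= 1")
    f = int(frequency)
    base = _icosahedron_vertices()
    hull = ConvexHull(base)
    points = []
    for tri in hull.simplices:
        corners = sorted(
            (base[i] for i in tri),
            key=lambda v: tuple(np.round(_canonical_axis(v), 9)),
        )
        a, b, c = corners
        for i in range(f + 1):
            p = _slerp(a, c, i / f)
            q = _slerp(b, c, i / f)
            ncols = f - i
            for j in range(ncols + 1):
                t = 0.0 if ncols == 0 else j / ncols
                points.append(_slerp(p, q, t))
    pts = np.asarray(points)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)

    # merge duplicated shared vertices (union-find on close pairs)
    tree = cKDTree(pts)
    parent = np.arange(len(pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(_MERGE_TOL):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    roots = np.array([find(i) for i in range(len(pts))])
    uniq = np.unique(roots)
    merged = np.empty((len(uniq), 3))
    for row, r in enumerate(uniq):
        v = pts[roots == r].mean(axis=0)
        merged[row] = v / np.linalg.norm(v)

    expected = 10 * f * f + 2
    if merged.shape[0] != expected:
        raise TessellationError(
            f"subdivision produced {merged.shape[0]} vertices, expected {expected}"
        )
    return DirectionSet(_lexsorted(merged), frequency=f, reduced=False)


def reduce_antipodal(dirs: DirectionSet) -> DirectionSet:
    """Collapse a full tessellation to one representative per antipodal pair.

    The representative of a pair is the member whose first nonzero coordinate
    is positive; the output order follows the full set's order.
    """
    if dirs.reduced:
        raise ValueError("direction set is already antipodally reduced")
    V = dirs.vectors
    tree = cKDTree(V)
    dist, anti = tree.query(-V)
    idx = np.arange(len(V))
    if np.any(dist > _PAIR_TOL) or np.any(anti == idx):
        raise TessellationError("tessellation has unpaired vectors")
    if np.any(anti[anti] != idx):
        raise TessellationError("antipodal pairing is not an involution")
    keep = idx < anti
    reps = np.array([_canonical_axis(v) for v in V[keep]])
    out = DirectionSet(reps, frequency=dirs.frequency, reduced=True)
    # duplicate-axis sanity: no two kept axes may be (anti)parallel
    dots = np.abs(out.vectors @ out.vectors.T)
    np.fill_diagonal(dots, 0.0)
    if np.any(dots > 1.0 - _PAIR_TOL):
        raise TessellationError("reduced set contains duplicate axes")
    return out


def axis_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle in degrees between two axes (orientations), in [0, 90].

    Antipodally invariant: ``axis_angle(u, v) == axis_angle(u, -v)``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    for w in (u, v):
        if abs(np.linalg.norm(w) - 1.0) > 1e-6:
            raise ValueError("axis_angle requires unit vectors")
    return float(np.degrees(np.arccos(min(abs(float(u @ v)), 1.0))))


def axis_angle_matrix(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Pairwise axis angles in degrees between rows of ``U`` and rows of ``V``."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    dots = np.clip(np.abs(U @ V.T), 0.0, 1.0)
    return np.degrees(np.arccos(dots))


class Peak(NamedTuple):
    """A local maximum of an ODF on the tessellation mesh."""

    index: int
    orientation: np.ndarray
    value: float


def find_peaks(odf, dirs: DirectionSet, min_fraction: float = 0.0) -> list[Peak]:
    """Local maxima of an ODF on the reduced tessellation mesh.

    An entry is a peak when it is positive, at least ``min_fraction``, and not
    smaller than any of its mesh neighbours (antipodally wrapped).  Adjacent
    nonzero entries of a sparse fiber ODF therefore merge into the largest one
    unless both are local maxima.  Peaks are ranked by descending value, ties
    broken by lower direction index.
    """
    values = np.asarray(getattr(odf, "values", odf), dtype=float)
    if not dirs.reduced:
        raise ValueError("find_peaks requires an antipodally reduced DirectionSet")
    if values.shape != (len(dirs),):
        raise ValueError("ODF length does not match the direction set")
    if min_fraction < 0:
        raise ValueError("min_fraction must be >= 0")
    neighbors = dirs.neighbors
    peaks = [
        Peak(i, dirs.vectors[i], float(values[i]))
        for i in range(len(dirs))
        if values[i] > 0
        and values[i] >= min_fraction
        and (neighbors[i].size == 0 or values[i] >= values[neighbors[i]].max())
    ]
    peaks.sort(key=lambda p: (-p.value, p.index))
    return peaks
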
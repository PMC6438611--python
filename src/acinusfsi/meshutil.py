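"""Small triangle-mesh utilities shared by geometry, solid and fluid stages."""

from __future__ import annotations

import numpy as np

__all__ = [
    "subdivide_triangles",
    "taubin_smooth",
    "icosphere",
    "boundary_ring",
    "orient_outward",
]


def subdivide_triangles(
    nodes: np.ndarray, tris: np.ndarray, levels: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform 4-to-1 triangle subdivision with welded edge midpoints."""
    nodes = np.asarray(nodes, float)
    tris = np.asarray(tris, int)
    for _ in range(levels):
        mid_cache: dict[tuple[int, int], int] = {}
        new_nodes = [nodes]
        offset = len(nodes)

        def midpoint(a: int, b: int) -> int:
            nonlocal offset
            key = (min(a, b), max(a, b))
            idx = mid_cache.get(key)
            if idx is None:
                mid_cache[key] = idx = offset
                new_nodes.append(0.5 * (nodes[a] + nodes[b])[None])
                offset += 1
            return idx

        out = np.empty((4 * len(tris), 3), int)
        for i, (a, b, c) in enumerate(tris):
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            out[4 * i : 4 * i + 4] = [(a, ab, ca), (ab, b, bc), (ca, bc, c), (ab, bc, ca)]
        nodes = np.vstack(new_nodes)
        tris = out
    return nodes, tris


def boundary_ring(tris: np.ndarray) -> np.ndarray:
    """Node indices on edges used by exactly one triangle."""
    edges: dict[tuple[int, int], int] = {}
    for t in tris:
        for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
            key = (min(a, b), max(a, b))
            edges[key] = edges.get(key, 0) + 1
    ring = {i for (a, b), c in edges.items() if c == 1 for i in (a, b)}
    return np.array(sorted(ring), int)


def _adjacency(n: int, tris: np.ndarray):
    import scipy.sparse as sp

    e = np.vstack(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]]
    )
    e = np.vstack([e, e[:, ::-1]])
    A = sp.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()
    A.data[:] = 1.0
    return A


def taubin_smooth(
    nodes: np.ndarray,
    tris: np.ndarray,
    iterations: int = 40,
    lam: float = 0.5,
    mu: float = -0.53,
    fixed: np.ndarray | None = None,
) -> np.ndarray:
    """Taubin lambda/mu smoothing (volume-friendly low-pass filter)."""
    x = np.asarray(nodes, float).copy()
    A = _adjacency(len(x), tris)
    deg = np.maximum(np.asarray(A.sum(axis=1)).ravel(), 1.0)
    free = np.ones(len(x), bool)
    if fixed is not None and len(fixed):
        free[np.asarray(fixed, int)] = False
    for _ in range(iterations):
        for factor in (lam, mu):
            dx = (A @ x) / deg[:, None] - x
            x[free] += factor * dx[free]
    return x


def icosphere(radius: float = 1.0, levels: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Geodesic sphere from a subdivided icosahedron, outward-oriented."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    v = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        float,
    )
    f = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        int,
    )
    nodes, tris = subdivide_triangles(v, f, levels)
    nodes = nodes / np.linalg.norm(nodes, axis=1)[:, None] * radius
    return orient_outward(nodes, tris)


def orient_outward(nodes: np.ndarray, tris: np.ndarray):
    """Flip triangles whose normals point toward the centroid (convex-ish)."""
    c = nodes.mean(axis=0)
    x = nodes[tris]
    n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
    mid = x.mean(axis=1) - c
    flip = np.einsum("ij,ij->i", n, mid) < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return nodes, tris
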
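"""Layered tetrahedral meshes and structured hex-to-tet generation.

The simulation domain is a three-layer tissue stack — rigid bone, soft dermis,
stiff thin epidermis — represented as a conforming tetrahedral mesh with
per-element layer labels.  Meshes are built from structured hexahedral grids
subdivided with the Kuhn (path) triangulation, which is conforming across
neighbouring cells and produces uniformly positively oriented tetrahedra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# layer codes (stored as per-tet integers)
BONE = 0
DERMIS = 1
EPIDERMIS = 2
LAYER_NAMES = {BONE: "bone", DERMIS: "dermis", EPIDERMIS: "epidermis"}

# boundary tag codes (per node)
FREE = 0
BONE_FIXED = 1
LATERAL = 2
TAG_NAMES = {FREE: "free", BONE_FIXED: "bone_fixed", LATERAL: "lateral"}

# the 6 permutations of (x, y, z) defining the Kuhn path tetrahedra
_KUHN_PERMS = [
    (0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0),
]


@dataclass
class LayeredMesh:
    """Tetrahedral mesh of a layered tissue block.

    Attributes
    ----------
    nodes : (n, 3) float array
        Reference coordinates.  1 length unit = initial epidermis thickness.
    tets : (m, 4) int array
        Node indices, positively oriented (signed volume > 0).
    layer : (m,) int array
        Per-tet layer code (``BONE``, ``DERMIS`` or ``EPIDERMIS``).
    surface_normal : (m, 3) float array
        Unit reference mid-surface normal of each tet's layer; the growth
        tensor's normal direction.
    boundary_tags : (n,) int array
        ``FREE``, ``BONE_FIXED`` or ``LATERAL`` per node.
    constraint : (n, 3, 3) float array
        Projection matrix onto each node's admissible displacement subspace
        (identity for free nodes, zero for bone, a sliding-plane projector
        for lateral rim nodes).
    metadata : dict
        Generator parameters and any generation warnings.
    """

    nodes: np.ndarray
    tets: np.ndarray
    layer: np.ndarray
    surface_normal: np.ndarray
    boundary_tags: np.ndarray
    constraint: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def signed_volumes(self) -> np.ndarray:
        return signed_volumes(self.nodes, self.tets)

    def layer_volume(self, layer_code: int) -> float:
        return float(self.signed_volumes()[self.layer == layer_code].sum())

    def total_volume(self) -> float:
        return float(self.signed_volumes().sum())

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (e, 2) index array."""
        t = self.tets
        pairs = np.concatenate(
            [t[:, [0, 1]], t[:, [0, 2]], t[:, [0, 3]],
             t[:, [1, 2]], t[:, [1, 3]], t[:, [2, 3]]]
        )
        pairs.sort(axis=1)
        return np.unique(pairs, axis=0)

    def validate(self) -> None:
        """Raise ``ValueError`` on violated structural invariants."""
        vols = self.signed_volumes()
        if not (vols > 0).all():
            bad = int((vols <= 0).sum())
            raise ValueError(f"{bad} tetrahedra are degenerate or inverted")
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.tets.ravel()] = True
        if not used.all():
            raise ValueError(f"{int((~used).sum())} nodes belong to no tet")
        norms = np.linalg.norm(self.surface_normal, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("surface normals are not unit length")


def signed_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volume of each tetrahedron (positive for correct orientation)."""
    p = nodes[tets]
    d = p[:, 1:] - p[:, :1]
    return np.linalg.det(d) / 6.0


def boundary_faces(tets: np.ndarray) -> np.ndarray:
    """Faces belonging to exactly one tet, outward-oriented.

    Each tet contributes the four faces opposite its vertices, wound so the
    outward normal points away from the remaining vertex.
    """
    # face (i, j, k) opposite vertex l, oriented outward for a positive tet
    f = np.concatenate(
        [tets[:, [1, 2, 3]], tets[:, [0, 3, 2]],
         tets[:, [0, 1, 3]], tets[:, [0, 2, 1]]]
    )
    key = np.sort(f, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return f[counts[inv] == 1]


def hex_grid_tets(shape: tuple[int, int, int]) -> np.ndarray:
    """Kuhn 6-tet subdivision of an (nx, ny, nz)-cell structured grid.

    Node (i, j, k) has index ``(i * (ny+1) + j) * (nz+1) + k``.  The split is
    conforming across shared faces and orientation is corrected to positive
    for any grid whose node positions are a monotone map of (i, j, k).
    """
    nx, ny, nz = shape

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ii, jj, kk = ii.ravel(), jj.ravel(), kk.ravel()
    tets = np.empty((len(ii), 6, 4), dtype=np.int64)
    for t, perm in enumerate(_KUHN_PERMS):
        steps = np.zeros((4, 3), dtype=np.int64)
        for s, ax in enumerate(perm):
            steps[s + 1] = steps[s]
            steps[s + 1, ax] += 1
        corners = []
        for s in range(4):
            corners.append(nid(ii + steps[s, 0], jj + steps[s, 1], kk + steps[s, 2]))
        tets[:, t, :] = np.stack(corners, axis=1)
    return tets.reshape(-1, 4)


def orient_positive(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Swap two vertices of any negatively oriented tet."""
    vols = signed_volumes(nodes, tets)
    idx = np.where(vols < 0)[0]
    tets = tets.copy()
    tets[idx, 2], tets[idx, 3] = tets[idx, 3].copy(), tets[idx, 2].copy()
    return tets


def structured_layered_grid(
    xs: np.ndarray,
    ys: np.ndarray,
    zs: np.ndarray,
    layer_of_cell_k: np.ndarray,
    warp=None,
):
    """Build nodes/tets/layers for a structured grid with per-z-slab layers.

    Parameters
    ----------
    xs, ys, zs : 1-D coordinate arrays (node levels).
    layer_of_cell_k : (len(zs) - 1,) int array, layer code of each z element slab.
    warp : optional callable mapping an (n, 3) array of (x, y, z) grid
        coordinates to final positions (used for the spherical cap).
    """
    nx, ny, nz = len(xs) - 1, len(ys) - 1, len(zs) - 1
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    if warp is not None:
        nodes = warp(nodes)
    tets = hex_grid_tets((nx, ny, nz))
    tets = orient_positive(nodes, tets)
    # layer of a tet = layer of the z slab of its parent hex
    cell_k = np.tile(
        np.repeat(np.arange(nz), 1), nx * ny
    )
    layer = np.repeat(layer_of_cell_k[cell_k], 6)
    return nodes, tets, layer, (nx, ny, nz)
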
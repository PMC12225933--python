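"""Volumetric microscopy-style segmentation of layered skin stacks.

Pipeline mirror of light-sheet tissue segmentation: 3D Canny edge detection
of a nuclear-stain volume yields point clouds on the two skin surfaces (the
outer epidermis surface and the epidermis-dermis boundary, separable because
the densely nucleated epidermis is much brighter than the sparse dermis);
intensity-gradient normals orient the clouds; an implicit signed
moving-least-squares field reconstructs light triangular surface meshes from
which the epidermis thickness map is computed; and a 3D principal-curvature
(Hessian) blob detector segments labelled proliferating cells even when they
touch.

Coordinates are voxel-centred, 0-based, z-slowest axis order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import apply_hysteresis_threshold
from skimage.measure import marching_cubes

from . import config
from .surfaces import TriSurface

logger = logging.getLogger(__name__)

__all__ = [
    "OrientedPointCloud", "CellDetection", "TriSurface",
    "canny_edges_3d", "estimate_normals", "reconstruct_surface",
    "thickness_map", "detect_cells", "proliferation_density",
    "split_edge_surfaces",
]


@dataclass
class OrientedPointCloud:
    """Edge points with outward unit normals (voxel units)."""

    points: np.ndarray      # (n, 3), (z, y, x)
    normals: np.ndarray     # (n, 3), unit, pointing from high to low intensity

    def __post_init__(self):
        if len(self.points) != len(self.normals):
            raise ValueError("points and normals must have equal length")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CellDetection:
    """Detected cell centroids with detection strengths."""

    centroids: np.ndarray   # (n, 3), (z, y, x)
    scores: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.centroids)


# --------------------------------------------------------------------------
# edges and normals
# --------------------------------------------------------------------------

def canny_edges_3d(
    stack: np.ndarray,
    sigma: float = config.CANNY_SIGMA,
    low: float = config.CANNY_LOW_QUANTILE,
    high: float = config.CANNY_HIGH_QUANTILE,
    threshold_mode: str = "quantile",
) -> np.ndarray:
    """3D Canny edge detection.

    Gaussian smoothing, 3D intensity gradient, non-maximum suppression along
    the gradient direction (trilinear sampling of the magnitude one voxel
    ahead and behind), then double-threshold hysteresis on the surviving
    magnitudes.  By default ``low``/``high`` are *quantiles* of the positive
    gradient magnitudes; ``threshold_mode='absolute'`` treats them as raw
    magnitude thresholds.  A constant stack yields an empty edge set.
    """
    if not (0 <= low < high):
        raise ValueError("thresholds must satisfy 0 <= low < high")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    stack = np.asarray(stack, dtype=float)
    sm = ndimage.gaussian_filter(stack, sigma, mode="nearest")
    gz, gy, gx = np.gradient(sm)
    mag = np.sqrt(gz**2 + gy**2 + gx**2)
    if mag.max() <= 0:
        return np.zeros(stack.shape, dtype=bool)

    with np.errstate(invalid="ignore", divide="ignore"):
        dz, dy, dx = (np.where(mag > 0, g / mag, 0.0) for g in (gz, gy, gx))
    zz, yy, xx = np.meshgrid(
        *(np.arange(s, dtype=float) for s in stack.shape), indexing="ij"
    )
    ahead = ndimage.map_coordinates(
        mag, [zz + dz, yy + dy, xx + dx], order=1, mode="nearest"
    )
    behind = ndimage.map_coordinates(
        mag, [zz - dz, yy - dy, xx - dx], order=1, mode="nearest"
    )
    nms = np.where((mag >= ahead) & (mag >= behind), mag, 0.0)

    if threshold_mode == "quantile":
        pos = nms[nms > 0]
        if pos.size == 0:
            return np.zeros(stack.shape, dtype=bool)
        lo_v, hi_v = np.quantile(pos, [low, high])
    elif threshold_mode == "absolute":
        lo_v, hi_v = low, high
    else:
        raise ValueError("threshold_mode must be 'quantile' or 'absolute'")
    if hi_v <= 0:
        return np.zeros(stack.shape, dtype=bool)
    return apply_hysteresis_threshold(nms, lo_v, hi_v) & (nms > 0)


def estimate_normals(
    stack: np.ndarray,
    points: np.ndarray,
    sigma: float = config.CANNY_SIGMA,
) -> OrientedPointCloud:
    """Surface normals from the smoothed intensity gradient at edge points.

    Orientation convention: normals point from high to low intensity, i.e.
    outward from the (bright) tissue.  Points with vanishing gradient are
    dropped with a logged count.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("no points given")
    sm = ndimage.gaussian_filter(np.asarray(stack, dtype=float), sigma,
                                 mode="nearest")
    grads = np.gradient(sm)
    g = np.stack([
        ndimage.map_coordinates(gi, points.T, order=1, mode="nearest")
        for gi in grads
    ], axis=1)
    norm = np.linalg.norm(g, axis=1)
    keep = norm > 1e-12
    if (~keep).any():
        logger.info("estimate_normals: dropped %d zero-gradient points",
                    int((~keep).sum()))
    normals = -g[keep] / norm[keep, None]
    return OrientedPointCloud(points=points[keep], normals=normals)


def split_edge_surfaces(
    stack: np.ndarray,
    edges: np.ndarray,
    sigma: float = config.CANNY_SIGMA,
    probe_distance: float = 3.0,
    min_points: int = 50,
) -> dict[str, OrientedPointCloud]:
    """Separate edge voxels into outer-surface and inner-boundary clouds.

    Edge voxels are grouped by 26-connectivity; for each sizeable component
    the mean intensity sampled a few voxels *outside* (along the normals)
    discriminates the outer epidermis surface (background, ~0) from the
    epidermis-dermis boundary (dim dermis).  Returns clouds keyed
    ``'outer'`` and ``'inner'``.
    """
    labels, n = ndimage.label(edges, structure=np.ones((3, 3, 3)))
    if n < 2:
        raise ValueError(
            f"expected at least two edge components, found {n}"
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    order = np.argsort(sizes)[::-1]
    candidates = [int(order[i]) + 1 for i in range(min(n, 6))
                  if sizes[order[i]] >= min_points]
    if len(candidates) < 2:
        raise ValueError("fewer than two sizeable edge components")
    img = np.asarray(stack, dtype=float)
    clouds, inside_i, outside_i = [], [], []
    for lab in candidates:
        pts = np.argwhere(labels == lab)
        cloud = estimate_normals(stack, pts, sigma)
        for sign, store in ((+1, outside_i), (-1, inside_i)):
            probe = cloud.points + sign * probe_distance * cloud.normals
            vals = ndimage.map_coordinates(img, probe.T, order=1,
                                           mode="nearest")
            store.append(float(vals.mean()))
        clouds.append(cloud)
    # the two skin surfaces bound the bright epidermis band: highest
    # *inside* intensity; among them the outer surface faces background
    # (lowest *outside* intensity)
    top2 = np.argsort(inside_i)[::-1][:2]
    a, b = int(top2[0]), int(top2[1])
    i_outer, i_inner = (a, b) if outside_i[a] <= outside_i[b] else (b, a)
    return {"outer": clouds[i_outer], "inner": clouds[i_inner]}


# --------------------------------------------------------------------------
# surface reconstruction
# --------------------------------------------------------------------------

def reconstruct_surface(
    cloud: OrientedPointCloud,
    spacing: float = config.RECON_SPACING,
    k_neighbors: int = config.RECON_NEIGHBORS,
    padding: float = 3.0,
) -> TriSurface:
    """Triangular surface from an oriented point cloud.

    A signed moving-least-squares field — the k-nearest-neighbour weighted
    average of ``(x - p_i) . n_i`` — is evaluated on a regular grid of the
    given spacing and its zero level set extracted by marching cubes.  The
    result represents the cloud in a much lighter format: the vertex count
    shrinks roughly with ``spacing^2``.  Incoherently oriented normals
    (mean neighbour alignment < 0.5) are rejected with advice to re-orient.
    """
    if len(cloud) < 100:
        raise ValueError("need at least 100 oriented points")
    pts = cloud.points
    nrm = cloud.normals
    tree = cKDTree(pts)
    # orientation coherence: average alignment with the nearest neighbours
    _, nb = tree.query(pts, k=min(6, len(pts)))
    align = np.einsum("ij,ikj->ik", nrm, nrm[nb[:, 1:]]).mean()
    if align < 0.5:
        raise ValueError(
            f"normals are incoherently oriented (mean neighbour alignment "
            f"{align:.2f} < 0.5); re-orient the cloud before reconstruction"
        )

    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    axes = [np.arange(lo[d], hi[d] + spacing, spacing) for d in range(3)]
    gz, gy, gx = np.meshgrid(*axes, indexing="ij")
    q = np.stack([gz.ravel(), gy.ravel(), gx.ravel()], axis=1)

    k = min(k_neighbors, len(pts))
    dist, idx = tree.query(q, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    diff = q[:, None, :] - pts[idx]
    signed = np.einsum("qkj,qkj->qk", diff, nrm[idx])
    h = 2.0 * spacing
    w = np.exp(-(dist / h) ** 2)
    f = (w * signed).sum(axis=1) / w.sum(axis=1)
    field_grid = f.reshape(gz.shape)

    if field_grid.min() >= 0 or field_grid.max() <= 0:
        raise ValueError("implicit field has no zero crossing")
    verts, faces, _, _ = marching_cubes(
        field_grid, level=0.0, gradient_direction="ascent"
    )
    verts = verts * spacing + lo
    surf = TriSurface(
        vertices=verts, faces=faces,
        metadata={"spacing": spacing, "n_input_points": len(pts)},
    ).drop_degenerate_faces()
    # orient faces so surface normals agree with the cloud normals
    vn = surf.vertex_normals()
    _, nearest = tree.query(surf.vertices)
    if float((vn * nrm[nearest]).sum(axis=1).mean()) < 0:
        surf.faces = surf.faces[:, [0, 2, 1]]
    return surf


def _ray_cast_distance(origins, directions, vertices, faces,
                       chunk: int = 256, eps: float = 1e-12) -> np.ndarray:
    """Nearest forward ray-triangle hit distance per ray (Moller-Trumbore).

    Vectorised over (ray chunk) x (all triangles); NaN where a ray misses.
    Intended for the moderate mesh sizes of reconstructed surfaces.
    """
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    out = np.full(len(origins), np.nan)
    for s in range(0, len(origins), chunk):
        o = origins[s:s + chunk][:, None, :]
        d = directions[s:s + chunk][:, None, :]
        p = np.cross(d, e2[None])                      # (r, t, 3)
        det = (p * e1[None]).sum(-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(np.abs(det) > eps, 1.0 / det, np.nan)
            tvec = o - v0[None]
            u = (tvec * p).sum(-1) * inv
            q = np.cross(tvec, e1[None])
            v = (q * d).sum(-1) * inv
            t = (q * e2[None]).sum(-1) * inv
        hit = (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t >= -1e-9)
        t = np.where(hit, np.maximum(t, 0.0), np.inf)
        tmin = t.min(axis=1)
        out[s:s + chunk] = np.where(np.isfinite(tmin), tmin, np.nan)
    return out


def thickness_map(outer: TriSurface, inner: TriSurface,
                  miss_warn_fraction: float = 0.1) -> np.ndarray:
    """Epidermis thickness at each outer vertex.

    Distance from the outer vertex to the inner surface along the inward
    vertex normal (ray cast); rays that miss fall back to the distance to
    the nearest point of the inner surface.  A warning reports the miss
    fraction when more than ``miss_warn_fraction`` of rays miss.
    """
    origins = outer.vertices
    directions = -outer.vertex_normals()
    thickness = _ray_cast_distance(origins, directions,
                                   inner.vertices, inner.faces)
    miss = np.isnan(thickness)
    if miss.any():
        frac = miss.mean()
        if frac > miss_warn_fraction:
            warnings.warn(
                f"thickness_map: {frac:.1%} of rays missed the inner "
                "surface; using nearest-point fallback for them",
                stacklevel=2,
            )
        tree = cKDTree(inner.vertices)
        d, _ = tree.query(origins[miss])
        thickness[miss] = d
    thickness = np.clip(thickness, 0.0, None)
    outer.vertex_data["thickness"] = thickness
    return thickness


# --------------------------------------------------------------------------
# cell detection and densities
# --------------------------------------------------------------------------

def detect_cells(
    stack: np.ndarray,
    scale: float = config.CELL_DETECT_SCALE,
    curvature_threshold: float = config.CELL_DETECT_THRESHOLD,
) -> CellDetection:
    """Bright-blob cells from 3D principal curvatures of the intensity.

    The Hessian of the scale-smoothed stack is evaluated everywhere; a voxel
    is a cell candidate when all three principal curvatures (Hessian
    eigenvalues) are negative — a bright blob in every direction — and the
    *smallest-magnitude* one exceeds the threshold, which suppresses ridge-
    and plate-like responses (layer boundaries).  Candidates are merged into
    connected components and reported at their intensity-weighted centroids,
    which separates touching cells of the expected scale.  An empty
    detection is a valid result.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.max() <= stack.min():
        return CellDetection(centroids=np.empty((0, 3)), scores=np.empty(0))
    h = np.empty((3, 3) + stack.shape)
    for a in range(3):
        for b in range(a, 3):
            order = [0, 0, 0]
            order[a] += 1
            order[b] += 1
            d = ndimage.gaussian_filter(stack, scale, order=order,
                                        mode="nearest")
            h[a, b] = d
            h[b, a] = d
    hm = np.moveaxis(h.reshape(3, 3, -1), -1, 0)
    eigs = np.linalg.eigvalsh(hm)          # ascending
    lam_max = eigs[:, 2].reshape(stack.shape)   # smallest magnitude if all < 0
    candidate = (lam_max < -abs(curvature_threshold))
    if not candidate.any():
        return CellDetection(centroids=np.empty((0, 3)), scores=np.empty(0))

    labels, n = ndimage.label(candidate)
    weight = np.where(candidate, -lam_max, 0.0)
    centroids = ndimage.center_of_mass(weight, labels, range(1, n + 1))
    scores = ndimage.maximum(weight, labels, range(1, n + 1))
    return CellDetection(
        centroids=np.asarray(centroids, dtype=float).reshape(-1, 3),
        scores=np.asarray(scores, dtype=float),
        meta={"scale": scale, "threshold": curvature_threshold},
    )


def proliferation_density(
    cells: CellDetection,
    layer_masks: dict[str, np.ndarray],
    voxel_size: float = 1.0,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Per-layer cell density with a spatial homogeneity statistic.

    Density is centroid count over mask volume.  Homogeneity: each mask's
    bounding box is split into an ``n_bins^3`` grid; the coefficient of
    variation of volume-normalised bin counts (bins holding at least 2% of
    the mask) measures spatial clustering — for a homogeneous (Poisson)
    distribution the count CV approaches ``1 / sqrt(mean bin count)``.
    Layers with empty masks are reported as missing, not zero.
    """
    masks = list(layer_masks.items())
    for i, (na, ma) in enumerate(masks):
        for nb, mb in masks[i + 1:]:
            if (ma & mb).any():
                raise ValueError(f"layer masks {na!r} and {nb!r} overlap")
    rows = []
    pts = cells.centroids
    for name, mask in masks:
        nvox = int(mask.sum())
        if nvox == 0:
            rows.append({"layer": name, "n_cells": 0, "volume": 0.0,
                         "density": np.nan, "cv": np.nan, "missing": True})
            continue
        if len(pts):
            ip = np.round(pts).astype(int)
            ip = np.clip(ip, 0, np.array(mask.shape) - 1)
            inside = mask[ip[:, 0], ip[:, 1], ip[:, 2]]
        else:
            inside = np.zeros(0, dtype=bool)
        n_in = int(inside.sum())
        volume = nvox * voxel_size**3
        cv = _binned_cv(pts[inside] if n_in else np.empty((0, 3)),
                        mask, n_bins)
        rows.append({"layer": name, "n_cells": n_in, "volume": volume,
                     "density": n_in / volume, "cv": cv, "missing": False})
    return pd.DataFrame(rows)


def _binned_cv(pts: np.ndarray, mask: np.ndarray, n_bins: int) -> float:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    edges = [np.linspace(lo[d], hi[d], n_bins + 1) for d in range(3)]
    # mask volume per bin
    vol, _ = np.histogramdd(idx.astype(float), bins=edges)
    counts, _ = np.histogramdd(pts, bins=edges) if len(pts) else (
        np.zeros((n_bins,) * 3), None)
    keep = vol > 0.02 * mask.sum() / n_bins**3 * 3   # bins with real support
    if keep.sum() < 2:
        return np.nan
    dens = counts[keep] / vol[keep]
    if dens.mean() == 0:
        return np.nan
    return float(dens.std() / dens.mean())
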
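"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: layered tetrahedral
meshes of a dome-shaped head-skin patch (stiff thin epidermis over soft
dermis over rigid bone), 3D light-sheet-style image phantoms (bright dense
epidermis band over a dim sparse dermis, Gaussian-blob labelled cells, a bone
shell mask), and Hertzian load-displacement indentation curves.

Lengths in the mesh generators are expressed in units of the initial
epidermis thickness; phantom lengths are in voxels (z-slowest axis order);
indentation lengths in microns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .indentation import IndentationCurve, hertz_force
from .meshing import (
    BONE,
    BONE_FIXED,
    DERMIS,
    EPIDERMIS,
    FREE,
    LATERAL,
    LayeredMesh,
    structured_layered_grid,
)

__all__ = [
    "LayeredMesh", "ImagePhantom", "IndentationCurve",
    "make_layered_cap", "make_flat_bilayer", "make_uniform_block",
    "make_image_phantom", "make_indentation_curves",
]


# --------------------------------------------------------------------------
# meshes
# --------------------------------------------------------------------------

def _radial_levels(h: float, n: int, start: float) -> np.ndarray:
    return start + np.linspace(0.0, h, n + 1)[1:]


def _graded_spacings(h_total: float, dz0: float, growth: float = 1.4,
                     dz_max: float | None = None) -> np.ndarray:
    """Element sizes grading geometrically from ``dz0`` up to ``dz_max``."""
    sizes = []
    dz = dz0
    while sum(sizes) < h_total:
        sizes.append(dz)
        dz = min(dz * growth, dz_max) if dz_max else dz * growth
    sizes = np.array(sizes)
    sizes *= h_total / sizes.sum()
    return sizes


def _apply_jitter(nodes, constraint, movable, amplitude, rng,
                  grid_shape=None, spacing=1.0,
                  correlation=config.PERTURB_CORRELATION):
    """Seeded stochastic node displacement, smooth at tissue scale.

    White noise on the structured grid is Gaussian-smoothed to the given
    correlation length and rescaled to the requested RMS amplitude — the
    finite-amplitude spatial fluctuations that break symmetry and nucleate
    subcritical creases.  The field is projected onto each node's admissible
    subspace so constrained boundaries stay exact, and clamped nodes do not
    move.
    """
    if amplitude <= 0:
        return nodes
    if grid_shape is not None:
        from scipy.ndimage import gaussian_filter

        shape = tuple(s + 1 for s in grid_shape)
        noise = rng.standard_normal(shape + (3,))
        sig = max(correlation / max(spacing, 1e-9), 1e-6)
        for c in range(3):
            noise[..., c] = gaussian_filter(noise[..., c],
                                            sigma=(sig, sig, sig * 0.5),
                                            mode="nearest")
        rms = np.sqrt((noise**2).mean())
        jitter = (noise / max(rms, 1e-30) * amplitude).reshape(-1, 3)
    else:
        jitter = rng.uniform(-amplitude, amplitude, nodes.shape)
    jitter = np.einsum("nij,nj->ni", constraint, jitter)
    nodes = nodes.copy()
    nodes[movable] += jitter[movable]
    return nodes


def make_layered_cap(
    cap_radius: float = config.CAP_RADIUS,
    h_epid: float = config.CAP_H_EPIDERMIS,
    h_dermis: float = config.CAP_H_DERMIS,
    resolution: int = config.CAP_RESOLUTION,
    perturb_amplitude: float = config.PERTURB_AMPLITUDE,
    seed: int = 0,
    h_bone: float = config.CAP_H_BONE,
    inplane_spacing: float = config.CAP_INPLANE_SPACING,
    half_width_fraction: float = config.CAP_HALF_WIDTH_FRACTION,
) -> LayeredMesh:
    """Spherical-cap shell of three concentric layers (bone, dermis, epidermis).

    The cap is a graph over a square patch: a (u, v) grid on
    ``[-a, a]^2`` (``a = half_width_fraction * cap_radius``) is projected onto
    concentric spheres centred at the origin.  ``cap_radius`` is the outer
    (epidermis) radius.  ``resolution`` sets the element count across the
    epidermis thickness; the dermis is graded to a comparable but coarser
    through-thickness resolution and the rigid bone shell gets one element.

    Node jitter of the given amplitude (uniform, seeded) breaks the symmetry
    of the subsequent growth simulation everywhere except on bone nodes.
    """
    if h_epid <= 0 or h_dermis <= 0 or h_bone <= 0:
        raise ValueError("layer thicknesses must be positive")
    if cap_radius <= h_epid + h_dermis:
        raise ValueError("cap_radius must exceed total skin thickness")
    if resolution < 2:
        raise ValueError("resolution must be >= 2 element layers per layer")

    R = float(cap_radius)
    a = half_width_fraction * R
    if np.hypot(a, a) >= R:
        raise ValueError("half_width_fraction too large for a graph-type cap")

    dz_epid = h_epid / resolution
    n_dermis = max(resolution, int(np.ceil(h_dermis / (2.5 * dz_epid))))

    r_bone_out = R - h_epid - h_dermis
    r0 = r_bone_out - h_bone
    levels = np.concatenate([
        [r0],
        _radial_levels(h_bone, 1, r0),
        _radial_levels(h_dermis, n_dermis, r_bone_out),
        _radial_levels(h_epid, resolution, R - h_epid),
    ])
    layer_of_slab = np.concatenate([
        np.full(1, BONE), np.full(n_dermis, DERMIS), np.full(resolution, EPIDERMIS),
    ])

    n_inplane = max(4, int(np.round(2 * a / inplane_spacing)))
    us = np.linspace(-a, a, n_inplane + 1)

    def warp(grid):
        u, v, r = grid[:, 0], grid[:, 1], grid[:, 2]
        w = np.sqrt(R * R - u * u - v * v)
        d = np.stack([u, v, w], axis=1) / R
        return d * r[:, None]

    nodes, tets, layer, (nx, ny, nz) = structured_layered_grid(
        us, us, levels, layer_of_slab, warp=warp
    )

    nzl = nz + 1
    idx = np.arange(len(nodes))
    k = idx % nzl
    ij = idx // nzl
    j = ij % (ny + 1)
    i = ij // (ny + 1)

    n_bone_levels = 2  # bone occupies levels k in {0, 1}
    tags = np.full(len(nodes), FREE, dtype=np.int64)
    tags[k < n_bone_levels] = BONE_FIXED
    rim = ((i == 0) | (i == nx) | (j == 0) | (j == ny)) & (k >= n_bone_levels)
    tags[rim] = LATERAL

    constraint = np.tile(np.eye(3), (len(nodes), 1, 1))
    constraint[tags == BONE_FIXED] = 0.0
    # Rim nodes slide within their cut surface (spanned by the radial and
    # the along-rim directions); the cut-surface normal is removed.  For the
    # u = +/-a face the normal is prop. to (-(v^2+w^2), u v, u w), and
    # symmetrically for the v faces, with w = sqrt(R^2 - u^2 - v^2).
    u_n = us[i]
    v_n = us[j]
    w_n = np.sqrt(R * R - u_n**2 - v_n**2)
    on_x = (i == 0) | (i == nx)
    on_y = (j == 0) | (j == ny)
    nrm_x = np.stack([-(v_n**2 + w_n**2), u_n * v_n, u_n * w_n], axis=1)
    nrm_y = np.stack([u_n * v_n, -(u_n**2 + w_n**2), v_n * w_n], axis=1)
    for axis_mask, nrm in ((on_x, nrm_x), (on_y, nrm_y)):
        m = axis_mask & (tags == LATERAL)
        for node in np.where(m)[0]:
            n1 = nrm[node]
            # orthogonalise against any previously applied constraint
            n1 = constraint[node] @ n1
            norm = np.linalg.norm(n1)
            if norm > 1e-12:
                n1 /= norm
                constraint[node] -= np.outer(n1, n1)

    rng = np.random.default_rng(seed)
    nodes = _apply_jitter(nodes, constraint, tags != BONE_FIXED,
                          perturb_amplitude, rng,
                          grid_shape=(nx, ny, nz), spacing=inplane_spacing)

    centroids = nodes[tets].mean(axis=1)
    normals = centroids / np.linalg.norm(centroids, axis=1, keepdims=True)

    mesh = LayeredMesh(
        nodes=nodes, tets=tets, layer=layer, surface_normal=normals,
        boundary_tags=tags, constraint=constraint,
        metadata={
            "generator": "make_layered_cap",
            "cap_radius": R, "h_epid": h_epid, "h_dermis": h_dermis,
            "h_bone": h_bone, "half_width": a, "resolution": resolution,
            "perturb_amplitude": perturb_amplitude, "seed": seed,
            "grid_shape": (nx, ny, nz),
        },
    )
    mesh.validate()
    return mesh


def make_flat_bilayer(
    lx: float,
    ly: float,
    h_film: float,
    h_substrate: float,
    resolution: int = 2,
    perturb_amplitude: float = config.PERTURB_AMPLITUDE,
    seed: int = 0,
    expected_wavelength: float | None = None,
) -> LayeredMesh:
    """Rectangular film-on-substrate slab (wrinkling test geometry).

    The film (labelled epidermis) spans exactly ``resolution`` element layers
    in z; the substrate (labelled dermis) is graded coarser with depth.  The
    bottom face is clamped (``bone_fixed``), vertical sides slide in their own
    plane (``lateral``), and the reference surface normal is +z everywhere.
    The substrate must dwarf the film (``h_substrate >= 5 * h_film``) for
    thin-film wrinkling theory to apply.
    """
    if h_film <= 0 or h_substrate <= 0:
        raise ValueError("layer thicknesses must be positive")
    if h_substrate < 5 * h_film:
        raise ValueError("h_substrate must be >= 5 * h_film")

    dz_f = h_film / resolution
    sub_sizes = _graded_spacings(h_substrate, dz0=2 * dz_f, dz_max=2 * h_film)
    zs = np.concatenate([
        [0.0], np.cumsum(sub_sizes),
        h_substrate + np.linspace(0, h_film, resolution + 1)[1:],
    ])
    n_sub = len(sub_sizes)
    layer_of_slab = np.concatenate([
        np.full(n_sub, DERMIS), np.full(resolution, EPIDERMIS),
    ])

    nx = max(1, int(np.round(lx / h_film)))
    ny = max(1, int(np.round(ly / h_film)))
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)

    nodes, tets, layer, (nx, ny, nz) = structured_layered_grid(
        xs, ys, zs, layer_of_slab
    )

    nzl = nz + 1
    idx = np.arange(len(nodes))
    k = idx % nzl
    ij = idx // nzl
    j = ij % (ny + 1)
    i = ij // (ny + 1)

    tags = np.full(len(nodes), FREE, dtype=np.int64)
    on_x = (i == 0) | (i == nx)
    on_y = (j == 0) | (j == ny)
    tags[(on_x | on_y)] = LATERAL
    tags[k == 0] = BONE_FIXED

    constraint = np.tile(np.eye(3), (len(nodes), 1, 1))
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    for axis_mask, e in ((on_x, ex), (on_y, ey)):
        m = axis_mask & (tags == LATERAL)
        constraint[m] -= np.einsum("i,j->ij", e, e)
    constraint[tags == BONE_FIXED] = 0.0

    rng = np.random.default_rng(seed)
    nodes = _apply_jitter(nodes, constraint, tags != BONE_FIXED,
                          perturb_amplitude, rng,
                          grid_shape=(nx, ny, nz), spacing=h_film)

    normals = np.tile(np.array([0.0, 0.0, 1.0]), (len(tets), 1))

    metadata = {
        "generator": "make_flat_bilayer",
        "lx": lx, "ly": ly, "h_film": h_film, "h_substrate": h_substrate,
        "resolution": resolution, "perturb_amplitude": perturb_amplitude,
        "seed": seed, "grid_shape": (nx, ny, nz), "warnings": [],
    }
    if expected_wavelength is not None and lx < 4 * expected_wavelength:
        metadata["warnings"].append(
            f"lx={lx} is below 4x the expected wrinkle wavelength "
            f"({expected_wavelength:.3g}); the spectral peak will be "
            "mode-quantised"
        )

    mesh = LayeredMesh(
        nodes=nodes, tets=tets, layer=layer, surface_normal=normals,
        boundary_tags=tags, constraint=constraint, metadata=metadata,
    )
    mesh.validate()
    return mesh


def make_uniform_block(
    lx: float, ly: float, lz: float, spacing: float = 1.0,
    layer: int = DERMIS,
) -> LayeredMesh:
    """Fully unconstrained single-layer block (free-growth test geometry).

    No clamped or lateral nodes: under compatible uniform growth the block
    must relax to a stress-free uniformly scaled copy of itself.
    """
    nx = max(1, int(np.round(lx / spacing)))
    ny = max(1, int(np.round(ly / spacing)))
    nz = max(1, int(np.round(lz / spacing)))
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    nodes, tets, layers, shape = structured_layered_grid(
        xs, ys, zs, np.full(nz, layer)
    )
    mesh = LayeredMesh(
        nodes=nodes, tets=tets, layer=layers,
        surface_normal=np.tile(np.array([0.0, 0.0, 1.0]), (len(tets), 1)),
        boundary_tags=np.full(len(nodes), FREE, dtype=np.int64),
        constraint=np.tile(np.eye(3), (len(nodes), 1, 1)),
        metadata={"generator": "make_uniform_block", "grid_shape": shape},
    )
    mesh.validate()
    return mesh


# --------------------------------------------------------------------------
# image phantoms
# --------------------------------------------------------------------------

@dataclass
class ImagePhantom:
    """Synthetic nuclear-stain style volume with analytic ground truth.

    The tissue is a spherical dome: a bright epidermis band (dense nuclei)
    of thickness ``h_epid`` over a dim dermis band of thickness ``h_dermis``,
    resting on a bone shell recorded in ``truth_bone_mask``.  Surfaces are
    stored analytically as ``{"kind": "sphere", "center": (z, y, x),
    "radius": r}``.  Axis order is z-slowest; coordinates are voxel-centred
    and 0-based.
    """

    stack: np.ndarray
    voxel_size: float
    truth_outer_surface: dict
    truth_inner_surface: dict
    truth_cells: np.ndarray
    truth_bone_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def layer_masks(self) -> dict[str, np.ndarray]:
        """Boolean masks for epidermis / dermis from the analytic truth."""
        r = _radius_grid(self.stack.shape, self.truth_outer_surface["center"])
        r_out = self.truth_outer_surface["radius"]
        r_in = self.truth_inner_surface["radius"]
        r_bone = self.metadata["bone_outer_radius"]
        return {
            "epidermis": (r <= r_out) & (r > r_in),
            "dermis": (r <= r_in) & (r > r_bone),
        }


def _radius_grid(shape, center):
    zz, yy, xx = np.meshgrid(
        *(np.arange(s, dtype=float) for s in shape), indexing="ij"
    )
    cz, cy, cx = center
    return np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)


def make_image_phantom(
    shape: tuple[int, int, int] = (64, 96, 96),
    h_epid: float = 8.0,
    h_dermis: float = 20.0,
    n_cells: int = 0,
    noise_sd: float = 0.0,
    seed: int = 0,
    cell_radius: float = config.PHANTOM_CELL_RADIUS,
    voxel_size: float = 1.0,
) -> ImagePhantom:
    """Dome-shaped two-band phantom with labelled cells and a bone shell.

    Cells are Gaussian blobs (sigma = radius/2, constant integrated
    intensity) placed uniformly in the dermis band with pairwise separation
    strictly greater than twice the cell radius; placement failure after
    bounded retries raises with the achieved count.  Additive Gaussian noise
    (seeded) is applied last and intensities are clipped to [0, 1].
    """
    if n_cells < 0 or noise_sd < 0:
        raise ValueError("n_cells and noise_sd must be non-negative")
    nz, ny, nx = shape
    R_out = 0.75 * min(ny, nx)
    apex_z = config.PHANTOM_DOME_APEX_FRACTION * nz
    center = (apex_z - R_out, (ny - 1) / 2.0, (nx - 1) / 2.0)
    if R_out <= h_epid + h_dermis + config.PHANTOM_BONE_THICKNESS:
        raise ValueError("stack too small for the requested layer thicknesses")

    r = _radius_grid(shape, center)
    r_in = R_out - h_epid
    r_bone = r_in - h_dermis

    stack = np.zeros(shape, dtype=float)
    stack[(r <= R_out) & (r > r_in)] = config.PHANTOM_EPIDERMIS_INTENSITY
    stack[(r <= r_in) & (r > r_bone)] = config.PHANTOM_DERMIS_INTENSITY
    bone_mask = (r <= r_bone) & (r > r_bone - config.PHANTOM_BONE_THICKNESS)

    rng = np.random.default_rng(seed)
    cells = _place_cells(
        shape, r, r_bone, r_in, n_cells, cell_radius, rng
    )
    sigma = cell_radius / 2.0
    for c in cells:
        _add_blob(stack, c, sigma, config.PHANTOM_CELL_AMPLITUDE)

    if noise_sd > 0:
        stack = stack + rng.normal(0.0, noise_sd, shape)
    stack = np.clip(stack, 0.0, 1.0)

    return ImagePhantom(
        stack=stack, voxel_size=voxel_size,
        truth_outer_surface={"kind": "sphere", "center": center, "radius": R_out},
        truth_inner_surface={"kind": "sphere", "center": center, "radius": r_in},
        truth_cells=np.array(cells).reshape(-1, 3),
        truth_bone_mask=bone_mask,
        metadata={
            "h_epid": h_epid, "h_dermis": h_dermis, "n_cells": n_cells,
            "noise_sd": noise_sd, "seed": seed, "cell_radius": cell_radius,
            "bone_outer_radius": r_bone,
            "epidermis_intensity": config.PHANTOM_EPIDERMIS_INTENSITY,
            "dermis_intensity": config.PHANTOM_DERMIS_INTENSITY,
        },
    )


def _place_cells(shape, r_grid, r_bone, r_in, n_cells, cell_radius, rng):
    if n_cells == 0:
        return []
    nz, ny, nx = shape
    margin = 2.0 * cell_radius + 1.0   # keep the full blob support in-volume
    min_sep = 2.0 * cell_radius + 0.5   # strictly > 2 * radius
    cells: list[np.ndarray] = []
    attempts = 0
    max_attempts = 500 * n_cells
    while len(cells) < n_cells and attempts < max_attempts:
        attempts += 1
        p = rng.uniform(
            [margin, margin, margin], [nz - margin, ny - margin, nx - margin]
        )
        zi, yi, xi = p
        rr = r_grid[int(round(zi)), int(round(yi)), int(round(xi))]
        if not (r_bone + cell_radius < rr < r_in - cell_radius):
            continue
        if all(np.linalg.norm(p - q) > min_sep for q in cells):
            cells.append(p)
    if len(cells) < n_cells:
        raise RuntimeError(
            f"could only place {len(cells)} of {n_cells} cells with pairwise "
            f"separation > {min_sep:.1f} voxels"
        )
    return cells


def _add_blob(stack, center, sigma, amplitude):
    nz, ny, nx = stack.shape
    cz, cy, cx = center
    w = int(np.ceil(4 * sigma))
    z0, z1 = max(0, int(cz) - w), min(nz, int(cz) + w + 1)
    y0, y1 = max(0, int(cy) - w), min(ny, int(cy) + w + 1)
    x0, x1 = max(0, int(cx) - w), min(nx, int(cx) + w + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1, dtype=float),
        np.arange(y0, y1, dtype=float),
        np.arange(x0, x1, dtype=float),
        indexing="ij",
    )
    d2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
    stack[z0:z1, y0:y1, x0:x1] += amplitude * np.exp(-d2 / (2 * sigma**2))


# --------------------------------------------------------------------------
# indentation curves
# --------------------------------------------------------------------------

def make_indentation_curves(
    E_true: float,
    probe_radius: float = config.PROBE_RADIUS_UM,
    max_depth: float = config.MAX_DEPTH_UM,
    n_curves: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_samples: int = config.N_CURVE_SAMPLES,
    replicate_id: str = "rep0",
) -> list[IndentationCurve]:
    """Synthetic spherical-probe load-displacement curves.

    Each curve samples the Hertz forward model on a uniform depth grid from 0
    to ``max_depth`` (um) and applies seeded multiplicative Gaussian noise,
    ``F * (1 + noise_sd * N(0, 1))`` pointwise, which preserves ``F(0) = 0``.
    ``max_depth`` must stay well inside the small-contact regime
    (``< probe_radius / 10``).
    """
    if E_true <= 0:
        raise ValueError("E_true must be positive")
    if max_depth >= probe_radius / 10.0:
        raise ValueError(
            "max_depth must be < probe_radius / 10 (Hertz small-contact regime)"
        )
    rng = np.random.default_rng(seed)
    delta = np.linspace(0.0, max_depth, n_samples)
    f0 = hertz_force(delta, E_true, probe_radius)
    curves = []
    for c in range(n_curves):
        f = f0.copy()
        if noise_sd > 0:
            f = f * (1.0 + noise_sd * rng.standard_normal(n_samples))
        curves.append(IndentationCurve(
            displacement=delta.copy(), force=f, probe_radius=probe_radius,
            truth_modulus=E_true, curve_id=f"{replicate_id}_c{c:03d}",
            replicate_id=replicate_id,
        ))
    return curves
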
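"""Finite-strain neo-Hookean growth mechanics on layered tetrahedral meshes.

The model: observed deformation decomposes multiplicatively, ``F = F_e G``,
into a stress-free growth tensor ``G`` and an elastic accommodation ``F_e``.
Growth is transversely isotropic about each layer's reference mid-surface
normal ``n``:

    G = (1 + g_t) (I - n n^T) + (1 + g_n) n n^T

with tangential and normal growth fractions ``(g_t, g_n)`` homogeneous within
each layer.  Elasticity is compressible neo-Hookean,

    W(F_e) = mu/2 (tr(F_e^T F_e) - 3) - mu ln J_e + lam/2 (ln J_e)^2,

with Lame parameters from each layer's Young's modulus and Poisson's ratio.
The bone layer is rigid and non-growing: its nodes are clamped and its
elements carry no elastic energy.  Quasi-static equilibria are found by
damped explicit (semi-implicit Euler) relaxation with node-triangle penalty
self-contact, growth ramped linearly over a schedule of increments.

Only modulus *ratios* matter: time step, damping, contact stiffness and the
convergence test all scale with the stiffest modulus, so multiplying every
Young's modulus by a constant leaves the relaxation trajectory unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import config
from ._kernels import add_contact, assemble_elastic, relax_chunk
from .meshing import BONE, DERMIS, EPIDERMIS, FREE, LayeredMesh, boundary_faces
from .surfaces import TriSurface

logger = logging.getLogger(__name__)

__all__ = [
    "MaterialSpec", "GrowthSpec", "SimState", "SimOptions",
    "species_parameters", "lame_parameters", "growth_tensor",
    "element_response", "contact_forces", "step", "simulate",
    "free_surface", "SPECIES_TABLE",
]


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

def lame_parameters(E: float, nu: float) -> tuple[float, float]:
    """Lame parameters (mu, lam) from Young's modulus and Poisson's ratio."""
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not (0 <= nu < 0.5):
        raise ValueError(
            "Poisson's ratio must satisfy 0 <= nu < 0.5 "
            "(the incompressible limit is unsupported)"
        )
    mu = E / (2.0 * (1.0 + nu))
    lam = E * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu, lam


@dataclass(frozen=True)
class MaterialSpec:
    """Per-layer elastic constants (relative units; only ratios matter)."""

    E_epid: float
    E_dermis: float
    nu_epid: float
    nu_dermis: float

    def __post_init__(self):
        lame_parameters(self.E_epid, self.nu_epid)
        lame_parameters(self.E_dermis, self.nu_dermis)

    def lame(self, layer: int) -> tuple[float, float]:
        if layer == EPIDERMIS:
            return lame_parameters(self.E_epid, self.nu_epid)
        if layer == DERMIS:
            return lame_parameters(self.E_dermis, self.nu_dermis)
        raise ValueError("bone is rigid: it has no material constants")

    def scaled(self, factor: float) -> "MaterialSpec":
        return replace(self, E_epid=self.E_epid * factor,
                       E_dermis=self.E_dermis * factor)


@dataclass(frozen=True)
class GrowthSpec:
    """Final tangential/normal growth fractions per skin layer.

    Growth is relative to the rigid, non-growing bone layer.  Ramped
    linearly from zero over ``ramp_steps`` increments.
    """

    gT_epid: float
    gN_epid: float
    gT_dermis: float
    gN_dermis: float
    ramp_steps: int = config.RAMP_STEPS
    # multiplicative stochastic spatial fluctuation of the growth field:
    # g(x) = g * (1 + eta(x)), eta smooth with the stated RMS and correlation
    # length, seeded from SimOptions.seed; identically zero when g is zero
    noise_amplitude: float = config.GROWTH_NOISE_AMPLITUDE
    noise_correlation: float = config.GROWTH_NOISE_CORRELATION

    def __post_init__(self):
        for g in (self.gT_epid, self.gN_epid, self.gT_dermis, self.gN_dermis):
            if 1.0 + g <= 0:
                raise ValueError("growth fractions must satisfy 1 + g > 0")
        if self.ramp_steps < 1:
            raise ValueError("ramp_steps must be >= 1")

    def of_layer(self, layer: int) -> tuple[float, float]:
        if layer == EPIDERMIS:
            return self.gT_epid, self.gN_epid
        if layer == DERMIS:
            return self.gT_dermis, self.gN_dermis
        if layer == BONE:
            return 0.0, 0.0
        raise ValueError(f"unknown layer code {layer}")


#: Mechanical parameter sets for the three tortoise species: Young's moduli
#: (E_epid, E_dermis), Poisson's ratios, and final tangential/normal growth
#: for epidermis and dermis, growth normalised to the rigid bone.
SPECIES_TABLE: dict[str, tuple[MaterialSpec, GrowthSpec]] = {
    "sulcata": (
        MaterialSpec(E_epid=3.0, E_dermis=1.0, nu_epid=0.10, nu_dermis=0.40),
        GrowthSpec(gT_epid=0.60, gN_epid=0.0, gT_dermis=0.60, gN_dermis=0.30),
    ),
    "graeca": (
        MaterialSpec(E_epid=2.0, E_dermis=1.0, nu_epid=0.25, nu_dermis=0.45),
        GrowthSpec(gT_epid=0.50, gN_epid=0.0, gT_dermis=0.70, gN_dermis=0.10),
    ),
    "marginata": (
        MaterialSpec(E_epid=2.0, E_dermis=1.0, nu_epid=0.25, nu_dermis=0.45),
        GrowthSpec(gT_epid=0.45, gN_epid=0.0, gT_dermis=0.70, gN_dermis=0.10),
    ),
}


def species_parameters(species: str) -> tuple[MaterialSpec, GrowthSpec]:
    """Elastic and growth parameters for a named tortoise species."""
    try:
        return SPECIES_TABLE[species]
    except KeyError:
        valid = ", ".join(sorted(SPECIES_TABLE))
        raise ValueError(f"unknown species {species!r}; valid names: {valid}")


@dataclass
class SimOptions:
    """Numerical controls of the quasi-static relaxation.

    Time step and damping are derived from the stiffest element (explicit
    stability bound with safety ``dt_safety``; drag at ``damping_zeta`` times
    the stiffest element frequency), so they need no manual tuning and are
    invariant to a global rescaling of the moduli.
    """

    dt_safety: float = config.DT_SAFETY
    damping_zeta: float = config.DAMPING_ZETA
    contact_stiffness: float = config.CONTACT_STIFFNESS
    contact_radius: float = config.CONTACT_RADIUS
    contact_refresh: int = config.CONTACT_REFRESH
    contact_exclusion: float = config.CONTACT_EXCLUSION
    tol: float = config.RESIDUAL_TOL
    max_steps_per_increment: int = config.MAX_STEPS_PER_INCREMENT
    final_relax_steps: int = config.FINAL_RELAX_STEPS
    snapshot_every: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("dt_safety", "damping_zeta", "contact_stiffness",
                     "contact_radius", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("contact_refresh", "max_steps_per_increment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SimState:
    """Evolving state of a growth simulation."""

    mesh: LayeredMesh
    positions: np.ndarray
    velocities: np.ndarray
    growth_fraction: float = 0.0
    time: float = 0.0
    growth_tensors: np.ndarray | None = None   # (n_elastic, 3, 3)

    @classmethod
    def initial(cls, mesh: LayeredMesh) -> "SimState":
        return cls(
            mesh=mesh,
            positions=mesh.nodes.copy(),
            velocities=np.zeros_like(mesh.nodes),
        )


# --------------------------------------------------------------------------
# element-level operations (reference numpy implementations)
# --------------------------------------------------------------------------

def growth_tensor(normal: np.ndarray, g_t: float, g_n: float) -> np.ndarray:
    """Transversely isotropic growth tensor about a unit normal.

    ``G = (1 + g_t)(I - n n^T) + (1 + g_n) n n^T``; symmetric positive
    definite with ``det G = (1 + g_t)^2 (1 + g_n)``.
    """
    n = np.asarray(normal, dtype=float)
    if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-8):
        raise ValueError("growth normal must be a unit vector")
    if 1.0 + g_t <= 0 or 1.0 + g_n <= 0:
        raise ValueError("growth fractions must satisfy 1 + g > 0")
    nn = np.outer(n, n)
    return (1.0 + g_t) * (np.eye(3) - nn) + (1.0 + g_n) * nn


def element_response(
    ref_nodes: np.ndarray,
    cur_nodes: np.ndarray,
    G: np.ndarray,
    mu: float,
    lam: float,
) -> tuple[float, np.ndarray]:
    """Energy and exact nodal forces of one grown neo-Hookean tetrahedron.

    ``ref_nodes`` and ``cur_nodes`` are (4, 3).  The element energy is
    ``W(F_e) * V_ref * det G`` (energy density integrated over the grown
    stress-free volume) and forces are the analytic negative gradient with
    respect to the current nodal positions.
    """
    X = np.asarray(ref_nodes, dtype=float)
    x = np.asarray(cur_nodes, dtype=float)
    Dm = (X[1:] - X[0]).T
    vref = np.linalg.det(Dm) / 6.0
    if vref <= 0:
        raise ValueError("reference tetrahedron is degenerate or inverted")
    Bm = np.linalg.inv(Dm)
    Ds = (x[1:] - x[0]).T
    F = Ds @ Bm
    Ginv = np.linalg.inv(G)
    Fe = F @ Ginv
    Je = np.linalg.det(Fe)
    if Je <= 0:
        raise FloatingPointError("element inverted: det F_e <= 0")
    lnJ = np.log(Je)
    FeInvT = np.linalg.inv(Fe).T
    W = 0.5 * mu * ((Fe * Fe).sum() - 3.0) - mu * lnJ + 0.5 * lam * lnJ**2
    vg = vref * np.linalg.det(G)
    energy = W * vg
    P = mu * (Fe - FeInvT) + lam * lnJ * FeInvT
    H = vg * (P @ Ginv.T) @ Bm.T          # column c = dE/d x_{c+1}
    forces = np.empty((4, 3))
    forces[1:] = -H.T
    forces[0] = H.sum(axis=1)
    return float(energy), forces


# --------------------------------------------------------------------------
# assembly preparation
# --------------------------------------------------------------------------

@dataclass
class _Prep:
    """Precomputed per-element arrays for the elastic (non-bone) mesh."""

    tets: np.ndarray            # (me, 4) elastic tets
    Bm: np.ndarray              # (me, 3, 3)
    vref: np.ndarray            # (me,)
    mu: np.ndarray
    lam: np.ndarray
    normals: np.ndarray         # (me, 3)
    g_final: np.ndarray         # (me, 2) tangential, normal growth
    e_scale: float              # max(lam + 2 mu)
    dt: float
    damping: float
    surface_faces: np.ndarray   # contact candidate faces (outer free surface)
    surface_nodes: np.ndarray
    ref_positions: np.ndarray
    h_min: float


def _characteristic_lengths(nodes, tets, vols):
    """Minimum altitude of each tet: 3 V / max face area."""
    p = nodes[tets]
    areas = np.empty((len(tets), 4))
    for face, (a, b, c) in enumerate(
        [(1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1)]
    ):
        cr = np.cross(p[:, b] - p[:, a], p[:, c] - p[:, a])
        areas[:, face] = 0.5 * np.linalg.norm(cr, axis=1)
    return 3.0 * vols / areas.max(axis=1)


def _prepare(mesh: LayeredMesh, material: MaterialSpec, growth: GrowthSpec,
             options: SimOptions) -> _Prep:
    elastic = mesh.layer != BONE
    tets = np.ascontiguousarray(mesh.tets[elastic])
    layer = mesh.layer[elastic]
    normals = np.ascontiguousarray(mesh.surface_normal[elastic])

    p = mesh.nodes[tets]
    Dm = np.transpose(p[:, 1:] - p[:, :1], (0, 2, 1))
    vref = np.linalg.det(Dm) / 6.0
    if not (vref > 0).all():
        raise ValueError("mesh contains degenerate or inverted elastic tets")
    Bm = np.ascontiguousarray(np.linalg.inv(Dm))

    mu = np.empty(len(tets))
    lam = np.empty(len(tets))
    g_final = np.empty((len(tets), 2))
    for code in (DERMIS, EPIDERMIS):
        m = layer == code
        mu_c, lam_c = material.lame(code)
        mu[m] = mu_c
        lam[m] = lam_c
        g_final[m] = growth.of_layer(code)

    e_scale = float((lam + 2 * mu).max())
    h = _characteristic_lengths(mesh.nodes, tets, vref)
    # explicit stability: dt <= alpha * h * sqrt(rho / (lam + 2 mu)), rho = 1
    dt_e = h / np.sqrt(lam + 2 * mu)
    dt = options.dt_safety * float(dt_e.min())
    h_min = float(h.min())
    # overdamped drag tied to the stiffest element frequency
    damping = options.damping_zeta * np.sqrt(e_scale) / h_min

    faces = boundary_faces(tets)
    all_free = (mesh.boundary_tags[faces] == FREE).all(axis=1)
    surface_faces = np.ascontiguousarray(faces[all_free])
    surface_nodes = np.unique(surface_faces)

    return _Prep(
        tets=tets, Bm=Bm, vref=vref, mu=mu, lam=lam, normals=normals,
        g_final=np.ascontiguousarray(g_final), e_scale=e_scale, dt=dt,
        damping=damping, surface_faces=surface_faces,
        surface_nodes=surface_nodes, ref_positions=mesh.nodes.copy(),
        h_min=h_min,
    )


def _growth_noise_field(mesh_nodes: np.ndarray, tets: np.ndarray,
                        amplitude: float, correlation: float,
                        seed: int) -> np.ndarray:
    """Smooth per-element fluctuation field eta with unit-free RMS amplitude.

    Seeded white noise on element centroids, kernel-smoothed over the given
    correlation length and rescaled to the requested RMS.
    """
    if amplitude <= 0:
        return np.zeros(len(tets))
    centroids = mesh_nodes[tets].mean(axis=1)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(len(tets))
    tree = cKDTree(centroids)
    pairs = tree.query_ball_point(centroids, r=2.0 * correlation)
    eta = np.empty(len(tets))
    c2 = 2.0 * correlation**2
    for e, nbrs in enumerate(pairs):
        nbrs = np.asarray(nbrs)
        d2 = ((centroids[nbrs] - centroids[e]) ** 2).sum(axis=1)
        w = np.exp(-d2 / c2)
        eta[e] = (w * white[nbrs]).sum() / np.sqrt((w**2).sum())
    rms = np.sqrt((eta**2).mean())
    return eta / max(rms, 1e-30) * amplitude


def _growth_arrays(prep: _Prep, fraction: float,
                   noise: np.ndarray | None = None):
    """Per-element G^{-1} and grown volumes at a ramp fraction."""
    factor = 1.0 if noise is None else 1.0 + noise
    gt = fraction * prep.g_final[:, 0] * factor
    gn = fraction * prep.g_final[:, 1] * factor
    n = prep.normals
    nn = np.einsum("ei,ej->eij", n, n)
    eye = np.eye(3)[None, :, :]
    G = (1 + gt)[:, None, None] * (eye - nn) + (1 + gn)[:, None, None] * nn
    Ginv = (1 / (1 + gt))[:, None, None] * (eye - nn) \
        + (1 / (1 + gn))[:, None, None] * nn
    detG = (1 + gt) ** 2 * (1 + gn)
    vg = prep.vref * detG
    return G, np.ascontiguousarray(Ginv), vg


def _lumped_mass(n_nodes: int, tets: np.ndarray, vg: np.ndarray) -> np.ndarray:
    mass = np.zeros(n_nodes)
    for c in range(4):
        np.add.at(mass, tets[:, c], vg / 4.0)
    return mass


def _contact_pairs(positions, prep: _Prep, options: SimOptions):
    """Candidate node-triangle pairs within reach of the penalty.

    Pairs are excluded when the node belongs to the triangle or when the two
    are reference-space neighbours (distance below ``contact_exclusion``):
    the penalty handles *self*-contact of distant surface patches, not the
    local surface stiffness.
    """
    faces = prep.surface_faces
    if len(faces) == 0:
        return (np.empty(0, dtype=np.int64), np.empty((0, 3), dtype=np.int64))
    centroids = positions[faces].mean(axis=1)
    tree = cKDTree(centroids)
    search = 2.0 * options.contact_radius
    node_ids = prep.surface_nodes
    neighbor_lists = tree.query_ball_point(positions[node_ids], r=search)
    counts = np.fromiter((len(l) for l in neighbor_lists), dtype=np.int64,
                         count=len(neighbor_lists))
    if counts.sum() == 0:
        return (np.empty(0, dtype=np.int64), np.empty((0, 3), dtype=np.int64))
    nodes_rep = np.repeat(node_ids, counts)
    tri_ids = np.fromiter(
        (t for l in neighbor_lists for t in l), dtype=np.int64,
        count=int(counts.sum()),
    )
    f = faces[tri_ids]
    ref = prep.ref_positions
    ref_centroids = ref[faces].mean(axis=1)
    dref = ref[nodes_rep] - ref_centroids[tri_ids]
    keep = ((nodes_rep != f[:, 0]) & (nodes_rep != f[:, 1])
            & (nodes_rep != f[:, 2])
            & ((dref * dref).sum(axis=1) >= options.contact_exclusion**2))
    if not keep.any():
        return (np.empty(0, dtype=np.int64), np.empty((0, 3), dtype=np.int64))
    return (np.ascontiguousarray(nodes_rep[keep]),
            np.ascontiguousarray(f[keep]))


# --------------------------------------------------------------------------
# public force / stepping operations
# --------------------------------------------------------------------------

def contact_forces(state: SimState, options: SimOptions | None = None,
                   material: MaterialSpec | None = None) -> np.ndarray:
    """Self-contact penalty force field for the current configuration.

    Penalty stiffness is ``options.contact_stiffness`` times the stiffest
    P-wave modulus (or 1 if no material is given, i.e. unit moduli).
    """
    options = options or SimOptions()
    mesh = state.mesh
    elastic = mesh.layer != BONE
    tets = mesh.tets[elastic]
    faces = boundary_faces(tets)
    all_free = (mesh.boundary_tags[faces] == FREE).all(axis=1)
    prep_like = _Prep(
        tets=tets, Bm=None, vref=None, mu=None, lam=None, normals=None,
        g_final=None, e_scale=1.0, dt=0.0, damping=0.0,
        surface_faces=np.ascontiguousarray(faces[all_free]),
        surface_nodes=np.unique(faces[all_free]),
        ref_positions=mesh.nodes, h_min=1.0,
    )
    e_scale = 1.0
    if material is not None:
        e_scale = max(sum(material.lame(c)) + material.lame(c)[0]
                      for c in (DERMIS, EPIDERMIS))
    k_con = options.contact_stiffness * e_scale
    pn, pt = _contact_pairs(state.positions, prep_like, options)
    forces = np.zeros_like(state.positions)
    pos = np.ascontiguousarray(state.positions)
    add_contact(pos, pn, pt, k_con, options.contact_radius, forces)
    return forces


def step(state: SimState, forces: np.ndarray, options: SimOptions,
         dt: float, damping: float, mass: np.ndarray) -> SimState:
    """One damped semi-implicit Euler update (reference implementation).

    ``v <- (v + dt f / m)(1 - c dt)`` projected onto each node's admissible
    subspace, then ``x <- x + dt v``.  Clamped (bone) nodes never move.
    """
    if not np.isfinite(forces).all():
        raise FloatingPointError(
            f"non-finite forces encountered (dt={dt:.3e}); the explicit "
            "step is unstable for the stiffest element"
        )
    decay = max(0.0, 1.0 - damping * dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        acc = np.where(mass[:, None] > 0, forces / mass[:, None], 0.0)
    v = (state.velocities + dt * acc) * decay
    v = np.einsum("nij,nj->ni", state.mesh.constraint, v)
    return SimState(
        mesh=state.mesh,
        positions=state.positions + dt * v,
        velocities=v,
        growth_fraction=state.growth_fraction,
        time=state.time + dt,
        growth_tensors=state.growth_tensors,
    )


# --------------------------------------------------------------------------
# the simulation driver
# --------------------------------------------------------------------------

def simulate(
    mesh: LayeredMesh,
    material: MaterialSpec,
    growth: GrowthSpec,
    options: SimOptions | None = None,
) -> tuple[SimState, list[tuple[float, np.ndarray]], pd.DataFrame]:
    """Quasi-static growth simulation.

    Growth ramps linearly from zero to the final per-layer values over
    ``growth.ramp_steps`` increments; after each increment the state is
    relaxed until the constraint-projected residual force maximum drops
    below ``options.tol * E_scale`` (per unit reference area) or the step
    budget is exhausted, whichever comes first.  A final extra relaxation
    runs after the last increment.

    Returns ``(final_state, snapshots, diagnostics)`` where snapshots are
    ``(growth_fraction, positions)`` copies taken every
    ``options.snapshot_every`` increments and diagnostics is one row per
    increment (residual, energies, min elastic Jacobian, step count).

    Element inversion or a numerical blow-up aborts the ramp and returns the
    partial trajectory with the failure recorded in the diagnostics and in
    ``state``'s metadata-free return; inspect ``diagnostics['failed']``.
    """
    options = options or SimOptions()
    prep = _prepare(mesh, material, growth, options)
    logger.info(
        "simulate: %d elastic tets, dt=%.3e, damping=%.3e, E_scale=%.3g",
        len(prep.tets), prep.dt, prep.damping, prep.e_scale,
    )

    pos = np.ascontiguousarray(mesh.nodes.copy())
    vel = np.zeros_like(pos)
    forces = np.zeros_like(pos)
    constraint = np.ascontiguousarray(mesh.constraint)
    k_con = options.contact_stiffness * prep.e_scale
    ftol = options.tol * prep.e_scale
    dt, damping = prep.dt, prep.damping

    rows = []
    snapshots: list[tuple[float, np.ndarray]] = []
    failed = False
    G = None

    noise = _growth_noise_field(
        mesh.nodes, prep.tets, growth.noise_amplitude,
        growth.noise_correlation, options.seed,
    )

    for inc in range(1, growth.ramp_steps + 1):
        fraction = inc / growth.ramp_steps
        G, Ginv, vg = _growth_arrays(prep, fraction, noise)
        mass = _lumped_mass(len(pos), prep.tets, vg)
        budget = options.max_steps_per_increment
        if inc == growth.ramp_steps:
            budget += options.final_relax_steps
        taken = 0
        res = np.inf
        en = cen = 0.0
        min_je = np.nan
        max_speed = 0.0
        while taken < budget:
            pn, pt = _contact_pairs(pos, prep, options)
            chunk = min(options.contact_refresh, budget - taken)
            (s, res, min_je, en, cen, max_speed, inverted) = relax_chunk(
                pos, vel, prep.tets, prep.Bm, Ginv, vg, prep.mu, prep.lam,
                mass, constraint, pn, pt, k_con, options.contact_radius,
                dt, damping, chunk, ftol, forces,
            )
            taken += s
            if inverted or not np.isfinite(res):
                failed = True
                logger.error(
                    "increment %d: element inversion or blow-up "
                    "(min J_e=%.3g, dt=%.3e)", inc, min_je, dt,
                )
                break
            if s < chunk:      # converged inside the chunk
                break
        rows.append({
            "increment": inc, "growth_fraction": fraction, "steps": taken,
            "residual": res / prep.e_scale, "elastic_energy": en,
            "contact_energy": cen, "max_speed": max_speed, "min_Je": min_je,
            "converged": res < ftol, "failed": failed,
        })
        if failed:
            break
        if inc % options.snapshot_every == 0 or inc == growth.ramp_steps:
            snapshots.append((fraction, pos.copy()))

    diagnostics = pd.DataFrame(rows)
    diagnostics.attrs.update({
        "dt": dt, "damping": damping, "e_scale": prep.e_scale,
        "energy_model": "compressible neo-Hookean: "
                        "W = mu/2 (I1 - 3) - mu ln Je + lam/2 (ln Je)^2",
        "integration": "damped semi-implicit Euler, linear growth ramp",
        "n_elastic_tets": int(len(prep.tets)),
    })
    state = SimState(
        mesh=mesh, positions=pos, velocities=vel,
        growth_fraction=float(diagnostics["growth_fraction"].iloc[-1]),
        time=float(diagnostics["steps"].sum()) * dt,
        growth_tensors=G,
    )
    return state, snapshots, diagnostics


def total_elastic_energy(
    mesh: LayeredMesh, positions: np.ndarray, material: MaterialSpec,
    growth: GrowthSpec, fraction: float = 1.0, seed: int = 0,
) -> float:
    """Total neo-Hookean energy of a configuration at a given ramp fraction.

    ``seed`` must match the simulation's ``SimOptions.seed`` so the growth
    fluctuation field is reproduced.
    """
    options = SimOptions()
    prep = _prepare(mesh, material, growth, options)
    noise = _growth_noise_field(mesh.nodes, prep.tets, growth.noise_amplitude,
                                growth.noise_correlation, seed)
    _, Ginv, vg = _growth_arrays(prep, fraction, noise)
    forces = np.zeros_like(positions)
    en, min_je = assemble_elastic(
        np.ascontiguousarray(positions), prep.tets, prep.Bm, Ginv, vg,
        prep.mu, prep.lam, forces,
    )
    if min_je <= 0:
        raise FloatingPointError("configuration contains inverted elements")
    return float(en)


def free_surface(mesh: LayeredMesh,
                 positions: np.ndarray | None = None) -> TriSurface:
    """Outward-oriented triangulation of the deformable outer skin surface.

    Boundary faces of the elastic (non-bone) mesh whose three nodes are all
    tagged free: the clamped bone interface and the lateral rim (plus the
    one-face margin touching it) are excluded.  Vertex indices are
    compacted; the original mesh node ids are kept in
    ``metadata['source_nodes']``.
    """
    pos = mesh.nodes if positions is None else positions
    faces = boundary_faces(mesh.tets[mesh.layer != BONE])
    keep = (mesh.boundary_tags[faces] == FREE).all(axis=1)
    faces = faces[keep]
    used, inv = np.unique(faces, return_inverse=True)
    surf = TriSurface(
        vertices=pos[used], faces=inv.reshape(-1, 3),
        metadata={"source_nodes": used},
    )
    return surf
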
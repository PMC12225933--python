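"""Simulation-level mechanics: stepping, relaxation, contact, invariances."""

import numpy as np
import pytest

from dermafold import mechanics as mech
from dermafold import synthetic as syn
from dermafold.meshing import signed_volumes


def _no_noise(growth: mech.GrowthSpec, **overrides) -> mech.GrowthSpec:
    from dataclasses import replace

    return replace(growth, noise_amplitude=0.0, **overrides)


class TestStep:
    def test_equilibrium_fixed_point(self, unit_cube_mesh):
        state = mech.SimState.initial(unit_cube_mesh)
        mass = np.ones(unit_cube_mesh.n_nodes)
        new = mech.step(state, np.zeros_like(state.positions),
                        mech.SimOptions(), dt=0.01, damping=1.0, mass=mass)
        assert np.array_equal(new.positions, state.positions)
        assert np.array_equal(new.velocities, state.velocities)

    def test_overdamped_decay_is_monotone(self):
        """Linear spring toward the origin: displacement decays without
        overshoot when the drag dominates (scalar damped-oscillator law)."""
        mesh = syn.make_uniform_block(1, 1, 1, spacing=1.0)
        state = mech.SimState.initial(mesh)
        state.positions = state.positions + np.array([0.1, 0.0, 0.0])
        mass = np.ones(mesh.n_nodes)
        k, c, dt = 1.0, 5.0, 0.1          # overdamped: c > 2 sqrt(k)
        disp = []
        for _ in range(700):
            forces = -k * (state.positions - mesh.nodes)
            state = mech.step(state, forces, mech.SimOptions(), dt=dt,
                              damping=c, mass=mass)
            disp.append(np.abs(state.positions - mesh.nodes).max())
        disp = np.array(disp)
        assert disp[-1] < 1e-3 * disp[0]
        assert (np.diff(disp) <= 1e-12).all()

    def test_clamped_nodes_never_move(self):
        mesh = syn.make_flat_bilayer(4, 4, 1, 6, seed=0)
        state = mech.SimState.initial(mesh)
        forces = np.ones_like(state.positions)
        mass = np.ones(mesh.n_nodes)
        state = mech.step(state, forces, mech.SimOptions(), dt=0.1,
                          damping=0.1, mass=mass)
        clamped = mesh.boundary_tags == 1
        assert np.array_equal(state.positions[clamped],
                              mesh.nodes[clamped])

    def test_nan_forces_raise(self, unit_cube_mesh):
        state = mech.SimState.initial(unit_cube_mesh)
        bad = np.full_like(state.positions, np.nan)
        with pytest.raises(FloatingPointError, match="dt"):
            mech.step(state, bad, mech.SimOptions(), dt=0.1, damping=0.1,
                      mass=np.ones(unit_cube_mesh.n_nodes))


class TestFreeGrowth:
    def test_zero_growth_identity(self):
        mesh = syn.make_uniform_block(2, 2, 2, spacing=1.0)
        mat = mech.MaterialSpec(3, 1, 0.1, 0.4)
        gro = mech.GrowthSpec(0, 0, 0, 0, ramp_steps=2, noise_amplitude=0.0)
        st, _, diag = mech.simulate(mesh, mat, gro, mech.SimOptions(seed=0))
        assert np.abs(st.positions - mesh.nodes).max() < 1e-9

    def test_compatible_growth_relaxes_to_det_g_volume(self):
        """Unconstrained block under uniform growth: stress-free scaling
        with volume ratio det G = (1+gt)^2 (1+gn)."""
        mesh = syn.make_uniform_block(3, 3, 3, spacing=0.75)
        mat = mech.MaterialSpec(3, 1, 0.1, 0.4)
        gro = mech.GrowthSpec(0.6, 0.0, 0.6, 0.3, ramp_steps=5,
                              noise_amplitude=0.0)
        opts = mech.SimOptions(seed=0, tol=1e-6,
                               max_steps_per_increment=2000,
                               final_relax_steps=6000)
        st, _, diag = mech.simulate(mesh, mat, gro, opts)
        ratio = (signed_volumes(st.positions, mesh.tets).sum()
                 / mesh.total_volume())
        assert ratio == pytest.approx(1.6**2 * 1.3, rel=0.01)
        mu_d, _ = mat.lame(1)
        energy = mech.total_elastic_energy(mesh, st.positions, mat, gro)
        assert energy < 1e-8 * mu_d * mesh.total_volume()


class TestContact:
    @staticmethod
    def _two_sheet_state(gap: float, gap_ref: float = 5.0):
        """Two thin slabs far apart in the reference, pushed together so the
        current surface-to-surface gap along z is ``gap``."""
        a = syn.make_uniform_block(4, 4, 0.5, spacing=0.5)
        b = syn.make_uniform_block(4, 4, 0.5, spacing=0.5)
        nodes = np.vstack([a.nodes,
                           b.nodes + np.array([0, 0, 0.5 + gap_ref])])
        tets = np.vstack([a.tets, b.tets + a.n_nodes])
        import dermafold.meshing as mm

        mesh = mm.LayeredMesh(
            nodes=nodes, tets=tets,
            layer=np.concatenate([a.layer, b.layer]),
            surface_normal=np.vstack([a.surface_normal, b.surface_normal]),
            boundary_tags=np.zeros(len(nodes), dtype=np.int64),
            constraint=np.tile(np.eye(3), (len(nodes), 1, 1)),
        )
        state = mech.SimState.initial(mesh)
        state.positions = state.positions.copy()
        state.positions[a.n_nodes:, 2] -= gap_ref - gap
        return state, a.n_nodes

    def test_separated_sheets_no_force(self):
        state, _ = self._two_sheet_state(gap=2.0)
        f = mech.contact_forces(state, mech.SimOptions())
        assert np.abs(f).max() == 0.0

    def test_overlapping_sheets_repel_and_conserve_momentum(self):
        state, n_a = self._two_sheet_state(gap=0.2)  # inside contact radius
        f = mech.contact_forces(state, mech.SimOptions())
        assert np.abs(f).max() > 0
        # net force on the pair vanishes; sheets are pushed apart along z
        assert np.abs(f.sum(axis=0)).max() < 1e-10
        assert f[:n_a, 2].sum() < 0
        assert f[n_a:, 2].sum() > 0

    def test_force_vanishes_continuously_at_radius(self):
        opts = mech.SimOptions()
        r = opts.contact_radius
        mags = []
        for gap in (0.9 * r, 0.999 * r):
            state, _ = self._two_sheet_state(gap=gap)
            mags.append(np.abs(mech.contact_forces(state, opts)).max())
        # penalty magnitude ~ (r - gap): shrinks ~100x as the gap closes
        # on the detection radius
        assert 0 < mags[1] < 0.05 * mags[0]

    def test_smooth_cap_has_no_self_contact(self, small_cap):
        state = mech.SimState.initial(small_cap)
        f = mech.contact_forces(state, mech.SimOptions())
        assert np.abs(f).max() == 0.0


class TestInvariances:
    def test_stiffness_scale_invariance(self, small_cap):
        """Multiplying all moduli by 10 leaves the converged geometry
        unchanged: only modulus ratios matter."""
        mat, gro = mech.species_parameters("sulcata")
        gro = _no_noise(gro, ramp_steps=5)
        opts = mech.SimOptions(seed=3, max_steps_per_increment=400,
                               final_relax_steps=1000)
        st1, _, _ = mech.simulate(small_cap, mat, gro, opts)
        st2, _, _ = mech.simulate(small_cap, mat.scaled(10.0), gro, opts)
        assert np.abs(st1.positions - st2.positions).max() < 1e-6

    def test_determinism_bit_identical(self, small_cap):
        mat, gro = mech.species_parameters("sulcata")
        from dataclasses import replace

        gro = replace(gro, ramp_steps=3)
        opts = mech.SimOptions(seed=5, max_steps_per_increment=200,
                               final_relax_steps=200)
        st1, snaps1, diag1 = mech.simulate(small_cap, mat, gro, opts)
        st2, snaps2, diag2 = mech.simulate(small_cap, mat, gro, opts)
        assert np.array_equal(st1.positions, st2.positions)
        assert diag1.equals(diag2)
        for (f1, p1), (f2, p2) in zip(snaps1, snaps2):
            assert f1 == f2 and np.array_equal(p1, p2)

    def test_energy_monotone_at_fixed_growth_overdamped(self):
        """With growth frozen and heavy drag, relaxation only dissipates."""
        mesh = syn.make_uniform_block(2, 2, 2, spacing=1.0)
        mat = mech.MaterialSpec(3, 1, 0.1, 0.4)
        gro = mech.GrowthSpec(0.3, 0.1, 0.3, 0.1, ramp_steps=1,
                              noise_amplitude=0.0)
        prep = mech._prepare(mesh, mat, gro, mech.SimOptions())
        _, Ginv, vg = mech._growth_arrays(prep, 1.0)
        from dermafold._kernels import relax_chunk

        pos = np.ascontiguousarray(mesh.nodes.copy())
        vel = np.zeros_like(pos)
        forces = np.zeros_like(pos)
        mass = mech._lumped_mass(len(pos), prep.tets, vg)
        dt = prep.dt
        damp = 50.0 * prep.damping     # strongly overdamped
        energies = []
        empty_n = np.empty(0, dtype=np.int64)
        empty_t = np.empty((0, 3), dtype=np.int64)
        for _ in range(60):
            _, _, _, en, cen, _, _ = relax_chunk(
                pos, vel, prep.tets, prep.Bm, Ginv, vg, prep.mu, prep.lam,
                mass, np.ascontiguousarray(mesh.constraint),
                empty_n, empty_t, 0.0, 0.0, dt, damp, 10, 0.0, forces)
            energies.append(en + cen)
        diffs = np.diff(energies)
        assert (diffs <= 1e-10 * max(energies)).all()

    def test_nonconvergence_is_reported_not_raised(self, small_cap):
        mat, gro = mech.species_parameters("sulcata")
        gro = _no_noise(gro, ramp_steps=2)
        opts = mech.SimOptions(seed=1, tol=1e-12,
                               max_steps_per_increment=20,
                               final_relax_steps=0)
        _, _, diag = mech.simulate(small_cap, mat, gro, opts)
        assert not diag["converged"].all()
        assert not diag["failed"].any()
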
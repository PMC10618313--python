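"""Potential terms: printed values, limits, and exact force gradients."""
import numpy as np
import pytest

import dsbsim as ds
from dsbsim.forcefield import TabulatedPotential, Tables
from conftest import fd_force_check


class TestScalarTerms:
    def test_bond_minimum(self):
        v, f = ds.bond_energy(3.8)
        assert v == 0.0 and f == 0.0

    def test_bond_one_angstrom_stretch(self):
        # V = k (r - r_b)^2 with k = 50 ε Å⁻² (no ½ prefactor)
        v, _ = ds.bond_energy(4.8)
        assert v == pytest.approx(50.0)

    @pytest.mark.parametrize("r,expected", [
        (5.0, 0.0),                  # evaluates to ε(1-2+1) at the cutoff
        (6.0, 0.0),                  # identically zero beyond r_o
        (5.0 / 2 ** (1 / 6), 1.0),   # (r0/r)^6 = 2
    ])
    def test_excluded_volume_examples(self, r, expected):
        assert ds.excluded_volume(r) == pytest.approx(expected, abs=1e-12)

    def test_excluded_volume_continuous_at_cutoff(self):
        eps = 1e-7
        assert ds.excluded_volume(5.0 - eps) < 1e-5
        assert ds.excluded_volume(5.0 + eps) == 0.0

    def test_contact_well_minimum_and_decay(self):
        assert ds.contact_well(6.8, 6.8) == pytest.approx(-1.0)
        assert ds.contact_well(5.0, 5.0, depth=4.0) == pytest.approx(-4.0)
        assert abs(ds.contact_well(500.0, 5.0)) < 1e-10

    def test_debye_huckel_zero_charge_and_sign(self):
        assert ds.debye_huckel(5.0, 0.0, 1.0) == 0.0
        assert ds.debye_huckel(5.0, 1.0, 1.0) > 0.0
        assert ds.debye_huckel(5.0, -1.0, 1.0) < 0.0

    def test_debye_huckel_distance_dependent_permittivity(self):
        # with eps_r ∝ r the Coulomb factor is 1/r², so
        # V(2r)/V(r) = (1/4)·exp(-r/λ_D)
        p = ds.ModelParams()
        r = 6.0
        ratio = ds.debye_huckel(2 * r, 1, 1, p) / ds.debye_huckel(r, 1, 1, p)
        assert ratio == pytest.approx(0.25 * np.exp(-r / p.debye_length))

    def test_wall_repulsion_at_sigma(self):
        assert ds.wall_potential(5.0) == pytest.approx(1.0 / 9.0)
        assert ds.wall_potential(500.0) < 1e-10

    def test_adhesive_wall_depth(self):
        # completed switching (λ=1): full 6-12 well, -4ε at the minimum
        assert ds.wall_potential(5.0, adhesive=True, lam=1.0) == \
            pytest.approx(-4.0)

    def test_wall_rejects_crossing(self):
        with pytest.raises(ValueError):
            ds.wall_potential(0.0)


class TestTables:
    def test_flat_tables_inert(self, small_topology):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(scale=2.0, size=(9, 3)), axis=0) + 50
        topo = ds.Topology(["AAAAAAAAA"])
        e, f = ds.angle_dihedral_energy(pos, topo, Tables.flat())
        assert e == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0, atol=1e-12)

    def test_harmonic_angle_table_minimum(self):
        theta0 = 1.9
        tab = Tables(angle=TabulatedPotential.harmonic_angle(theta0, 5.0),
                     dihedral=TabulatedPotential.flat(periodic=True))
        topo = ds.Topology(["AAA"])
        pos = np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0],
                        [3.8 + 3.8 * np.cos(np.pi - theta0),
                         3.8 * np.sin(np.pi - theta0), 0.0]])
        e, _ = ds.angle_dihedral_energy(pos + 50, topo, tab)
        assert e == pytest.approx(0.0, abs=1e-6)

    def test_non_covering_table_rejected(self):
        x = np.linspace(0.3, 2.0, 30)   # does not span [0, π]
        with pytest.raises(ValueError, match="cover"):
            TabulatedPotential(x, np.zeros_like(x))

    def test_rigid_motion_invariance(self, small_topology):
        rng = np.random.default_rng(3)
        topo = ds.Topology(["AAAAAAAA"])
        pos = np.zeros((8, 3))
        for i in range(1, 8):
            v = rng.normal(size=3)
            pos[i] = pos[i - 1] + 3.8 * v / np.linalg.norm(v)
        e0, _ = ds.angle_dihedral_energy(pos, topo, Tables.default())
        # random rotation + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        e1, _ = ds.angle_dihedral_energy(pos @ q.T + [7.0, -3.0, 11.0],
                                         topo, Tables.default())
        assert e1 == pytest.approx(e0, rel=1e-9)


class TestAssembledForces:
    def test_two_isolated_residues_beyond_cutoffs(self):
        topo = ds.Topology(["Q", "Q"])
        box = ds.Box.cube(100.0)
        pos = np.array([[40.0, 50.0, 50.0], [60.0, 50.0, 50.0]])
        e, f = ds.total_energy_forces(pos, topo, box)
        assert e.total == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(f, 0.0)

    def test_overlapping_residues_error(self):
        topo = ds.Topology(["Q", "Q"])
        box = ds.Box.cube(50.0)
        pos = np.array([[25.0, 25.0, 25.0], [25.0, 25.0, 25.0]])
        with pytest.raises(FloatingPointError):
            ds.total_energy_forces(pos, topo, box)

    def test_forces_match_central_differences(self, forcefield, saw_state):
        rel = fd_force_check(forcefield, saw_state.positions, saw_state.box)
        assert rel < 1e-5

    def test_forces_match_fd_with_contacts_and_walls(self, small_topology):
        st = ds.init_saw(small_topology, 0.05, seed=4)
        ff = ds.ForceField(small_topology)
        ds.run_segment(st, ff, 600, check_every=10)
        ds.enable_wall_adhesion(st)
        ds.run_segment(st, ff, 600, check_every=10)
        assert st.registry.n_active > 0
        rel = fd_force_check(ff, st.positions, st.box,
                             registry=st.registry, wall_on=True)
        assert rel < 1e-5

    def test_forces_match_fd_with_charges(self):
        topo = ds.Topology(["KDERKD"])
        ff = ds.ForceField(topo)
        assert ff.q_pref > 0
        rng = np.random.default_rng(5)
        pos = np.zeros((6, 3))
        for i in range(1, 6):
            v = rng.normal(size=3)
            pos[i] = pos[i - 1] + 3.8 * v / np.linalg.norm(v)
        box = ds.Box.cube(80.0)
        rel = fd_force_check(ff, pos + 40.0, box, stride=1)
        assert rel < 1e-5

    def test_newtons_third_law(self, forcefield, saw_state):
        # internal forces only (no walls): total momentum change is zero
        _, f = forcefield.energy_forces(saw_state.positions, saw_state.box)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)

    def test_translation_by_cell_vector_invariance(self, forcefield,
                                                   saw_state):
        box = saw_state.box
        e0, _ = forcefield.energy_forces(saw_state.positions, box)
        shifted = saw_state.positions + np.array([box.ax, 0.0, 0.0])
        e1, _ = forcefield.energy_forces(shifted, box)
        assert e1.total == pytest.approx(e0.total, rel=1e-9)

    def test_breakdown_total_is_component_sum(self, forcefield, saw_state):
        e, _ = forcefield.energy_forces(saw_state.positions, saw_state.box)
        parts = (e.bond + e.angle + e.dihedral + e.excluded + e.contact_bb
                 + e.contact_bs + e.contact_ss + e.go + e.disulfide
                 + e.electrostatic + e.wall)
        assert e.total == pytest.approx(parts, rel=1e-12)

    def test_i_plus_two_pairs_use_excluded_volume_only(self):
        # a j=i+2 pair inside a contact well distance must contribute no
        # attractive energy even with perfect geometry
        topo = ds.Topology(["QQQ"])
        box = ds.Box.cube(60.0)
        pos = np.array([[30.0, 30.0, 30.0], [33.0, 32.2, 30.0],
                        [36.0, 30.0, 30.0]])
        e, _ = ds.total_energy_forces(pos, topo, box)
        assert e.contact_bb == 0.0 and e.contact_ss == 0.0
        assert e.excluded >= 0.0
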
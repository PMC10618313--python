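"""Directional frames, contact eligibility, switching and disulfides."""
import numpy as np
import pytest

import dsbsim as ds
from dsbsim import _kernels as K
from dsbsim.contact_dynamics import (ContactRegistry, eligible_contacts,
                                     local_frames, solvation_adjustment,
                                     update_registry)


def _zigzag_chain(n=9, angle_deg=120.0, b=3.8):
    """Planar zig-zag in the xy-plane."""
    pos = np.zeros((n, 3))
    theta = np.deg2rad(180.0 - angle_deg)
    direction = 1.0
    for i in range(1, n):
        pos[i] = pos[i - 1] + [b * np.cos(theta / 2),
                               direction * b * np.sin(theta / 2), 0.0]
        direction *= -1.0
    return pos


class TestLocalFrames:
    def test_zigzag_binormals_perpendicular_to_plane(self):
        topo = ds.Topology(["A" * 9])
        fr = local_frames(_zigzag_chain(), topo)
        inner = fr.b_hat[1:-1]
        assert fr.ok[1:-1].all()
        assert np.allclose(np.abs(inner[:, 2]), 1.0, atol=1e-9)
        # all parallel
        assert np.allclose(np.abs(inner @ inner[0]), 1.0, atol=1e-9)

    def test_collinear_chain_flagged_degenerate(self):
        topo = ds.Topology(["AAAA"])
        pos = np.zeros((4, 3))
        pos[:, 0] = np.arange(4) * 3.8
        fr = local_frames(pos, topo)
        assert not fr.ok.any()

    def test_frames_are_rotation_equivariant(self):
        topo = ds.Topology(["A" * 9])
        pos = _zigzag_chain()
        rng = np.random.default_rng(7)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        fr0 = local_frames(pos, topo)
        fr1 = local_frames(pos @ q.T, topo)
        sel = fr0.ok
        assert np.allclose(fr1.n_hat[sel], fr0.n_hat[sel] @ q.T, atol=1e-9)
        assert np.allclose(fr1.b_hat[sel], fr0.b_hat[sel] @ q.T, atol=1e-9)

    def test_termini_have_no_frame(self):
        topo = ds.Topology(["AAAAA"])
        fr = local_frames(_zigzag_chain(5), topo)
        assert not fr.ok[0] and not fr.ok[-1]


def _two_zigzags(gap=5.0):
    """Two parallel zig-zag chains stacked along z: b̂ vectors aligned with
    the inter-chain axis, the textbook backbone-backbone geometry."""
    a = _zigzag_chain()
    b = a.copy()
    b[:, 2] += gap
    topo = ds.Topology(["A" * 9] * 2)
    return topo, np.vstack([a, b]) + 40.0


class TestEligibility:
    def test_far_pairs_not_eligible(self):
        topo, pos = _two_zigzags(gap=20.0)
        box = ds.Box.cube(120.0)
        p = ds.ModelParams()
        reg = ContactRegistry(topo, p)
        fr = local_frames(pos, topo, box)
        assert eligible_contacts(pos, box, fr, topo, p, reg) == []

    def test_stacked_zigzags_form_bb_candidates(self):
        topo, pos = _two_zigzags(gap=5.0)
        box = ds.Box.cube(120.0)
        p = ds.ModelParams()
        reg = ContactRegistry(topo, p)
        fr = local_frames(pos, topo, box)
        cands = eligible_contacts(pos, box, fr, topo, p, reg)
        kinds = {c[3] for c in cands}
        assert K.K_BB in kinds

    def test_next_nearest_neighbors_never_eligible(self):
        topo = ds.Topology(["A" * 9])
        pos = _zigzag_chain() + 40.0
        box = ds.Box.cube(120.0)
        p = ds.ModelParams()
        fr = local_frames(pos, topo, box)
        cands = eligible_contacts(pos, box, fr, topo, p,
                                  ContactRegistry(topo, p))
        assert all(abs(c[1] - c[2]) > 2 for c in cands)

    def test_exhausted_slots_refuse_new_contacts(self):
        topo, pos = _two_zigzags(gap=5.0)
        box = ds.Box.cube(120.0)
        p = ds.ModelParams()
        reg = ContactRegistry(topo, p)
        fr = local_frames(pos, topo, box)
        cands = eligible_contacts(pos, box, fr, topo, p, reg)
        update_registry(reg, cands, 0.0, topo, p, positions=pos, box=box)
        n_first = reg.n_active
        assert n_first > 0
        bb, ss, _ = reg.slot_usage(topo.n_residues)
        assert (bb <= p.nc_bb).all()
        # saturated residues accept nothing more in a second pass
        fr = local_frames(pos, topo, box)
        cands = eligible_contacts(pos, box, fr, topo, p, reg)
        update_registry(reg, cands, 0.0, topo, p, positions=pos, box=box)
        bb2, ss2, _ = reg.slot_usage(topo.n_residues)
        assert (bb2 <= p.nc_bb).all()
        assert (ss2 <= p.nc_ss[topo.type_index]).all()


class TestSwitching:
    def _registry_with_one(self, topo, p, t0=0.0):
        reg = ContactRegistry(topo, p)
        reg.add_record(1, 12, K.K_BB, p.r_bb, 1.0, t0)
        return reg

    def test_lambda_completes_in_exactly_ten_tau(self, small_topology):
        p = ds.ModelParams()
        reg = self._registry_with_one(small_topology, p)
        reg.advance(5.0)
        assert reg.lam[0] == pytest.approx(0.5)
        reg.advance(10.0)
        assert reg.lam[0] == 1.0 and reg.direction[0] == 0
        reg.advance(11.0)
        assert reg.lam[0] == 1.0

    def test_bb_off_threshold_value(self, small_topology):
        p = ds.ModelParams()
        thresh = p.breakage_factor * p.r_bb / 2 ** (1 / 6)
        assert thresh == pytest.approx(7.5 / 2 ** (1 / 6), abs=1e-9)
        assert thresh == pytest.approx(6.68, abs=0.01)
        reg = self._registry_with_one(small_topology, p)
        reg.advance(10.0)
        box = ds.Box.cube(200.0)
        pos = np.zeros((small_topology.n_residues, 3))
        pos[:, 0] = np.arange(small_topology.n_residues) * 50.0
        pos[12] = pos[1] + [6.7, 0.0, 0.0]   # just past the threshold
        reg.trigger_breakage(pos, box, 10.0)
        assert reg.direction[0] == -1
        # λ ramps back down and the record disappears after 10 τ
        reg.advance(15.0)
        assert reg.lam[0] == pytest.approx(0.5)
        reg.advance(20.0)
        assert reg.n_active == 0

    def test_contact_below_threshold_survives(self, small_topology):
        p = ds.ModelParams()
        reg = self._registry_with_one(small_topology, p)
        reg.advance(10.0)
        pos = np.zeros((small_topology.n_residues, 3))
        pos[:, 0] = np.arange(small_topology.n_residues) * 50.0
        pos[12] = pos[1] + [6.6, 0.0, 0.0]
        reg.trigger_breakage(pos, ds.Box.cube(200.0), 10.0)
        assert reg.direction[0] == 0


class TestDisulfides:
    def test_at_most_one_bond_per_cysteine(self):
        topo = ds.Topology(["GCG", "GCG", "GCG"])
        p = ds.ModelParams()
        reg = ContactRegistry(topo, p)
        # three mutually close cysteines: indices 1, 4, 7
        cands = [(5.5, 1, 4, K.K_DISULFIDE, 5.4, 4.0),
                 (5.6, 1, 7, K.K_DISULFIDE, 5.4, 4.0),
                 (5.7, 4, 7, K.K_DISULFIDE, 5.4, 4.0)]
        update_registry(reg, cands, 0.0, topo, p)
        _, _, ds_count = reg.slot_usage(topo.n_residues)
        assert ds_count.max() == 1
        assert reg.n_active == 1  # only the closest pair bonds

    def test_no_cysteines_registry_unchanged(self):
        topo = ds.Topology(["GQG", "GQG"])
        p = ds.ModelParams()
        reg = ContactRegistry(topo, p)
        box = ds.Box.cube(100.0)
        pos = np.random.default_rng(0).uniform(20, 80, (6, 3))
        from dsbsim.contact_dynamics import disulfide_pairing
        disulfide_pairing(pos, box, topo, p, reg)
        assert reg.n_active == 0

    def test_ruptured_bond_frees_both_partners(self):
        topo = ds.Topology(["GCG", "GCG"])
        p = ds.ModelParams()
        reg = ContactRegistry(topo, p)
        reg.add_record(1, 4, K.K_DISULFIDE, 5.4, 4.0, 0.0)
        reg.advance(10.0)
        pos = np.zeros((6, 3))
        pos[3:, 0] = 50.0   # pull the chains apart
        pos[:, 1] = np.tile([0, 4, 8], 2)
        reg.trigger_breakage(pos, ds.Box.cube(200.0), 10.0)
        reg.advance(20.0)
        assert reg.n_active == 0
        _, _, ds_count = reg.slot_usage(6)
        assert ds_count.sum() == 0


class TestSolvation:
    def test_disabled_is_identity(self, small_topology):
        p = ds.ModelParams()
        pos = np.random.default_rng(1).uniform(0, 50, (99, 3))
        bb, ss = solvation_adjustment(pos, ds.Box.cube(50.0),
                                      small_topology, p)
        assert (bb == p.nc_bb).all()
        assert (ss == p.nc_ss[small_topology.type_index]).all()

    def test_buried_residue_shifted(self):
        topo = ds.Topology(["Q" * 9])
        p = ds.ModelParams(solvation_n_t=5)
        box = ds.Box.cube(200.0)
        pos = np.full((9, 3), 100.0)
        pos[1:] += np.random.default_rng(2).uniform(-3, 3, (8, 3))
        bb, ss = solvation_adjustment(pos, box, topo, p)   # 8 close neighbors
        assert bb[0] == p.nc_bb + 1
        assert ss[0] == p.nc_ss[topo.type_index[0]] + 1

    def test_isolated_residue_unchanged(self):
        topo = ds.Topology(["Q", "Q"])
        p = ds.ModelParams(solvation_n_t=1)
        pos = np.array([[10.0, 10, 10], [90.0, 90, 90]])
        bb, ss = solvation_adjustment(pos, ds.Box.cube(100.0), topo, p)
        assert (bb == p.nc_bb).all()


class TestRegistryBookkeeping:
    def test_snapshot_table_columns(self, small_topology):
        p = ds.ModelParams()
        reg = ContactRegistry(small_topology, p)
        reg.add_record(0, 5, K.K_SS, 6.2, 1.0, 0.0)
        pos = np.random.default_rng(0).uniform(0, 40, (99, 3))
        table = reg.to_table(pos, ds.Box.cube(40.0), step=7)
        assert list(table.columns) == ["step", "i", "j", "kind", "r",
                                       "lambda"]
        assert table.iloc[0]["kind"] == "ss"

    def test_go_contacts_preloaded_and_permanent(self):
        topo = ds.Topology(["QQQQQQ"], go_contacts=[(0, 4, 6.0)])
        p = ds.ModelParams()
        reg = ContactRegistry(topo, p)
        assert reg.n_active == 1 and reg.lam[0] == 1.0
        pos = np.zeros((6, 3))
        pos[:, 0] = np.arange(6) * 50.0   # far beyond any off threshold
        reg.trigger_breakage(pos, ds.Box.cube(400.0), 5.0)
        reg.advance(100.0)
        assert reg.n_active == 1
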
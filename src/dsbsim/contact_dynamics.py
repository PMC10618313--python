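"""Dynamic contact registry: directional criteria and quasi-adiabatic switching.

A one-bead-per-residue chain has no explicit side chains, so contact
*direction* is recovered from the local geometry of three consecutive beads
(i-1, i, i+1): the in-plane bisector at bead i defines the normal n̂ (its
negative points roughly along the side chain) and the cross product of the
adjacent bond vectors defines the binormal b̂ (roughly the backbone
hydrogen-bond direction).  A backbone slot of a contact requires b̂ to be
aligned with the inter-residue axis; a side-chain slot requires -n̂ to point
toward the partner.

Contacts carry an activation λ ∈ [0, 1] ramped linearly over the switching
time (10 τ) when they form, and ramped back down - then removed - once the
pair distance exceeds (3/2)·r0/2^(1/6).  Each residue offers a limited
number of backbone and side-chain slots (the coordination numbers n_c);
cysteine pairs use the side-chain mechanism with a 4ε well and each
cysteine may hold at most one disulfide.  Go-mapped pairs are permanently
attractive and bypass geometry and slot accounting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as _K
from .core_types import (Box, ModelParams, Topology, minimum_image,
                         wrap_displacement)

__all__ = [
    "KIND_NAMES",
    "Frames",
    "ContactRegistry",
    "local_frames",
    "eligible_contacts",
    "update_registry",
    "disulfide_pairing",
    "solvation_adjustment",
]

KIND_NAMES = {_K.K_BB: "bb", _K.K_BS: "bs", _K.K_SB: "sb", _K.K_SS: "ss",
              _K.K_DISULFIDE: "disulfide", _K.K_GO: "go"}


@dataclass
class Frames:
    """Per-residue local frames; ``ok`` is False at termini and collinear
    triples (those residues sit out of directional contacts this step)."""

    n_hat: np.ndarray
    b_hat: np.ndarray
    ok: np.ndarray


def local_frames(positions: np.ndarray, topology: Topology,
                 box: Box | None = None) -> Frames:
    """Build n̂ (bisector) and b̂ (binormal) for every interior residue."""
    n = topology.n_residues
    pos = np.asarray(positions, dtype=float)
    n_hat = np.zeros((n, 3))
    b_hat = np.zeros((n, 3))
    ok = np.zeros(n, dtype=bool)
    mids = [np.arange(a + 1, b - 1) for a, b in topology.chains if b - a >= 3]
    if not mids:
        return Frames(n_hat=n_hat, b_hat=b_hat, ok=ok)
    mid = np.concatenate(mids)
    u = pos[mid - 1] - pos[mid]
    v = pos[mid + 1] - pos[mid]
    if box is not None:
        wrap_displacement(u, box)
        wrap_displacement(v, box)
    nu = np.linalg.norm(u, axis=1, keepdims=True)
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    good = (nu[:, 0] > 1e-9) & (nv[:, 0] > 1e-9)
    uh = np.divide(u, nu, out=np.zeros_like(u), where=nu > 1e-12)
    vh = np.divide(v, nv, out=np.zeros_like(v), where=nv > 1e-12)
    bis = uh + vh
    nbis = np.linalg.norm(bis, axis=1, keepdims=True)
    cr = np.cross(-uh, vh)  # bond_in x bond_out
    ncr = np.linalg.norm(cr, axis=1, keepdims=True)
    good &= (nbis[:, 0] > 1e-6) & (ncr[:, 0] > 1e-6)
    n_hat[mid] = np.divide(bis, nbis, out=np.zeros_like(bis),
                           where=nbis > 1e-12)
    b_hat[mid] = np.divide(cr, ncr, out=np.zeros_like(cr),
                           where=ncr > 1e-12)
    ok[mid] = good
    return Frames(n_hat=n_hat, b_hat=b_hat, ok=ok)


class ContactRegistry:
    """Active-contact bookkeeping (pair contacts + wall adhesion contacts).

    Stored as parallel numpy arrays; records are few (a handful per
    residue) so python-level mutation is cheap relative to the force loop.
    """

    def __init__(self, topology: Topology, params: ModelParams):
        self.params = params
        self.adhesion_enabled = False
        self.i = np.empty(0, dtype=np.int64)
        self.j = np.empty(0, dtype=np.int64)
        self.kind = np.empty(0, dtype=np.int64)
        self.r0 = np.empty(0, dtype=float)
        self.depth = np.empty(0, dtype=float)
        self.lam = np.empty(0, dtype=float)
        self.lam0 = np.empty(0, dtype=float)
        self.direction = np.empty(0, dtype=np.int64)  # +1 on, -1 off, 0 steady
        self.t_phase = np.empty(0, dtype=float)
        # wall adhesion records
        self.w_res = np.empty(0, dtype=np.int64)
        self.w_side = np.empty(0, dtype=np.int64)
        self.w_lam = np.empty(0, dtype=float)
        self.w_lam0 = np.empty(0, dtype=float)
        self.w_dir = np.empty(0, dtype=np.int64)
        self.w_t = np.empty(0, dtype=float)
        if topology.go_contacts:
            go = topology.go_contacts
            self.i = np.array([min(i, j) for i, j, _ in go], dtype=np.int64)
            self.j = np.array([max(i, j) for i, j, _ in go], dtype=np.int64)
            self.kind = np.full(len(go), _K.K_GO, dtype=np.int64)
            self.r0 = np.array([d for _, _, d in go], dtype=float)
            self.depth = np.ones(len(go))
            self.lam = np.ones(len(go))
            self.lam0 = np.ones(len(go))
            self.direction = np.zeros(len(go), dtype=np.int64)
            self.t_phase = np.zeros(len(go))

    # -- views ------------------------------------------------------------

    @property
    def n_active(self) -> int:
        return self.i.size

    def contact_arrays(self):
        return self.r0, self.depth, self.lam, self.kind

    def pair_contact_index(self, pairs: np.ndarray, n: int) -> np.ndarray:
        """Index of the active record for each pair-list entry (-1 if none)."""
        out = np.full(pairs.shape[0], -1, dtype=np.int64)
        if self.n_active == 0 or pairs.shape[0] == 0:
            return out
        keys = self.i * n + self.j
        order = np.argsort(keys)
        skeys = keys[order]
        pkeys = pairs[:, 0] * n + pairs[:, 1]
        loc = np.searchsorted(skeys, pkeys)
        loc_c = np.clip(loc, 0, skeys.size - 1)
        hit = skeys[loc_c] == pkeys
        out[hit] = order[loc_c[hit]]
        return out

    def wall_lambda_arrays(self, n: int):
        lo = np.zeros(n)
        hi = np.zeros(n)
        if self.w_res.size:
            m = self.w_side == 0
            lo[self.w_res[m]] = self.w_lam[m]
            hi[self.w_res[~m]] = self.w_lam[~m]
        return lo, hi

    def slot_usage(self, n: int):
        """Backbone and side-chain slot occupancy + per-residue disulfide
        counts.  Off-ramping records keep their slot until fully removed."""
        k = self.kind
        bb_members = np.concatenate([
            self.i[k == _K.K_BB], self.j[k == _K.K_BB],
            self.i[k == _K.K_BS], self.j[k == _K.K_SB]])
        ss_members = np.concatenate([
            self.j[k == _K.K_BS], self.i[k == _K.K_SB],
            self.i[k == _K.K_SS], self.j[k == _K.K_SS],
            self.i[k == _K.K_DISULFIDE], self.j[k == _K.K_DISULFIDE]])
        ds_members = np.concatenate([
            self.i[k == _K.K_DISULFIDE], self.j[k == _K.K_DISULFIDE]])
        bb = np.bincount(bb_members, minlength=n)
        ss = np.bincount(ss_members, minlength=n)
        ds = np.bincount(ds_members, minlength=n)
        return bb, ss, ds

    def active_pair_keys(self, n: int) -> set:
        return set((self.i * n + self.j).tolist())

    # -- evolution ---------------------------------------------------------

    def advance(self, t: float) -> None:
        """Update every λ from its phase timestamp; drop fully-off records."""
        T = self.params.switch_time
        if self.n_active:
            on = self.direction == 1
            self.lam[on] = np.minimum(
                1.0, self.lam0[on] + (t - self.t_phase[on]) / T)
            done = on & (self.lam >= 1.0)
            self.direction[done] = 0
            off = self.direction == -1
            self.lam[off] = np.maximum(
                0.0, self.lam0[off] - (t - self.t_phase[off]) / T)
            keep = ~(off & (self.lam <= 0.0))
            if not keep.all():
                self._filter(keep)
        if self.w_res.size:
            on = self.w_dir == 1
            self.w_lam[on] = np.minimum(
                1.0, self.w_lam0[on] + (t - self.w_t[on]) / T)
            done = on & (self.w_lam >= 1.0)
            self.w_dir[done] = 0
            off = self.w_dir == -1
            self.w_lam[off] = np.maximum(
                0.0, self.w_lam0[off] - (t - self.w_t[off]) / T)
            keep = ~(off & (self.w_lam <= 0.0))
            if not keep.all():
                for name in ("w_res", "w_side", "w_lam", "w_lam0",
                             "w_dir", "w_t"):
                    setattr(self, name, getattr(self, name)[keep])

    def _filter(self, keep: np.ndarray) -> None:
        for name in ("i", "j", "kind", "r0", "depth", "lam", "lam0",
                     "direction", "t_phase"):
            setattr(self, name, getattr(self, name)[keep])

    def trigger_breakage(self, positions: np.ndarray, box: Box,
                         t: float) -> None:
        """Start the off-ramp for contacts beyond (3/2)·r0/2^(1/6).

        Go contacts are permanent and never break.
        """
        if not self.n_active:
            return
        p = self.params
        d = wrap_displacement(positions[self.i] - positions[self.j], box)
        r = np.linalg.norm(d, axis=1)
        thresh = p.breakage_factor * self.r0 / 2 ** (1 / 6)
        brk = (r > thresh) & (self.direction != -1) & (self.kind != _K.K_GO)
        if brk.any():
            self.lam0[brk] = self.lam[brk]
            self.direction[brk] = -1
            self.t_phase[brk] = t

    def add_record(self, i: int, j: int, kind: int, r0: float, depth: float,
                   t: float) -> None:
        self.add_records([(i, j, kind, r0, depth)], t)

    def add_records(self, records, t: float) -> None:
        """Batch-append new on-ramping records ((i, j, kind, r0, depth))."""
        if not records:
            return
        m = len(records)
        ii = np.array([min(r[0], r[1]) for r in records], dtype=np.int64)
        jj = np.array([max(r[0], r[1]) for r in records], dtype=np.int64)
        self.i = np.concatenate([self.i, ii])
        self.j = np.concatenate([self.j, jj])
        self.kind = np.concatenate(
            [self.kind, np.array([r[2] for r in records], dtype=np.int64)])
        self.r0 = np.concatenate(
            [self.r0, np.array([r[3] for r in records], dtype=float)])
        self.depth = np.concatenate(
            [self.depth, np.array([r[4] for r in records], dtype=float)])
        self.lam = np.concatenate([self.lam, np.zeros(m)])
        self.lam0 = np.concatenate([self.lam0, np.zeros(m)])
        self.direction = np.concatenate(
            [self.direction, np.ones(m, dtype=np.int64)])
        self.t_phase = np.concatenate([self.t_phase, np.full(m, t)])

    def update_walls(self, positions: np.ndarray, box: Box, t: float) -> None:
        """Form / break adhesive wall contacts (when adhesion is enabled)."""
        if not self.adhesion_enabled:
            return
        p = self.params
        z = positions[:, 2]
        dist = np.stack([z - box.z_lo, box.z_hi - z], axis=1)
        thresh_off = p.breakage_factor * p.wall_r0 / 2 ** (1 / 6)
        # breakage
        if self.w_res.size:
            d = dist[self.w_res, self.w_side]
            brk = (d > thresh_off) & (self.w_dir != -1)
            if brk.any():
                self.w_lam0[brk] = self.w_lam[brk]
                self.w_dir[brk] = -1
                self.w_t[brk] = t
        # capture
        have = set(zip(self.w_res.tolist(), self.w_side.tolist()))
        cap = p.capture_factor * p.wall_r0
        res, side = np.nonzero(dist < cap)
        new = [(r, s) for r, s in zip(res.tolist(), side.tolist())
               if (r, s) not in have]
        if new:
            nr = np.array([r for r, _ in new], dtype=np.int64)
            ns = np.array([s for _, s in new], dtype=np.int64)
            self.w_res = np.concatenate([self.w_res, nr])
            self.w_side = np.concatenate([self.w_side, ns])
            self.w_lam = np.concatenate([self.w_lam, np.zeros(len(new))])
            self.w_lam0 = np.concatenate([self.w_lam0, np.zeros(len(new))])
            self.w_dir = np.concatenate(
                [self.w_dir, np.ones(len(new), dtype=np.int64)])
            self.w_t = np.concatenate([self.w_t, np.full(len(new), t)])

    def to_table(self, positions=None, box=None, step=0) -> pd.DataFrame:
        """Snapshot as a tab-friendly table (step, i, j, kind, r, lambda)."""
        if positions is not None and self.n_active:
            d = minimum_image(positions[self.i], positions[self.j], box)
            r = np.linalg.norm(np.atleast_2d(d), axis=1)
        else:
            r = np.full(self.n_active, np.nan)
        return pd.DataFrame({
            "step": step,
            "i": self.i, "j": self.j,
            "kind": [KIND_NAMES[k] for k in self.kind],
            "r": r, "lambda": self.lam,
        })


# ---------------------------------------------------------------------------
# eligibility and the per-step update
# ---------------------------------------------------------------------------

def solvation_adjustment(positions: np.ndarray, box: Box, topology: Topology,
                         params: ModelParams):
    """Coordination numbers adjusted by the solvent-competition rule.

    Residues with more than ``solvation_n_t`` neighbors within 0.75 nm get
    their coordination capacities shifted by ``solvation_delta`` (buried
    residues are shielded from the solvent and may coordinate differently).
    With the feature disabled (``solvation_n_t is None``) the base tables
    are returned unchanged.
    """
    n = topology.n_residues
    nc_bb = np.full(n, params.nc_bb, dtype=np.int64)
    nc_ss = params.nc_ss[topology.type_index].copy()
    if params.solvation_n_t is None:
        return nc_bb, nc_ss
    pos = np.asarray(positions, dtype=float)
    n_n = np.zeros(n, dtype=np.int64)
    for i in range(n):
        d = minimum_image(pos, pos[i], box)
        r = np.linalg.norm(np.atleast_2d(d), axis=1)
        n_n[i] = int(np.sum(r < params.solvation_radius)) - 1
    shift = (n_n > params.solvation_n_t).astype(np.int64) * params.solvation_delta
    return np.maximum(nc_bb + shift, 0), np.maximum(nc_ss + shift, 0)


def eligible_contacts(positions: np.ndarray, box: Box, frames: Frames,
                      topology: Topology, params: ModelParams,
                      registry: ContactRegistry,
                      pairs: np.ndarray | None = None,
                      flag: np.ndarray | None = None):
    """Candidate (r, i, j, kind, r0, depth) list, sorted by (r, i, j).

    A candidate must be within the capture range of its kind's equilibrium
    distance, pass the directional-cosine criteria, and not already have an
    active record.  j = i+2 pairs are never eligible.  Slot capacity is
    checked later, at acceptance time (see :func:`update_registry`).
    """
    p = params
    t = topology
    n = t.n_residues
    pos = np.asarray(positions, dtype=float)
    if pairs is None:
        pairs, flag = _K.build_pairs(
            np.ascontiguousarray(pos), box.as_array(),
            p.capture_factor * max(p.r_bs, float(p.r_ss.max())) + 1e-9,
            t.chain_id)
    if pairs.shape[0] == 0:
        return []
    sel = flag == 1
    pi = pairs[sel, 0]
    pj = pairs[sel, 1]
    d = wrap_displacement(pos[pi] - pos[pj], box)
    r = np.linalg.norm(d, axis=1)
    within = r < p.capture_factor * max(p.r_bs, float(p.r_ss.max()))
    pi, pj, d, r = pi[within], pj[within], d[within], r[within]
    if pi.size == 0:
        return []
    # drop pairs that already hold a record
    if registry.n_active:
        fresh = ~np.isin(pi * n + pj, registry.i * n + registry.j)
        pi, pj, d, r = pi[fresh], pj[fresh], d[fresh], r[fresh]
    if pi.size == 0:
        return []
    rhat = d / r[:, None]
    okf = frames.ok
    bb_i = np.abs(np.einsum("ij,ij->i", frames.b_hat[pi], rhat)) >= p.cos_bb
    bb_j = np.abs(np.einsum("ij,ij->i", frames.b_hat[pj], rhat)) >= p.cos_bb
    # side chain of i points along -n̂_i; toward j means (-n̂_i)·r̂_ji ≥ cos
    ss_i = np.einsum("ij,ij->i", frames.n_hat[pi], rhat) >= p.cos_ss
    ss_j = np.einsum("ij,ij->i", frames.n_hat[pj], -rhat) >= p.cos_ss
    bb_i &= okf[pi]
    bb_j &= okf[pj]
    ss_i &= okf[pi]
    ss_j &= okf[pj]
    cys = t.is_cysteine
    r_ss_pair = p.r_ss[t.type_index[pi], t.type_index[pj]]
    cap = p.capture_factor
    # fixed kind priority: bb, bs, sb, ss/disulfide
    m_bb = bb_i & bb_j & (r < cap * p.r_bb)
    m_bs = ~m_bb & bb_i & ss_j & (r < cap * p.r_bs)
    m_sb = ~m_bb & ~m_bs & ss_i & bb_j & (r < cap * p.r_bs)
    m_ss = (~m_bb & ~m_bs & ~m_sb & ss_i & ss_j
            & (r < cap * r_ss_pair))
    m_cys = m_ss & cys[pi] & cys[pj]
    kind = np.full(pi.size, -1, dtype=np.int64)
    kind[m_bb] = _K.K_BB
    kind[m_bs] = _K.K_BS
    kind[m_sb] = _K.K_SB
    kind[m_ss] = _K.K_SS
    kind[m_cys] = _K.K_DISULFIDE
    r0 = np.where(m_bb, p.r_bb, np.where(m_bs | m_sb, p.r_bs, r_ss_pair))
    depth = np.where(m_cys, p.depth_disulfide, p.depth_ss)
    sel = kind >= 0
    order = np.lexsort((pj[sel], pi[sel], r[sel]))
    rs = r[sel][order]
    pis = pi[sel][order]
    pjs = pj[sel][order]
    ks = kind[sel][order]
    r0s = r0[sel][order]
    ds = depth[sel][order]
    return list(zip(rs.tolist(), pis.tolist(), pjs.tolist(), ks.tolist(),
                    r0s.tolist(), ds.tolist()))


def update_registry(registry: ContactRegistry, candidates, t: float,
                    topology: Topology, params: ModelParams,
                    positions=None, box=None) -> ContactRegistry:
    """Advance λ ramps, trigger distance breakage, accept new candidates.

    Acceptance is greedy in (distance, i, j) order under the coordination
    limits; each cysteine may hold one disulfide.
    """
    registry.advance(t)
    if positions is not None:
        registry.trigger_breakage(positions, box, t)
        registry.advance(t)
    n = topology.n_residues
    if positions is not None and box is not None:
        nc_bb_arr, nc_ss_arr = solvation_adjustment(
            positions, box, topology, params)
    else:
        nc_bb_arr = np.full(n, params.nc_bb, dtype=np.int64)
        nc_ss_arr = params.nc_ss[topology.type_index].copy()
    use_bb, use_ss, use_ds = registry.slot_usage(n)
    accepted = []
    for rk, i, j, kind, r0, depth in candidates:
        if kind == _K.K_BB:
            if use_bb[i] >= nc_bb_arr[i] or use_bb[j] >= nc_bb_arr[j]:
                continue
            use_bb[i] += 1
            use_bb[j] += 1
        elif kind == _K.K_BS:
            if use_bb[i] >= nc_bb_arr[i] or use_ss[j] >= nc_ss_arr[j]:
                continue
            use_bb[i] += 1
            use_ss[j] += 1
        elif kind == _K.K_SB:
            if use_ss[i] >= nc_ss_arr[i] or use_bb[j] >= nc_bb_arr[j]:
                continue
            use_ss[i] += 1
            use_bb[j] += 1
        elif kind in (_K.K_SS, _K.K_DISULFIDE):
            if use_ss[i] >= nc_ss_arr[i] or use_ss[j] >= nc_ss_arr[j]:
                continue
            if kind == _K.K_DISULFIDE and (use_ds[i] >= 1 or use_ds[j] >= 1):
                continue
            use_ss[i] += 1
            use_ss[j] += 1
            if kind == _K.K_DISULFIDE:
                use_ds[i] += 1
                use_ds[j] += 1
        else:
            continue
        accepted.append((i, j, kind, r0, depth))
    registry.add_records(accepted, t)
    return registry


def disulfide_pairing(positions: np.ndarray, box: Box, topology: Topology,
                      params: ModelParams,
                      registry: ContactRegistry) -> ContactRegistry:
    """Run one registry update restricted to cysteine-cysteine candidates."""
    frames = local_frames(positions, topology, box)
    cands = eligible_contacts(positions, box, frames, topology, params,
                              registry)
    cands = [c for c in cands if c[3] == _K.K_DISULFIDE]
    return update_registry(registry, cands, 0.0, topology, params)


def update_contacts(state, topology: Topology, params: ModelParams,
                    pairs: np.ndarray, flag: np.ndarray) -> None:
    """Full per-step contact update used by the integrator driver."""
    reg: ContactRegistry = state.registry
    t = state.time
    reg.advance(t)
    reg.trigger_breakage(state.positions, state.box, t)
    reg.update_walls(state.positions, state.box, t)
    frames = local_frames(state.positions, topology, state.box)
    cands = eligible_contacts(state.positions, state.box, frames, topology,
                              params, reg, pairs=pairs, flag=flag)
    update_registry(reg, cands, t, topology, params,
                    positions=state.positions, box=state.box)
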
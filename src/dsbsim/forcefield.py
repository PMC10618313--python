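"""Potential-energy terms and forces of the coarse-grained model.

The model combines:

* harmonic bonds  V = k (r - r_b)^2  with k = 50 ε Å⁻², r_b = 3.8 Å
  (no ½ prefactor - the spring constant is quoted directly in ε Å⁻²);
* tabulated bond-angle and dihedral stiffness (random-coil-like, any
  two-column table is accepted; a smooth synthetic default ships with the
  package as a documented stand-in);
* excluded volume: a Lennard-Jones repulsion shifted to zero at the
  cutoff r_o = 5 Å,  V_r = ε[(r_o/r)¹² - 2(r_o/r)⁶ + 1] for r ≤ r_o;
* dynamic contact wells: full 6-12 LJ with depth ε (4ε for disulfides)
  and a kind-dependent minimum (bb 5 Å, bs 6.8 Å, ss pairwise matrix,
  Go-map distances), scaled by the quasi-adiabatic activation λ and
  cross-faded with the excluded-volume term, (1-λ)V_r + λV_LJ, so the
  energy is continuous through contact birth and death;
* Debye-Hückel electrostatics with a distance-dependent relative
  permittivity ε_r(r) = κ·r (κ = 4 Å⁻¹), i.e. an effective 1/r² Coulomb
  times exp(-r/λ_D), truncated-and-shifted at the cutoff;
* slab walls: repulsive (ε/9)(σ/z)⁹ with σ = 0.5 nm; the adhesive wall
  variant is a full 6-12 well of depth 4ε cross-faded with the repulsion
  by the wall-contact activation λ.

Beads separated by two bonds along a chain (j = i+2) interact through the
excluded-volume term only.
"""
from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy.interpolate import CubicSpline

from . import _kernels as _K
from .core_types import Box, ModelParams, Topology

__all__ = [
    "EnergyBreakdown",
    "bond_energy",
    "excluded_volume",
    "contact_well",
    "debye_huckel",
    "wall_potential",
    "TabulatedPotential",
    "Tables",
    "ForceField",
    "total_energy_forces",
]


@dataclass
class EnergyBreakdown:
    """Per-term potential energies, in ε."""

    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    excluded: float = 0.0
    contact_bb: float = 0.0
    contact_bs: float = 0.0
    contact_ss: float = 0.0
    go: float = 0.0
    disulfide: float = 0.0
    electrostatic: float = 0.0
    wall: float = 0.0

    @property
    def total(self) -> float:
        return float(sum(getattr(self, f.name) for f in dc_fields(self)))

    @classmethod
    def from_array(cls, e: np.ndarray) -> "EnergyBreakdown":
        return cls(*[float(x) for x in e])


# ---------------------------------------------------------------------------
# scalar term functions (reference forms, used directly in tests and docs)
# ---------------------------------------------------------------------------

def bond_energy(r: float, params: ModelParams | None = None):
    """Harmonic bond V = k (r - r_b)²; returns (energy, radial force -dV/dr)."""
    p = params or ModelParams()
    if r <= 0:
        raise ValueError("bond length must be positive")
    dr = r - p.r_bond
    return p.k_bond * dr * dr, -2.0 * p.k_bond * dr


def excluded_volume(r: float, r0: float = 5.0) -> float:
    """Repulsive LJ cut and shifted to zero at ``r0``; exactly 0 for r ≥ r0."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if r >= r0:
        return 0.0
    s6 = (r0 / r) ** 6
    return s6 * s6 - 2.0 * s6 + 1.0


def contact_well(r: float, r0: float, depth: float = 1.0) -> float:
    """Full 6-12 LJ well with minimum -depth at r = r0."""
    if r <= 0:
        raise ValueError("distance must be positive")
    s6 = (r0 / r) ** 6
    return depth * (s6 * s6 - 2.0 * s6)


def debye_huckel(r: float, q_i: float, q_j: float,
                 params: ModelParams | None = None) -> float:
    """Screened Coulomb with ε_r(r) = κ·r (unshifted reference form)."""
    p = params or ModelParams()
    if r <= 0:
        raise ValueError("distance must be positive")
    if q_i == 0.0 or q_j == 0.0:
        return 0.0
    pref = p.coulomb_const / p.kappa_perm
    return pref * q_i * q_j / r**2 * np.exp(-r / p.debye_length)


def wall_potential(z_dist: float, params: ModelParams | None = None,
                   adhesive: bool = False, lam: float = 1.0) -> float:
    """Wall energy at distance ``z_dist`` from the nearer Z wall.

    Plain walls are purely repulsive, (ε/9)(σ/z)⁹.  With ``adhesive`` the
    repulsion cross-fades (weight 1-λ) into a 6-12 well of depth 4ε whose
    minimum is -4ε at z = wall_r0 once the switching completes (λ = 1).
    """
    p = params or ModelParams()
    if z_dist <= 0:
        raise ValueError("residue is at or beyond the wall")
    lam_eff = lam if adhesive else 0.0
    v = (1.0 - lam_eff) * (p.wall_sigma / z_dist) ** 9 / 9.0
    if lam_eff > 0.0:
        v += lam_eff * contact_well(z_dist, p.wall_r0, p.wall_adhesion_depth)
    return v


# ---------------------------------------------------------------------------
# tabulated angle / dihedral potentials
# ---------------------------------------------------------------------------

class TabulatedPotential:
    """Cubic-spline interpolated potential on a uniform grid.

    Angle tables must cover [0, π]; dihedral tables must cover [-π, π] and
    are interpolated with periodic boundary conditions.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray, periodic: bool = False):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape or x.size < 4:
            raise ValueError("table must be two matching 1-D columns (n ≥ 4)")
        h = np.diff(x)
        if (h <= 0).any() or not np.allclose(h, h[0], rtol=1e-8):
            raise ValueError("table grid must be strictly increasing, uniform")
        lo, hi = (-np.pi, np.pi) if periodic else (0.0, np.pi)
        if x[0] > lo + 1e-9 or x[-1] < hi - 1e-9:
            raise ValueError(
                f"table does not cover the required range [{lo:.3f}, {hi:.3f}]")
        self.periodic = periodic
        if periodic:
            if not np.isclose(y[0], y[-1], atol=1e-10):
                raise ValueError("periodic table must have matching endpoints")
            self._spline = CubicSpline(x, y, bc_type="periodic")
        else:
            self._spline = CubicSpline(x, y, bc_type="natural")
        self.x0 = float(x[0])
        self.h = float(h[0])
        self.coef = np.ascontiguousarray(self._spline.c)

    def energy(self, x):
        return self._spline(self._wrap(x))

    def derivative(self, x):
        return self._spline(self._wrap(x), 1)

    def _wrap(self, x):
        if not self.periodic:
            return x
        return (np.asarray(x) + np.pi) % (2 * np.pi) - np.pi

    @classmethod
    def from_file(cls, path, periodic: bool = False) -> "TabulatedPotential":
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1], periodic=periodic)

    @classmethod
    def flat(cls, periodic: bool = False) -> "TabulatedPotential":
        lo, hi = (-np.pi, np.pi) if periodic else (0.0, np.pi)
        x = np.linspace(lo, hi, 61)
        return cls(x, np.zeros_like(x), periodic=periodic)

    @classmethod
    def harmonic_angle(cls, theta0: float, k: float,
                       n: int = 181) -> "TabulatedPotential":
        x = np.linspace(0.0, np.pi, n)
        return cls(x, k * (x - theta0) ** 2, periodic=False)


@dataclass
class Tables:
    """Angle + dihedral stiffness tables used by the force field."""

    angle: TabulatedPotential
    dihedral: TabulatedPotential

    @classmethod
    def default(cls) -> "Tables":
        """Smooth synthetic random-coil-like stiffness (stand-in tables).

        Gentle harmonic angle bias around 105° and a weak cosine-series
        dihedral keep chains flexible, as expected for disordered proteins.
        """
        th = np.linspace(0.0, np.pi, 181)
        v_ang = 4.0 * (th - np.deg2rad(105.0)) ** 2
        ph = np.linspace(-np.pi, np.pi, 181)
        v_dih = 0.3 * (1.0 + np.cos(ph)) + 0.2 * (1.0 + np.cos(3.0 * ph))
        return cls(angle=TabulatedPotential(th, v_ang),
                   dihedral=TabulatedPotential(ph, v_dih, periodic=True))

    @classmethod
    def flat(cls) -> "Tables":
        return cls(angle=TabulatedPotential.flat(),
                   dihedral=TabulatedPotential.flat(periodic=True))


# ---------------------------------------------------------------------------
# assembled force field
# ---------------------------------------------------------------------------

_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=float)


class ForceField:
    """Packs topology + parameters + tables into kernel-ready arrays."""

    #: neighbor-list cutoff margin (Å) beyond the largest interaction reach
    SKIN = 2.0

    def __init__(self, topology: Topology, params: ModelParams | None = None,
                 tables: Tables | None = None):
        self.topology = topology
        self.params = params or ModelParams()
        self.tables = tables or Tables.default()
        p = self.params
        self.charges = p.charges[topology.type_index].copy()
        if not np.any(self.charges):
            self.q_pref = 0.0
        else:
            self.q_pref = p.coulomb_const / p.kappa_perm
        self.elec_cut = min(2.0 * p.debye_length, 20.0)
        reach = p.breakage_factor * max(
            p.r_bb, p.r_bs, float(p.r_ss.max())) / 2 ** (1 / 6)
        reach = max(reach, p.r_excl, p.capture_factor * p.r_bs,
                    self.elec_cut if self.q_pref else 0.0,
                    p.solvation_radius if p.solvation_n_t is not None else 0.0)
        self.cutoff = reach + self.SKIN
        self.wall_cut = 3.0 * p.wall_sigma

    # -- neighbor list ----------------------------------------------------

    def build_pairs(self, positions: np.ndarray, box: Box):
        """Verlet pair list (indices + i+2 flags) within the skinned cutoff.

        Go-mapped pairs are appended unconditionally so permanent contacts
        never fall off the list.
        """
        pairs, flag = _K.build_pairs(
            np.ascontiguousarray(positions), box.as_array(), self.cutoff,
            self.topology.chain_id)
        go = self.topology.go_contacts
        if go:
            n = self.topology.n_residues
            have = set((int(i) * n + int(j)) for i, j in pairs)
            extra = [(min(i, j), max(i, j)) for i, j, _ in go
                     if min(i, j) * n + max(i, j) not in have]
            if extra:
                pairs = np.vstack([pairs, np.array(extra, dtype=np.int64)])
                flag = np.concatenate(
                    [flag, np.ones(len(extra), dtype=np.int64)])
        return pairs, flag

    # -- kernel argument packing -----------------------------------------

    def kernel_args(self, box: Box, pairs, flag, pair_cidx,
                    contact_arrays=None, wall_arrays=None, wall_on=False):
        p = self.params
        t = self.topology
        if contact_arrays is None:
            con_r0 = con_depth = con_lam = _EMPTY_F
            con_kind = _EMPTY_I
        else:
            con_r0, con_depth, con_lam, con_kind = contact_arrays
        n = t.n_residues
        if wall_arrays is None:
            wl = np.zeros(n)
            wh = np.zeros(n)
        else:
            wl, wh = wall_arrays
        tb = self.tables
        return (
            box.as_array(),
            t.bonded_pairs, p.k_bond, p.r_bond,
            t.angle_triples, tb.angle.coef, tb.angle.x0, tb.angle.h,
            t.dihedral_quads, tb.dihedral.coef, tb.dihedral.x0, tb.dihedral.h,
            pairs, flag, pair_cidx,
            con_r0, con_depth, con_lam, con_kind,
            self.charges, self.q_pref, p.debye_length, self.elec_cut,
            p.r_excl,
            1 if wall_on else 0, p.wall_sigma, p.wall_r0,
            p.wall_adhesion_depth, self.wall_cut,
            wl, wh,
        )

    def energy_forces(self, positions: np.ndarray, box: Box,
                      registry=None, wall_on: bool = False):
        """Evaluate all terms; returns (EnergyBreakdown, forces (N,3))."""
        positions = np.ascontiguousarray(positions, dtype=float)
        pairs, flag = self.build_pairs(positions, box)
        if registry is not None:
            contact_arrays = registry.contact_arrays()
            pair_cidx = registry.pair_contact_index(
                pairs, self.topology.n_residues)
            wall_arrays = registry.wall_lambda_arrays(self.topology.n_residues)
            wall_on = wall_on or registry.adhesion_enabled
        else:
            contact_arrays = None
            pair_cidx = np.full(pairs.shape[0], -1, dtype=np.int64)
            wall_arrays = None
        frc = np.zeros_like(positions)
        ebrk = np.zeros(_K.N_ETERMS)
        _K.compute_forces(positions,
                          *self.kernel_args(box, pairs, flag, pair_cidx,
                                            contact_arrays, wall_arrays,
                                            wall_on),
                          frc, ebrk)
        if not np.isfinite(frc).all():
            raise FloatingPointError(
                "non-finite force (overlapping residues?)")
        return EnergyBreakdown.from_array(ebrk), frc


def angle_dihedral_energy(positions, topology: Topology, tables: Tables,
                          box: Box | None = None,
                          params: ModelParams | None = None):
    """Angle + dihedral stiffness energy and forces alone.

    Evaluates only the tabulated bonded-geometry terms (useful for table
    validation); rigid rotations and translations leave the energy
    unchanged.
    """
    positions = np.ascontiguousarray(positions, dtype=float)
    if box is None:
        lo = positions.min(axis=0) - 10.0
        hi = positions.max(axis=0) + 10.0
        box = Box(ax=hi[0] - lo[0], by=hi[1] - lo[1], z_lo=lo[2], z_hi=hi[2])
    ff = ForceField(topology, params, tables)
    t = topology
    tb = ff.tables
    pairs = np.empty((0, 2), dtype=np.int64)
    iempty = np.empty(0, dtype=np.int64)
    frc = np.zeros_like(positions)
    ebrk = np.zeros(_K.N_ETERMS)
    _K.compute_forces(
        positions, box.as_array(),
        np.empty((0, 2), dtype=np.int64), ff.params.k_bond, ff.params.r_bond,
        t.angle_triples, tb.angle.coef, tb.angle.x0, tb.angle.h,
        t.dihedral_quads, tb.dihedral.coef, tb.dihedral.x0, tb.dihedral.h,
        pairs, iempty, iempty,
        _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_I,
        ff.charges, 0.0, ff.params.debye_length, ff.elec_cut,
        ff.params.r_excl,
        0, ff.params.wall_sigma, ff.params.wall_r0,
        ff.params.wall_adhesion_depth, ff.wall_cut,
        np.zeros(t.n_residues), np.zeros(t.n_residues),
        frc, ebrk)
    return float(ebrk[_K.E_ANGLE] + ebrk[_K.E_DIHEDRAL]), frc


def total_energy_forces(positions, topology: Topology, box: Box,
                        params: ModelParams | None = None,
                        registry=None, tables: Tables | None = None,
                        wall_on: bool = False):
    """One-shot convenience wrapper around :class:`ForceField`."""
    ff = ForceField(topology, params, tables)
    return ff.energy_forces(positions, box, registry=registry, wall_on=wall_on)
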
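"""Core data model: system topology, model parameters, box geometry, state.

Internal unit system
--------------------
* length   : Å  (the coarse-grained bond length is 3.8 Å)
* energy   : ε  (the depth of a single contact well; room temperature
               corresponds to 0.3 ε ≲ k_B T ≲ 0.38 ε)
* time     : τ  (≈ 1 ns; one τ equals 200 integrator steps)
* mass     : m  (the average residue mass; m = 1 internally, ~120 Da)

Residue *density* crosses the public API in nm⁻³ — the number of amino-acid
beads per cubic nanometer of box volume — because that is the natural control
variable for an implicit-solvent condensate simulation.  All conversions
happen at the API boundary; nothing inside the force loop ever sees a nm.

The simulation cell is periodic in X and Y and bounded by solid walls in Z
(a slab geometry).  Under shear the in-plane cell becomes a parallelogram,
so the cell is stored as a lower-triangular 2x2 in-plane matrix plus the two
wall positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AA_CODES",
    "AA_INDEX",
    "NM",
    "Topology",
    "ModelParams",
    "Box",
    "SimState",
    "residue_density",
    "box_side_for_density",
    "minimum_image",
]

#: Standard one-letter amino-acid alphabet accepted by the model.
AA_CODES = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {c: i for i, c in enumerate(AA_CODES)}

#: One nanometer in internal length units (Å).
NM = 10.0

# Side-chain size parameters (Å) used to build the default pairwise
# side-chain--side-chain equilibrium distance matrix r_ss[a][b] = r_a + r_b.
# These are coarse effective radii ordered by side-chain volume; the matrix
# is a documented stand-in and fully configurable.
_SIDECHAIN_RADIUS = {
    "G": 2.25, "A": 2.50, "S": 2.60, "C": 2.70, "T": 2.80, "P": 2.80,
    "V": 2.90, "D": 2.80, "N": 2.90, "I": 3.10, "L": 3.10, "E": 3.00,
    "Q": 3.10, "M": 3.20, "H": 3.20, "K": 3.20, "F": 3.40, "R": 3.40,
    "Y": 3.50, "W": 3.60,
}

# Default maximum coordination numbers per residue type (stand-in tables,
# configurable): every backbone offers two hydrogen-bonding slots; side-chain
# capacity grows loosely with side-chain size, and glycine - having no side
# chain - gets a single weak slot.
_NC_BACKBONE_DEFAULT = 2
_NC_SIDECHAIN = {
    "G": 1,
    "A": 2, "S": 2, "C": 2, "T": 2, "P": 2, "V": 2, "D": 2, "N": 2,
    "I": 2, "L": 2, "E": 2, "Q": 2, "M": 2, "H": 2,
    "K": 3, "F": 3, "R": 3, "Y": 3, "W": 3,
}

# Default charge assignment (elementary charges): acidic residues -1,
# basic residues +1, histidine neutral.  Configurable on ModelParams.
_CHARGE = {"D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0}


def _default_r_ss() -> np.ndarray:
    r = np.array([_SIDECHAIN_RADIUS[c] for c in AA_CODES])
    return r[:, None] + r[None, :]


def _default_nc_ss() -> np.ndarray:
    return np.array([_NC_SIDECHAIN[c] for c in AA_CODES], dtype=np.int64)


def _default_charges() -> np.ndarray:
    return np.array([_CHARGE.get(c, 0.0) for c in AA_CODES])


@dataclass
class Topology:
    """Bead-per-residue topology of a multichain system.

    ``sequences`` holds one string of one-letter codes per chain instance
    (copies are expanded, one entry per physical chain).  All derived index
    arrays (bonds, angle triples, dihedral quads, chain membership) are
    built once at construction.
    """

    sequences: list[str]
    go_contacts: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("topology needs at least one chain")
        for seq in self.sequences:
            if not seq:
                raise ValueError("empty chain sequence")
            bad = set(seq) - set(AA_CODES)
            if bad:
                raise ValueError(f"unknown residue code(s): {sorted(bad)}")
        lengths = [len(s) for s in self.sequences]
        starts = np.concatenate([[0], np.cumsum(lengths)])
        #: per-chain residue index ranges [start, stop)
        self.chains: list[tuple[int, int]] = [
            (int(starts[k]), int(starts[k + 1])) for k in range(len(lengths))
        ]
        seq_all = "".join(self.sequences)
        self.residue_types: str = seq_all
        self.type_index = np.array([AA_INDEX[c] for c in seq_all], dtype=np.int64)
        self.is_cysteine = np.array([c == "C" for c in seq_all], dtype=bool)
        self.chain_id = np.concatenate(
            [np.full(n, k, dtype=np.int64) for k, n in enumerate(lengths)]
        )

        bonds, angles, dihedrals = [], [], []
        for a, b in self.chains:
            for i in range(a, b - 1):
                bonds.append((i, i + 1))
            for i in range(a, b - 2):
                angles.append((i, i + 1, i + 2))
            for i in range(a, b - 3):
                dihedrals.append((i, i + 1, i + 2, i + 3))
        self.bonded_pairs = np.array(bonds, dtype=np.int64).reshape(-1, 2)
        self.angle_triples = np.array(angles, dtype=np.int64).reshape(-1, 3)
        self.dihedral_quads = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

        for i, j, d in self.go_contacts:
            if self.chain_id[i] != self.chain_id[j]:
                raise ValueError(f"Go contact ({i},{j}) crosses chains")
            if abs(i - j) < 3:
                raise ValueError(f"Go contact ({i},{j}) too local (|i-j|<3)")
            if d <= 0:
                raise ValueError("Go contact distance must be positive")

    @property
    def n_residues(self) -> int:
        return len(self.residue_types)

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def chain_slice(self, k: int) -> slice:
        a, b = self.chains[k]
        return slice(a, b)


@dataclass
class ModelParams:
    """Force-field and protocol constants, in internal units (Å, ε, τ, m).

    Defaults follow the published coarse-grained model where a value is
    printed; everything that is not printed (side-chain pair distances,
    coordination tables, directional cosine cutoffs, the Debye length, the
    Coulomb prefactor) is a documented, configurable stand-in.
    """

    epsilon: float = 1.0
    tau: float = 1.0
    mass: float = 1.0
    kBT: float = 0.35            # mid room-temperature range [0.3, 0.38] ε

    k_bond: float = 50.0         # ε Å⁻², V = k (r - r_b)²  (no ½ factor)
    r_bond: float = 3.8          # Å
    r_excl: float = 5.0          # Å, excluded-volume cutoff r_o
    r_bb: float = 5.0            # Å, backbone-backbone contact minimum
    r_bs: float = 6.8            # Å, backbone-side-chain contact minimum
    r_ss: np.ndarray = field(default_factory=_default_r_ss)
    nc_bb: int = _NC_BACKBONE_DEFAULT
    nc_ss: np.ndarray = field(default_factory=_default_nc_ss)
    depth_ss: float = 1.0        # ε
    depth_disulfide: float = 4.0  # ε

    charges: np.ndarray = field(default_factory=_default_charges)
    kappa_perm: float = 4.0      # Å⁻¹; relative permittivity ε_r(r) = κ·r
    debye_length: float = 10.0   # Å (not printed; configurable)
    coulomb_const: float = 195.0  # ε·Å: e²/(4πε₀) with ε ≈ 1.7 kcal/mol

    switch_time: float = 10.0    # τ, quasi-adiabatic on/off ramp
    breakage_factor: float = 1.5  # off threshold = factor · r0 / 2^{1/6}
    capture_factor: float = 1.1   # on range = factor · r0 (not printed)
    cos_bb: float = 0.5          # |b̂·r̂| cutoff for backbone slots (stand-in)
    cos_ss: float = 0.5          # (-n̂)·r̂ cutoff for side-chain slots

    wall_sigma: float = 5.0      # Å (0.5 nm), repulsive wall length scale
    wall_adhesion_depth: float = 4.0  # ε
    wall_r0: float = 5.0         # Å, adhesive wall well minimum distance

    solvation_n_t: int | None = None   # neighbor threshold; None = disabled
    solvation_radius: float = 7.5      # Å (0.75 nm)
    solvation_delta: int = +1          # n_c shift sign (ambiguous; config)

    @property
    def dt(self) -> float:
        """Integrator step: one τ is exactly 200 steps."""
        return self.tau / 200.0

    @property
    def gamma(self) -> float:
        """Langevin damping γ = 2m/τ (overdamped regime)."""
        return 2.0 * self.mass / self.tau

    def __post_init__(self) -> None:
        for name in ("k_bond", "r_bond", "r_excl", "r_bb", "r_bs",
                     "wall_sigma", "wall_r0", "switch_time", "tau", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.r_ss = np.asarray(self.r_ss, dtype=float)
        if self.r_ss.shape != (20, 20) or (self.r_ss <= 0).any():
            raise ValueError("r_ss must be a positive 20x20 matrix")
        self.nc_ss = np.asarray(self.nc_ss, dtype=np.int64)
        if self.nc_ss.shape != (20,):
            raise ValueError("nc_ss must have one entry per residue type")
        self.charges = np.asarray(self.charges, dtype=float)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class Box:
    """Slab simulation cell: periodic in X/Y, solid walls in Z.

    In-plane cell matrix (column vectors) is ``[[ax, bx], [0, by]]``; the
    cell is rectangular when ``bx`` (the shear tilt) is zero.  ``z_lo`` and
    ``z_hi`` are the wall positions.
    """

    ax: float
    by: float
    z_lo: float
    z_hi: float
    bx: float = 0.0

    @classmethod
    def cube(cls, side: float) -> "Box":
        return cls(ax=side, by=side, z_lo=0.0, z_hi=side)

    @property
    def lz(self) -> float:
        return self.z_hi - self.z_lo

    @property
    def volume(self) -> float:
        """Cell volume in Å³."""
        return self.ax * self.by * self.lz

    def validate(self) -> None:
        if self.ax <= 0 or self.by <= 0 or self.lz <= 0:
            raise ValueError("degenerate box")
        if abs(self.bx) >= self.ax:
            raise ValueError("shear tilt too large for a valid cell")

    def cell_vectors(self) -> np.ndarray:
        """3x3 matrix of cell vectors as rows (Z row spans the walls)."""
        return np.array([
            [self.ax, 0.0, 0.0],
            [self.bx, self.by, 0.0],
            [0.0, 0.0, self.lz],
        ])

    def as_array(self) -> np.ndarray:
        """Packed (ax, bx, by, z_lo, z_hi) for the numeric kernels."""
        return np.array([self.ax, self.bx, self.by, self.z_lo, self.z_hi])


@dataclass
class SimState:
    """Mutable simulation state: coordinates, velocities, box, registry.

    ``registry`` is the dynamic-contact registry owned by
    :mod:`dsbsim.contact_dynamics`; it is carried here so that one object
    fully determines the next step of the trajectory (together with the
    RNG seed).
    """

    positions: np.ndarray
    velocities: np.ndarray
    box: Box
    registry: object | None = None
    time: float = 0.0            # elapsed simulation time, τ
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions/velocities shape mismatch")
        if not np.isfinite(self.positions).all():
            raise ValueError("non-finite positions")

    @property
    def n_residues(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SimState":
        import copy as _copy
        return SimState(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            box=replace(self.box),
            registry=_copy.deepcopy(self.registry),
            time=self.time,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# density / geometry operations
# ---------------------------------------------------------------------------

def residue_density(state: SimState) -> float:
    """Residue density ρ of a state, in nm⁻³.

    ρ is the number of beads per cubic nanometer of box volume - the proxy
    concentration variable of an implicit-solvent model, not the true mass
    density of a protein solution.
    """
    state.box.validate()
    vol_nm3 = state.box.volume / NM**3
    return state.n_residues / vol_nm3


def box_side_for_density(n_residues: int, rho: float) -> float:
    """Cubic box side (nm) that puts ``n_residues`` beads at density ``rho``.

    Inverse of :func:`residue_density` for cubic boxes:
    side = (N/ρ)^(1/3).  E.g. 4271 residues at 3.5 nm⁻³ need a ≈10.7 nm box.
    """
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    if rho <= 0:
        raise ValueError("rho must be positive")
    return float((n_residues / rho) ** (1.0 / 3.0))


def minimum_image(r_i: np.ndarray, r_j: np.ndarray, box: Box) -> np.ndarray:
    """Shortest displacement r_i - r_j under X/Y periodicity.

    Handles sheared (parallelogram) in-plane cells exactly by wrapping in
    fractional coordinates and then minimizing over the 3x3 block of
    neighboring in-plane images.  Z is never wrapped (walls).

    Accepts single points or (N, 3) arrays (broadcast together).
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    d = np.atleast_2d(r_i - r_j).astype(float)
    ax, bx, by = box.ax, box.bx, box.by
    # fractional wrap in the periodic plane
    fy = d[:, 1] / by
    ny = np.round(fy)
    d[:, 1] -= ny * by
    d[:, 0] -= ny * bx
    d[:, 0] -= np.round(d[:, 0] / ax) * ax
    # exact minimization: for every candidate Y image the X component is
    # re-wrapped exactly, and the Y image range is wide enough that any
    # further image is provably longer than the current best
    best0 = np.sqrt((d[:, :2] ** 2).sum(axis=1))
    k = int(np.floor(best0.max() / by)) + 1
    best_norm2 = np.full(d.shape[0], np.inf)
    best_xy = d[:, :2].copy()
    for nb in range(-k, k + 1):
        dy = d[:, 1] + nb * by
        dx = d[:, 0] + nb * bx
        dx = dx - np.round(dx / ax) * ax
        n2 = dx * dx + dy * dy
        upd = n2 < best_norm2
        best_norm2[upd] = n2[upd]
        best_xy[upd, 0] = dx[upd]
        best_xy[upd, 1] = dy[upd]
    d[:, :2] = best_xy
    if r_i.ndim == 1 and r_j.ndim == 1:
        return d[0]
    return d


def wrap_displacement(d: np.ndarray, box: Box) -> np.ndarray:
    """Fast in-plane minimum image by fractional rounding (in place).

    Matches the force-kernel convention; exact while displacements of
    interest stay below half the cell extents (the 9-image search in
    :func:`minimum_image` is the general form).
    """
    d = np.atleast_2d(d)
    ny = np.rint(d[:, 1] / box.by)
    d[:, 1] -= ny * box.by
    d[:, 0] -= ny * box.bx
    d[:, 0] -= np.rint(d[:, 0] / box.ax) * box.ax
    return d


def wrap_in_plane(positions: np.ndarray, box: Box) -> np.ndarray:
    """Copy of ``positions`` with X/Y wrapped into the primary cell."""
    p = np.array(positions, dtype=float)
    fy = np.floor(p[:, 1] / box.by)
    p[:, 1] -= fy * box.by
    p[:, 0] -= fy * box.bx
    p[:, 0] -= np.floor(p[:, 0] / box.ax) * box.ax
    return p
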
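"""Density profiles, pair correlations, chain shape metrics, regime labels.

These diagnostics translate a residue density ρ (beads · nm⁻³, the only
concentration-like variable an implicit-solvent model exposes) into a
physical picture of the system: how homogeneous it is (profiles, cavity
statistics), how structured the local packing is (g(r) with its bb/bs
contact peaks), how compact the chains are (R_ee, R_g, asphericity), and
which of four regimes the density falls into.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core_types import Box, Topology, minimum_image, wrap_in_plane

__all__ = [
    "ShapeMetrics",
    "density_profile",
    "radial_distribution",
    "shape_metrics",
    "classify_regime",
    "REGIMES",
    "standard_measurements",
]


@dataclass
class ShapeMetrics:
    """Chain shape: end-to-end distance, gyration radius, asphericity.

    The asphericity W is the relative shape anisotropy built from the
    gyration-tensor eigenvalues λ₁ ≥ λ₂ ≥ λ₃:

        W = [(λ₁-λ₂)² + (λ₂-λ₃)² + (λ₃-λ₁)²] / [2 (λ₁+λ₂+λ₃)²]

    bounded in [0, 1]; 0 for an isotropic cloud, 1 for a straight rod.
    """

    ree: float
    rg: float
    w: float


def density_profile(positions: np.ndarray, box: Box, axis: int = 1,
                    bin_width: float = 2.0):
    """Residue-count histogram along one axis (single-frame observable).

    Profiles are meant to be taken from individual (late) frames: cavities
    wander, so time-averaged profiles flatten out and hide inhomogeneity.
    Returns (bin_edges, counts); the counts sum to the number of residues.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    pos = np.asarray(positions, dtype=float)
    if axis in (0, 1):
        pos = wrap_in_plane(pos, box)
        lo = 0.0
        hi = box.ax if axis == 0 else box.by
    else:
        lo, hi = box.z_lo, box.z_hi
    nbin = max(int(math.ceil((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(nbin + 1) * bin_width
    counts, _ = np.histogram(np.clip(pos[:, axis], lo, edges[-1] - 1e-12),
                             bins=edges)
    return edges, counts


def radial_distribution(positions: np.ndarray, box: Box,
                        r_max: float, dr: float = 0.2):
    """Radial distribution function g(r) with minimum-image distances.

    Pair counts are normalized by the ideal-gas expectation in the slab
    cell: the spherical-shell volume weighted by the probability
    (1 - r/(2 L_z)) that a uniform |Δz| keeps the pair inside the walls
    (exact for r ≤ L_z).  ``r_max`` must stay below half the smallest
    periodic extent.  Returns (r_centers, g).
    """
    if r_max > min(box.ax, box.by) / 2:
        raise ValueError("r_max exceeds half the periodic cell extent")
    if r_max > box.lz:
        raise ValueError("r_max exceeds the wall separation")
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    nbin = int(math.ceil(r_max / dr))
    counts = np.zeros(nbin)
    for i in range(n - 1):
        d = minimum_image(pos[i + 1:], pos[i], box)
        r = np.linalg.norm(np.atleast_2d(d), axis=1)
        h, _ = np.histogram(r, bins=nbin, range=(0.0, nbin * dr))
        counts += h
    edges = np.arange(nbin + 1) * dr
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    slab_corr = 1.0 - centers / (2.0 * box.lz)
    ideal = n * (n - 1) / 2.0 * shell * slab_corr / box.volume
    g = np.divide(counts, ideal, out=np.zeros(nbin), where=ideal > 0)
    return centers, g


def shape_metrics(chain_positions: np.ndarray) -> ShapeMetrics:
    """R_ee, R_g and asphericity W of one chain (positions must be
    spatially contiguous, i.e. already unwrapped across the boundary)."""
    p = np.asarray(chain_positions, dtype=float)
    if p.shape[0] < 2:
        raise ValueError("chain needs at least two residues")
    ree = float(np.linalg.norm(p[-1] - p[0]))
    c = p - p.mean(axis=0)
    gyr = c.T @ c / p.shape[0]
    ev = np.sort(np.linalg.eigvalsh(gyr))[::-1]
    rg = float(math.sqrt(ev.sum()))
    tr = ev.sum()
    if tr <= 0:
        w = 0.0
    else:
        w = float(((ev[0] - ev[1]) ** 2 + (ev[1] - ev[2]) ** 2
                   + (ev[2] - ev[0]) ** 2) / (2.0 * tr * tr))
    return ShapeMetrics(ree=ree, rg=rg, w=w)


#: regime thresholds in nm⁻³ (system-dependent; these fit long, sticky,
#: essentially uncharged chains)
REGIMES = ((0.0, "infinitely-dilute"), (1.0, "dilute"),
           (3.0, "intermediate"), (math.inf, "dense"))


def classify_regime(rho: float, thresholds=(1.0, 3.0)) -> str:
    """Density-regime label for ρ (nm⁻³).

    * ρ = 0: infinitely dilute - isolated chains;
    * 0 < ρ < 1: dilute - freely diffusing chains, occasional oligomers;
    * 1 ≤ ρ ≤ 3: intermediate - a connected network with large cavities;
    * ρ > 3: dense - homogeneous, many small cavities.
    """
    if rho < 0:
        raise ValueError("density cannot be negative")
    lo, hi = thresholds
    if rho == 0:
        return "infinitely-dilute"
    if rho < lo:
        return "dilute"
    if rho <= hi:
        return "intermediate"
    return "dense"


def standard_measurements(state, topology: Topology) -> dict:
    """Final-frame observables used by the density sweep.

    Cavity statistics, entanglement count and per-chain shape metrics
    (averaged over chains).  Heavy imports are local to keep the module
    graph acyclic.
    """
    from .cavity_analysis import SpaceballParams, spaceball
    from .entanglement_analysis import analyze_entanglements
    pos = state.positions
    box = state.box
    out = {}
    try:
        # slab-variant classification: the simulation cell is periodic in
        # X/Y with walls in Z, so the exterior is seeded at the wall faces
        rep = spaceball(pos, box, SpaceballParams(periodic_xy=True))
        out.update(n_cavities=rep.n_cavities, v_c_max=rep.v_c_max,
                   v_c_total=rep.v_c_total)
    except ValueError:
        out.update(n_cavities=np.nan, v_c_max=np.nan, v_c_total=np.nan)
    ent = analyze_entanglements(pos, topology, box)
    out["n_entanglements"] = ent.n_entanglements
    ms = [shape_metrics(path) for path in
          (_unwrapped_chain(pos, topology, box, k)
           for k in range(topology.n_chains))]
    out["ree"] = float(np.mean([m.ree for m in ms]))
    out["rg"] = float(np.mean([m.rg for m in ms]))
    out["w"] = float(np.mean([m.w for m in ms]))
    return out


def _unwrapped_chain(positions, topology: Topology, box: Box, k: int):
    a, b = topology.chains[k]
    p = np.asarray(positions[a:b], dtype=float).copy()
    for i in range(1, p.shape[0]):
        p[i] = p[i - 1] + minimum_image(positions[a + i], p[i - 1], box)
    return p
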
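"""Grid-of-balls cavity detection for multichain bead systems.

The detector fills the cell with a cubic grid of probe balls (radius
1.9 Å, spacing 1 Å by default - half the coarse-grained length unit, since
a water-sized probe makes no sense between 3.8 Å beads).  Balls overlapping
any residue are occupied; empty balls reachable from the faces of the box
are exterior (the cell is treated as a finite container for this
classification, the way a stand-alone cavity tool treats any PDB box);
whatever remains is cavity volume.  A strict slab variant
(``periodic_xy=True``) instead wraps the X/Y adjacency periodically and
seeds the exterior only from the open Z faces beyond the outermost
residues.
Cavity balls are clustered into connected components and each component's
volume is its ball count times the grid-cell volume.

With more than one grid rotation the classification is repeated with the
system rotated about the Z axis and only balls interior in *every*
rotation are kept (intersection rule).  Rotations are only available in
non-periodic mode, where the grid just covers the coordinate bounding box
(e.g. a free-standing structure read from a PDB file).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as _K
from .core_types import NM, Box, wrap_in_plane

__all__ = ["SpaceballParams", "CavityReport", "spaceball", "cavity_vs_density"]


@dataclass
class SpaceballParams:
    """Probe-grid settings.  Volumes are reported in nm³."""

    ball_radius: float = 1.9     # Å
    spacing: float = 1.0         # Å
    rotations: int = 1           # 1 = single unrotated grid
    residue_radius: float = 3.8  # Å occlusion radius (the CG length unit)
    periodic_xy: bool = False    # True = strict slab (periodic X/Y) variant
    connectivity: int = 6        # 6 or 26 for cavity clustering

    def __post_init__(self) -> None:
        if self.spacing > 2.0 * self.ball_radius:
            raise ValueError("grid spacing must not exceed the ball diameter")
        if self.rotations < 1:
            raise ValueError("rotations must be ≥ 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclass
class CavityReport:
    """Cavity statistics of one configuration (volumes in nm³, descending)."""

    n_cavities: int
    volumes: list[float]
    params: SpaceballParams = field(default_factory=SpaceballParams)

    @property
    def v_c_max(self) -> float:
        return self.volumes[0] if self.volumes else 0.0

    @property
    def v_c_total(self) -> float:
        return float(sum(self.volumes))


def _classify(positions, params, nx, ny, nz, hx, hy, hz, x0, y0, z0, ax, by):
    """One occupancy + exterior flood-fill pass; returns the occ array."""
    reach = params.ball_radius + params.residue_radius
    occ = _K.mark_occupied(
        np.ascontiguousarray(positions, dtype=float),
        nx, ny, nz, hx, hy, hz, x0, y0, z0, reach,
        1 if params.periodic_xy else 0, ax, by)
    occ3 = occ.reshape(nx, ny, nz)
    zocc = np.nonzero(occ3.any(axis=(0, 1)))[0]
    seeds = []
    if params.periodic_xy:
        # open Z faces: the wall-adjacent layers plus every fully empty
        # layer beyond the outermost occupied one
        if zocc.size == 0:
            layers = set(range(nz))
        else:
            layers = set(range(int(zocc[0]) + 1)) | \
                set(range(int(zocc[-1]), nz))
        for layer in sorted(layers):
            idx = (np.arange(nx)[:, None] * ny
                   + np.arange(ny)[None, :]) * nz + layer
            seeds.append(idx.ravel())
    else:
        # all boundary cells of the bounding grid
        mask = np.zeros((nx, ny, nz), dtype=bool)
        mask[0, :, :] = mask[-1, :, :] = True
        mask[:, 0, :] = mask[:, -1, :] = True
        mask[:, :, 0] = mask[:, :, -1] = True
        seeds.append(np.nonzero(mask.ravel())[0])
    seeds = (np.concatenate(seeds) if seeds
             else np.empty(0, dtype=np.int64)).astype(np.int64)
    _K.flood_exterior(occ, nx, ny, nz, seeds,
                      1 if params.periodic_xy else 0)
    return occ


def spaceball(positions: np.ndarray, box: Box | None = None,
              params: SpaceballParams | None = None) -> CavityReport:
    """Detect cavities in one configuration.

    In periodic mode the grid tiles the (rectangular) cell exactly, so the
    effective spacing per axis is the cell length divided by a whole number
    of grid cells; volumes use the product of effective spacings.
    """
    params = params or SpaceballParams()
    pos = np.asarray(positions, dtype=float)
    if params.periodic_xy:
        box.validate()
        if abs(box.bx) > 1e-9:
            raise ValueError("cavity analysis needs a rectangular cell")
        if params.rotations != 1:
            raise ValueError("grid rotations require non-periodic mode")
        pos = wrap_in_plane(pos, box)
        nx = max(int(round(box.ax / params.spacing)), 2)
        ny = max(int(round(box.by / params.spacing)), 2)
        nz = max(int(round(box.lz / params.spacing)), 2)
        hx, hy, hz = box.ax / nx, box.by / ny, box.lz / nz
        x0, y0, z0 = 0.0, 0.0, box.z_lo
        ax_cell, by_cell = box.ax, box.by
        interior = None
        occ = _classify(pos, params, nx, ny, nz, hx, hy, hz, x0, y0, z0,
                        ax_cell, by_cell)
        interior = occ
    else:
        if box is not None:
            # keep beads inside the cell so the bounding grid matches it
            pos = wrap_in_plane(pos, box)
        pad = params.ball_radius + params.residue_radius + 2 * params.spacing
        lo = pos.min(axis=0) - pad
        hi = pos.max(axis=0) + pad
        nx, ny, nz = (max(int(math.ceil((hi[k] - lo[k]) / params.spacing)) + 1,
                          2) for k in range(3))
        hx = hy = hz = params.spacing
        x0, y0, z0 = lo
        center = 0.5 * (lo + hi)
        interior = None
        for k in range(params.rotations):
            ang = 2.0 * math.pi * k / params.rotations
            c, s = math.cos(-ang), math.sin(-ang)
            rp = pos - center
            rot = np.stack([c * rp[:, 0] - s * rp[:, 1],
                            s * rp[:, 0] + c * rp[:, 1],
                            rp[:, 2]], axis=1) + center
            occ = _classify(rot, params, nx, ny, nz, hx, hy, hz, x0, y0, z0,
                            0.0, 0.0)
            if interior is None:
                interior = occ
            else:
                # keep a ball as cavity candidate only if interior everywhere
                interior[(interior == 0) & (occ != 0)] = 2
    labels, ncomp = _K.label_components(
        interior, nx, ny, nz, 1 if params.periodic_xy else 0,
        1 if params.connectivity == 26 else 0)
    cell_vol_nm3 = hx * hy * hz / NM**3
    volumes = sorted(
        (float(np.sum(labels == k)) * cell_vol_nm3 for k in range(ncomp)),
        reverse=True)
    return CavityReport(n_cavities=ncomp, volumes=volumes, params=params)


def cavity_vs_density(sweep_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a density sweep into ρ → (n_cavities, V^C_max, V^C_total).

    Expects per-run rows holding ``rho``, ``n_cavities``, ``v_c_max`` and
    ``v_c_total`` columns (as produced by the standard sweep measurements,
    evaluated near the end of each run); returns means with standard
    errors per density.
    """
    cols = ["rho", "n_cavities", "v_c_max", "v_c_total"]
    if sweep_table.empty:
        return pd.DataFrame(columns=cols)
    t = sweep_table[cols].dropna(subset=["n_cavities"])
    g = t.groupby("rho")
    out = g.mean().join(g.sem(), rsuffix="_err").reset_index()
    return out
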
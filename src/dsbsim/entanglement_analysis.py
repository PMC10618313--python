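"""Pairwise entanglement counting by primitive-path shrinking.

Each chain's termini stay pinned while its contour is shortened by two
local moves - removing an interior vertex, or pulling it halfway toward
the midpoint of its neighbors - with every move vetoed if the triangle it
sweeps is crossed by a segment of any *other* chain.  A chain that can
contract to the straight line between its termini is unentangled; residual
kinks mark topological obstructions, and a pair of chains counts as
entangled when at least one kink of one path is blocked by the other
chain.  Crossing tests use minimum-image segment placement in the periodic
X/Y plane (one image per segment; valid while paths are short compared to
the cell).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _K
from .core_types import Box, Topology, minimum_image

__all__ = ["EntanglementReport", "shrink_chains", "count_entanglements",
           "analyze_entanglements"]

#: interior vertices straighter than this turn cosine are not kinks
_KINK_COS = 1.0 - 1e-6


@dataclass
class EntanglementReport:
    """Entangled chain pairs, their kink points, and the primitive paths."""

    n_entanglements: int
    pairs: list[tuple[int, int]]
    kinks: list[tuple[int, int, np.ndarray]]  # (chain_a, chain_b, point)
    primitive_paths: list[np.ndarray] = field(default_factory=list)
    converged: bool = True


def _unwrap_chain(path: np.ndarray, box: Box | None) -> np.ndarray:
    """Make a chain spatially contiguous across the periodic boundary."""
    if box is None:
        return path.copy()
    out = path.copy()
    for k in range(1, out.shape[0]):
        out[k] = out[k - 1] + minimum_image(path[k], out[k - 1], box)
    return out


def _segments_of(paths, skip=None):
    segs = []
    chain_of = []
    for c, p in enumerate(paths):
        for k in range(p.shape[0] - 1):
            segs.append(np.concatenate([p[k], p[k + 1]]))
            chain_of.append(c)
    if not segs:
        return np.empty((0, 6)), np.empty(0, dtype=np.int64)
    return np.array(segs), np.array(chain_of, dtype=np.int64)


def _path_length(p: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())


def shrink_chains(positions: np.ndarray, topology: Topology,
                  box: Box | None = None,
                  tol: float = 1e-6, max_sweeps: int = 2000):
    """Contract every chain toward its termini chord; returns the paths.

    Returns (paths, converged): one polyline per chain whose endpoints are
    the original termini; total contour length is non-increasing sweep by
    sweep and the iteration stops once the relative decrease per sweep
    falls below ``tol``.
    """
    if box is not None:
        cell = (box.ax, box.bx, box.by)
        periodic = 1
    else:
        cell = (1e12, 0.0, 1e12)
        periodic = 0
    paths = [_unwrap_chain(np.asarray(positions[a:b], dtype=float), box)
             for a, b in topology.chains]
    converged = False
    for sweep in range(max_sweeps):
        total0 = sum(_path_length(p) for p in paths)
        for c in range(len(paths)):
            # other chains' paths are frozen while chain c moves, so the
            # segment table only needs a rebuild per chain pass
            segs, seg_chain = _segments_of(paths)
            p = paths[c]
            k = 1
            while k < p.shape[0] - 1:
                a, v, b = p[k - 1], p[k], p[k + 1]
                # degenerate (collinear) corner: always removable
                area2 = np.linalg.norm(np.cross(v - a, b - a))
                blocked = -1
                if area2 > 1e-9:
                    blocked = _K.triangle_blocked(
                        a, v, b, segs, seg_chain, c,
                        cell[0], cell[1], cell[2], periodic)
                if blocked < 0:
                    p = np.delete(p, k, axis=0)
                    paths[c] = p
                    continue
                # try straightening toward the neighbor midpoint
                new = 0.5 * (v + 0.5 * (a + b))
                t1 = _K.triangle_blocked(a, v, new, segs, seg_chain, c,
                                         cell[0], cell[1], cell[2], periodic)
                t2 = _K.triangle_blocked(v, b, new, segs, seg_chain, c,
                                         cell[0], cell[1], cell[2], periodic)
                if t1 < 0 and t2 < 0:
                    p[k] = new
                k += 1
        total1 = sum(_path_length(p) for p in paths)
        if total1 > total0 + 1e-9:
            raise AssertionError("contour length increased during shrinking")
        if total0 - total1 < tol * max(total0, 1e-12):
            converged = True
            break
    return paths, converged


def count_entanglements(paths, box: Box | None = None,
                        converged: bool = True) -> EntanglementReport:
    """Count entangled chain pairs from the shrunken primitive paths.

    Every residual kink (an interior vertex with a genuine turn) is
    attributed to the chain whose segment blocks its removal triangle;
    a chain pair is entangled when at least one kink links them.
    """
    if box is not None:
        cell = (box.ax, box.bx, box.by)
        periodic = 1
    else:
        cell = (1e12, 0.0, 1e12)
        periodic = 0
    segs, seg_chain = _segments_of(paths)
    pairs = set()
    kinks = []
    for c, p in enumerate(paths):
        for k in range(1, p.shape[0] - 1):
            a, v, b = p[k - 1], p[k], p[k + 1]
            u1 = v - a
            u2 = b - v
            n1 = np.linalg.norm(u1)
            n2 = np.linalg.norm(u2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            if np.dot(u1, u2) / (n1 * n2) > _KINK_COS:
                continue
            blocker = _K.triangle_blocked(a, v, b, segs, seg_chain, c,
                                          cell[0], cell[1], cell[2], periodic)
            if blocker >= 0:
                pairs.add((min(c, int(blocker)), max(c, int(blocker))))
                kinks.append((c, int(blocker), v.copy()))
    return EntanglementReport(
        n_entanglements=len(pairs), pairs=sorted(pairs), kinks=kinks,
        primitive_paths=list(paths), converged=converged)


def analyze_entanglements(positions: np.ndarray, topology: Topology,
                          box: Box | None = None,
                          tol: float = 1e-6) -> EntanglementReport:
    """Shrink chains and count entangled pairs in one call."""
    paths, conv = shrink_chains(positions, topology, box, tol=tol)
    return count_entanglements(paths, box, converged=conv)
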
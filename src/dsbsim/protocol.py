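"""Simulation protocol: SAW start, equilibration, squeeze, adhesion, strain.

The full schedule mirrors a condensate-preparation experiment:

1. chains are grown as self-avoiding random walks in a dilute box
   (ρ_start < 0.1 nm⁻³, no chain touching another);
2. first equilibration;
3. the box is squeezed in every direction at 0.02 Å/τ - slow enough to be
   quasi-static - until the target residue density ρ₀ is reached;
4. second equilibration;
5. the Z walls become adhesive (4ε wells, switched quasi-adiabatically);
6. third equilibration;
7. the cell shape oscillates (period 40,000 τ) through alternating normal
   strain and shear cycles, emulating mechanical working of the material.

Every span is scalable by a single factor so that desk-scale systems run
the complete schedule in minutes; see :meth:`Schedule.scaled`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_types import (NM, Box, ModelParams, SimState, Topology,
                         box_side_for_density, minimum_image, residue_density)
from .dynamics import run_segment, _derive_seed
from .forcefield import ForceField, Tables

__all__ = [
    "Schedule",
    "init_saw",
    "squeeze_to_density",
    "enable_wall_adhesion",
    "oscillate_box",
    "run_protocol",
    "density_sweep",
]


@dataclass
class Schedule:
    """Protocol schedule; defaults are the full-scale study conditions."""

    rho_start: float = 0.05          # nm⁻³, dilute start (< 0.1)
    equil_tau: float = 200_000.0     # τ, each of the three equilibrations
    squeeze_speed: float = 0.02      # Å/τ per box dimension
    osc_period: float = 40_000.0     # τ
    osc_amplitude: float = 0.1       # strain amplitude (not printed; default)
    n_cycles: int = 2
    osc_order: tuple = ("normal", "shear")
    check_every: int = 10            # integrator steps between contact updates

    def __post_init__(self) -> None:
        if self.rho_start >= 0.1:
            raise ValueError("rho_start must be below 0.1 nm⁻³")
        if self.squeeze_speed <= 0 or self.osc_period <= 0:
            raise ValueError("speeds and periods must be positive")

    def scaled(self, time_factor: float,
               squeeze_factor: float | None = None) -> "Schedule":
        """Compress the schedule: spans × factor, squeeze speed / factor."""
        sf = squeeze_factor if squeeze_factor is not None else time_factor
        return replace(self,
                       equil_tau=self.equil_tau * time_factor,
                       osc_period=self.osc_period * time_factor,
                       squeeze_speed=self.squeeze_speed / sf)

    @classmethod
    def desk_scale(cls) -> "Schedule":
        """The compressed schedule used for desk-scale density sweeps.

        Spans are shortened so a ~500-residue multichain system completes
        the full protocol in well under a minute of CPU; the contact-update
        stride (0.1 τ) stays far below the 10 τ switching time.
        """
        return cls(equil_tau=100.0, squeeze_speed=2.0, osc_period=60.0,
                   n_cycles=2, check_every=20)


# ---------------------------------------------------------------------------
# self-avoiding-walk initialization
# ---------------------------------------------------------------------------

def init_saw(topology: Topology, rho_start: float, seed: int,
             params: ModelParams | None = None,
             exclusion: float = 3.8, separation: float = 7.6,
             max_retries: int = 60, max_restarts: int = 200) -> SimState:
    """Grow every chain as a self-avoiding random walk in a dilute box.

    Bond length is fixed at r_bond (3.8 Å); beads of the same chain keep a
    hard-core ``exclusion`` distance, and chains are placed so that no
    inter-chain pair is within ``separation`` (beyond any contact-capture
    range) - freshly placed chains are not in contact with each other.
    """
    p = params or ModelParams()
    if rho_start >= 0.1:
        raise ValueError("rho_start must be below 0.1 nm⁻³")
    rng = np.random.default_rng(seed)
    side = box_side_for_density(topology.n_residues, rho_start) * NM
    box = Box.cube(side)
    margin = p.wall_sigma
    placed: list[np.ndarray] = []

    def far_enough(pt, others, dmin):
        if others.shape[0] == 0:
            return True
        d = minimum_image(others, pt, box)
        return bool((np.linalg.norm(np.atleast_2d(d), axis=1) >= dmin).all())

    for a, b in topology.chains:
        length = b - a
        other = (np.vstack(placed) if placed
                 else np.empty((0, 3)))
        for restart in range(max_restarts):
            start = np.array([rng.uniform(0, box.ax),
                              rng.uniform(0, box.by),
                              rng.uniform(margin, side - margin)])
            if not far_enough(start, other, separation):
                continue
            chain = [start]
            ok = True
            for _ in range(length - 1):
                accepted = False
                for _try in range(max_retries):
                    v = rng.normal(size=3)
                    v *= p.r_bond / np.linalg.norm(v)
                    cand = chain[-1] + v
                    if not (margin <= cand[2] <= side - margin):
                        continue
                    own = np.array(chain[:-1]) if len(chain) > 1 else \
                        np.empty((0, 3))
                    if not far_enough(cand, own, exclusion):
                        continue
                    if not far_enough(cand, other, separation):
                        continue
                    chain.append(cand)
                    accepted = True
                    break
                if not accepted:
                    ok = False
                    break
            if ok:
                placed.append(np.array(chain))
                break
        else:
            raise RuntimeError(
                "self-avoiding-walk placement failed; lower rho_start")
    positions = np.vstack(placed)
    velocities = rng.normal(
        0.0, math.sqrt(p.kBT / p.mass), size=positions.shape)
    return SimState(positions=positions, velocities=velocities, box=box,
                    seed=seed)


# ---------------------------------------------------------------------------
# box deformation stages
# ---------------------------------------------------------------------------

def _rescale(state: SimState, fx: float, fy: float, fz: float) -> None:
    """Affine remap of coordinates under a diagonal box rescale."""
    box = state.box
    state.positions[:, 0] *= fx
    state.positions[:, 1] *= fy
    zc = 0.5 * (box.z_lo + box.z_hi)
    state.positions[:, 2] = zc + (state.positions[:, 2] - zc) * fz
    lz = box.lz * fz
    box.ax *= fx
    box.by *= fy
    box.bx *= fx
    box.z_lo = zc - 0.5 * lz
    box.z_hi = zc + 0.5 * lz


def squeeze_to_density(state: SimState, ff: ForceField, rho_target: float,
                       schedule: Schedule | None = None) -> SimState:
    """Shrink every box dimension at the squeeze speed until ρ = ρ₀.

    Dynamics run while the cell shrinks; fractional coordinates are
    remapped affinely each sub-step.  The final density matches the target
    to well within 0.1%.
    """
    sch = schedule or Schedule()
    rho = residue_density(state)
    if rho_target < rho * (1 - 1e-9):
        raise ValueError("target density below current density")
    p = ff.params
    dt = p.dt
    k = sch.check_every
    dL = sch.squeeze_speed * dt * k          # per-dimension shrink per block
    target_vol = state.n_residues / rho_target * NM**3
    while state.box.volume > target_vol * (1 + 1e-12):
        box = state.box
        # stop exactly at the target with a final uniform rescale
        s_final = (target_vol / box.volume) ** (1.0 / 3.0)
        if min(box.ax, box.by, box.lz) - dL <= 0:
            raise ValueError("squeeze collapsed the box")
        if 1.0 - s_final <= dL / min(box.ax, box.by, box.lz):
            _rescale(state, s_final, s_final, s_final)
            run_segment(state, ff, k, check_every=k)
            break
        run_segment(state, ff, k, check_every=k)
        box = state.box
        _rescale(state, (box.ax - dL) / box.ax, (box.by - dL) / box.by,
                 (box.lz - dL) / box.lz)
    return state


def enable_wall_adhesion(state: SimState) -> SimState:
    """Make the Z walls adhesive; wells switch on quasi-adiabatically."""
    if state.registry is None:
        raise ValueError("state has no contact registry yet (run dynamics)")
    state.registry.adhesion_enabled = True
    return state


def oscillate_box(state: SimState, ff: ForceField,
                  schedule: Schedule | None = None,
                  measure=None):
    """Periodic cell deformation: alternating normal-strain / shear cycles.

    Normal cycles stretch X by 1 + A·sin(2πt/T) and compress Z by the
    inverse (volume conserved); shear cycles tilt the Y cell vector by
    A·ax·sin(2πt/T).  Each full cycle returns the cell to its initial
    shape.  ``measure(state, cycle)`` is evaluated after every cycle and
    the collected values are returned alongside the state.
    """
    sch = schedule or Schedule()
    if not 0.0 <= sch.osc_amplitude < 0.5:
        raise ValueError("oscillation amplitude would degenerate the cell")
    p = ff.params
    k = sch.check_every
    steps_per_cycle = max(int(round(sch.osc_period / p.dt)), k)
    per_cycle = []
    for cyc in range(sch.n_cycles):
        mode = sch.osc_order[cyc % len(sch.osc_order)]
        ax0, by0, lz0 = state.box.ax, state.box.by, state.box.lz
        done = 0
        phase_prev = 0.0
        while done < steps_per_cycle:
            kk = min(k, steps_per_cycle - done)
            run_segment(state, ff, kk, check_every=kk)
            done += kk
            phase = math.sin(2.0 * math.pi * done / steps_per_cycle)
            if done == steps_per_cycle:
                phase = 0.0  # exact return to the initial shape
            box = state.box
            if mode == "shear":
                bx_new = sch.osc_amplitude * ax0 * phase
                state.positions[:, 0] += (
                    (bx_new - box.bx) * state.positions[:, 1] / box.by)
                box.bx = bx_new
            else:
                f_new = 1.0 + sch.osc_amplitude * phase
                f_old = 1.0 + sch.osc_amplitude * phase_prev
                _rescale(state, f_new / f_old, 1.0, f_old / f_new)
            phase_prev = phase
        if measure is not None:
            per_cycle.append(measure(state, cyc))
    return state, per_cycle


# ---------------------------------------------------------------------------
# end-to-end runs and the density sweep
# ---------------------------------------------------------------------------

def run_protocol(topology: Topology, rho: float, seed: int,
                 schedule: Schedule | None = None,
                 params: ModelParams | None = None,
                 tables: Tables | None = None,
                 measure_cycles=None):
    """One full protocol run at density ``rho`` (ρ = 0 means free chains).

    Returns the final :class:`SimState` (and per-cycle measurements when
    ``measure_cycles`` is given).
    """
    sch = schedule or Schedule()
    p = params or ModelParams()
    ff = ForceField(topology, p, tables)
    equil_steps = int(round(sch.equil_tau / p.dt))
    if rho == 0.0:
        # infinitely dilute reference: chains never meet; no squeeze,
        # no adhesion, no strain
        state = init_saw(topology, sch.rho_start, seed, p)
        run_segment(state, ff, equil_steps, check_every=sch.check_every)
        return state, []
    state = init_saw(topology, sch.rho_start, seed, p)
    run_segment(state, ff, equil_steps, check_every=sch.check_every)
    squeeze_to_density(state, ff, rho, sch)
    run_segment(state, ff, equil_steps, check_every=sch.check_every)
    enable_wall_adhesion(state)
    run_segment(state, ff, equil_steps, check_every=sch.check_every)
    state, cycles = oscillate_box(state, ff, sch, measure=measure_cycles)
    return state, cycles


def density_sweep(topology: Topology, rho_list, repeats: int,
                  schedule: Schedule | None = None,
                  params: ModelParams | None = None,
                  tables: Tables | None = None,
                  base_seed: int = 0,
                  measure=None) -> pd.DataFrame:
    """Run the full protocol over densities × seeds and tabulate observables.

    ``measure(state, topology)`` must return a dict of scalars; by default
    the cavity report, entanglement count and chain shape metrics of the
    final frame are recorded.  Repeats use distinct derived seeds; the
    returned frame has one row per (ρ, seed).
    """
    if repeats < 1:
        raise ValueError("repeats must be ≥ 1")
    if measure is None:
        from .observables import standard_measurements as measure
    rows = []
    for ir, rho in enumerate(rho_list):
        for rep in range(repeats):
            seed = _derive_seed(base_seed, ir * 1000 + rep)
            state, _ = run_protocol(topology, rho, seed, schedule, params,
                                    tables)
            row = {"rho": rho, "seed": seed}
            row.update(measure(state, topology))
            rows.append(row)
    return pd.DataFrame(rows)


def aggregate_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± standard error per density; single repeats get NaN errors."""
    g = table.drop(columns=["seed"]).groupby("rho")
    mean = g.mean()
    sem = g.sem()
    out = mean.join(sem, rsuffix="_err").reset_index()
    return out
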
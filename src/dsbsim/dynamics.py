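"""Langevin dynamics: m r̈ = F - γ ṙ + Γ, integrated with BAOAB splitting.

The thermostat is the white-noise term alone: Γ has per-component variance
σ² = 2 γ k_B T, and γ = 2m/τ puts the dynamics in the overdamped regime.
BAOAB treats the friction/noise part of the update exactly
(v → e^{-γdt/m} v + ξ), so a free particle reproduces both the exponential
velocity decay rate γ/m and the Maxwell-Boltzmann stationary distribution
exactly; with the thermostat disabled (γ = 0, no noise) the scheme reduces
to velocity Verlet.

One τ is exactly 200 integrator steps (dt = τ/200).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _K
from .contact_dynamics import ContactRegistry, update_contacts
from .core_types import ModelParams, SimState, Topology
from .forcefield import EnergyBreakdown, ForceField

__all__ = ["IntegratorConfig", "langevin_step", "run_segment"]


@dataclass
class IntegratorConfig:
    """Integrator controls; defaults follow the model constants."""

    dt: float = 1.0 / 200.0
    gamma: float = 2.0
    mass: float = 1.0
    kBT: float = 0.35
    noise: bool = True
    seed: int = 0

    @classmethod
    def from_params(cls, params: ModelParams, seed: int = 0,
                    noise: bool = True) -> "IntegratorConfig":
        return cls(dt=params.dt, gamma=params.gamma, mass=params.mass,
                   kBT=params.kBT, noise=noise, seed=seed)


def _derive_seed(seed: int, counter: int) -> int:
    return int((seed * 1000003 + counter * 7919 + 12345) % (2**31 - 1))


def langevin_step(state: SimState, ff: ForceField,
                  config: IntegratorConfig | None = None,
                  forces: np.ndarray | None = None) -> SimState:
    """Advance the state by one integrator step (thin run_segment wrapper)."""
    return run_segment(state, ff, 1, config=config, check_every=1)


def run_segment(state: SimState, ff: ForceField, n_steps: int,
                config: IntegratorConfig | None = None,
                check_every: int = 10,
                callbacks=(), callback_every: int | None = None,
                wall_on: bool = True):
    """Run ``n_steps`` of contact-updating Langevin dynamics in place.

    Every ``check_every`` steps the Verlet pair list is refreshed if any
    bead moved more than half the skin, and the contact registry is
    advanced (λ ramps, breakage, new candidates).  Identical seeds produce
    identical trajectories.

    ``callbacks`` are called as ``cb(state)`` every ``callback_every`` steps
    (default: once at the end).
    """
    if n_steps < 0:
        raise ValueError("n_steps must be non-negative")
    if n_steps == 0:
        return state
    cfg = config or IntegratorConfig.from_params(ff.params, seed=state.seed)
    topo = ff.topology
    if state.registry is None:
        state.registry = ContactRegistry(topo, ff.params)
    reg: ContactRegistry = state.registry
    counter = getattr(state, "_rng_counter", 0)
    rng = np.random.default_rng(
        _derive_seed(cfg.seed if config is not None else state.seed, counter))
    state._rng_counter = counter + 1

    pos = state.positions
    vel = state.velocities
    n = pos.shape[0]
    frc = np.zeros_like(pos)
    ebrk = np.zeros(_K.N_ETERMS)
    pairs = flag = None
    ref_pos = None
    wall_active = wall_on or reg.adhesion_enabled

    done = 0
    while done < n_steps:
        k = min(check_every, n_steps - done)
        rebuild = (pairs is None or ref_pos is None
                   or _K.max_displacement(pos, ref_pos) > 0.5 * ff.SKIN)
        if rebuild:
            pairs, flag = ff.build_pairs(pos, state.box)
            ref_pos = pos.copy()
        update_contacts(state, topo, ff.params, pairs, flag)
        pair_cidx = reg.pair_contact_index(pairs, n)
        wall_arrays = reg.wall_lambda_arrays(n)
        wall_active = wall_on or reg.adhesion_enabled
        args = ff.kernel_args(state.box, pairs, flag, pair_cidx,
                              reg.contact_arrays(), wall_arrays,
                              wall_active)
        _K.compute_forces(pos, *args, frc, ebrk)
        if cfg.noise:
            noise = rng.standard_normal((k, n, 3))
        else:
            noise = np.zeros((1, 1, 3))
        status = _K.integrate_block(
            pos, vel, frc, k, cfg.dt, cfg.gamma, cfg.mass, cfg.kBT,
            noise, 1 if cfg.noise else 0, *args, ebrk)
        if status != 0 or not np.isfinite(frc).all():
            raise FloatingPointError(
                f"non-finite force at t={state.time:.3f} τ; "
                "check for overlapping residues or too-large steps")
        done += k
        state.time += k * cfg.dt
        if callbacks and (
                (callback_every and done % callback_every < k)
                or (not callback_every and done >= n_steps)):
            for cb in callbacks:
                cb(state)
    state._last_energy = EnergyBreakdown.from_array(ebrk)
    return state
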
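"""Reference protocols for the three thermodynamic phases.

The strings-and-binders homopolymer has three stable conformational classes
controlled by binder concentration c and affinity E_X:

* **coil** — no or weak binding: the chain is an open self-avoiding walk;
* **disordered globule** — strong binding at finite temperature: binders
  bridge the chain into a compact, liquid/glassy aggregate;
* **ordered globule** — the deep-quench strong-coupling corner
  (E_X/kT -> infinity, high c): the bead-binder packing is crystalline-like.

This module pins down one concrete, reproducible simulation protocol per
phase (chain profile, binder count and affinity, initial structure,
temperature, integration settings). The collapsed phases start from ordered
or compact packings because the spontaneous coil-to-globule collapse and,
far more so, crystallisation are much slower than any desk-scale run: the
protocols probe the stability of each phase's structure, not the kinetics
of reaching it. At finite temperature the crystalline packing is only
marginally metastable at these system sizes (its surface remodels within
hundreds of time units), so the ordered-globule reference runs athermal
(T = 0) overdamped dynamics, where it is indefinitely mechanically stable;
see docs/methods.md for the full discussion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import BindingProfile
from .simulate import (
    BinderSpec,
    SimulationParams,
    Trajectory,
    build_initial_compact,
    build_initial_ordered,
    build_initial_saw,
    ordered_binder_capacity,
    simulate_trajectory,
)

__all__ = ["PhaseProtocol", "PHASE_PROTOCOLS", "corner_system", "run_phase_corner"]

PHASE_LABELS = ("coil", "disordered_globule", "ordered_globule")


@dataclass(frozen=True)
class PhaseProtocol:
    """One reproducible simulation recipe for a phase corner."""

    affinity: float  # binding well depth, kT units
    binders: str  # "none" | "capacity" (lattice capacity of the ordered packing)
    init: str  # "saw" | "compact" | "ordered"
    temperature: float = 1.0
    friction: float = 0.5
    timestep: float = 0.01
    box_margin: float | None = None  # ordered init only; None -> builder default
    tau_total: float = 600.0  # default run length in time units
    save_every_tau: float = 5.0


PHASE_PROTOCOLS: dict[str, PhaseProtocol] = {
    # low c / zero affinity: plain self-avoiding chain
    "coil": PhaseProtocol(affinity=0.0, binders="none", init="saw"),
    # strong affinity at kT = 1: the ordered start melts in place into a
    # compact disordered aggregate within ~20 tau
    "disordered_globule": PhaseProtocol(affinity=8.0, binders="capacity", init="ordered"),
    # deep quench (E_X/kT -> inf) at higher binder concentration (snug box):
    # athermal overdamped dynamics keep the crystalline packing stable
    "ordered_globule": PhaseProtocol(
        affinity=12.0,
        binders="capacity",
        init="ordered",
        temperature=0.0,
        friction=2.0,
        timestep=0.005,
        box_margin=1.0,
        tau_total=200.0,
        save_every_tau=2.5,
    ),
}


def corner_system(label: str, n_beads: int) -> tuple[BindingProfile, BinderSpec]:
    """Homopolymer profile and binder species for a phase corner."""
    proto = PHASE_PROTOCOLS[label]
    abundance = (
        np.zeros((1, n_beads), dtype=np.int64)
        if proto.affinity == 0.0
        else np.ones((1, n_beads), dtype=np.int64)
    )
    profile = BindingProfile(abundance)
    if proto.binders == "none":
        binders = BinderSpec.none(1)
    else:
        binders = BinderSpec(
            np.array([ordered_binder_capacity(n_beads)]), np.array([proto.affinity])
        )
    return profile, binders


def _build_start(proto: PhaseProtocol, profile: BindingProfile, binders: BinderSpec, seed: int):
    if proto.init == "saw":
        return build_initial_saw(profile, seed=seed, binders=binders)
    if proto.init == "compact":
        return build_initial_compact(profile, seed=seed, binders=binders)
    if proto.init == "ordered":
        kw = {} if proto.box_margin is None else {"box_margin": proto.box_margin}
        return build_initial_ordered(profile, seed=seed, binders=binders, **kw)
    raise ValueError(f"unknown init {proto.init!r}")


def run_phase_corner(
    label: str,
    n_beads: int = 64,
    seed: int = 0,
    tau_total: float | None = None,
) -> tuple[Trajectory, BinderSpec]:
    """Simulate one phase-corner trajectory; deterministic in ``seed``."""
    proto = PHASE_PROTOCOLS[label]
    profile, binders = corner_system(label, n_beads)
    start = _build_start(proto, profile, binders, seed)
    tau = proto.tau_total if tau_total is None else tau_total
    params = SimulationParams(
        timestep=proto.timestep,
        n_steps=int(round(tau / proto.timestep)),
        friction=proto.friction,
        temperature=proto.temperature,
        seed=seed,
        save_stride=max(1, int(round(proto.save_every_tau / proto.timestep))),
    )
    return simulate_trajectory(start, profile, binders, params), binders
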
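"""Brownian/Langevin dynamics of the strings-and-binders system.

The chromatin filament is a self-avoiding bead-spring chain (FENE bonds plus
purely repulsive excluded volume); diffusing binder particles attract beads
that carry a cognate binding-site type through a short-range truncated 12-6
well whose depth is the binding affinity E_X (in kT) scaled by the bead's
site abundance. Bridging by binders spontaneously creates loops and, at
sufficient concentration c and affinity, collapses the chain.

Units: bead diameter sigma = 1, thermal energy kT = 1, time tau = 1, mass 1.
Integration is underdamped Langevin with a BAOAB splitting in a periodic
cubic box (minimum-image convention); coordinates are stored unwrapped so
chain observables are directly meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .profiles import BindingProfile

__all__ = [
    "BinderSpec",
    "SimulationParams",
    "Conformation",
    "Trajectory",
    "build_initial_saw",
    "build_initial_compact",
    "build_initial_ordered",
    "ordered_binder_capacity",
    "simulate_trajectory",
    "run_ensemble",
    "equilibrium_bond_length",
    "default_box_side",
    "write_xyz",
]

FENE_K = 30.0
FENE_R0 = 1.5
WCA_CUT = 2.0 ** (1.0 / 6.0)
MIN_SEPARATION = 0.8  # hard floor between chain beads in initial structures
BINDER_MIN_SEPARATION = 1.0  # binders start outside the steep part of their wells


@dataclass(frozen=True)
class BinderSpec:
    """Binder species: one diffusing particle type per binding-site type.

    counts[t] binders of type t are present (concentration c = count / box
    volume); affinities[t] is the binding well depth E_X in kT; binders only
    attract beads whose abundance of type t is positive. interaction_range is
    the attraction cutoff in bead diameters and must exceed hard-core contact.
    """

    counts: np.ndarray
    affinities: np.ndarray
    interaction_range: float = 1.5

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.counts, dtype=np.int64))
        a = np.atleast_1d(np.asarray(self.affinities, dtype=float))
        if c.shape != a.shape:
            raise ValueError("counts and affinities must have equal length (one per type)")
        if c.size and c.min() < 0:
            raise ValueError("binder counts must be non-negative")
        if a.size and a.min() < 0:
            raise ValueError("affinities must be non-negative (kT units)")
        if self.interaction_range <= 1.0:
            raise ValueError("interaction_range must exceed the hard-core contact distance (1 sigma)")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "affinities", a)

    @property
    def n_types(self) -> int:
        return len(self.counts)

    @property
    def n_binders(self) -> int:
        return int(self.counts.sum())

    def binder_types(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_types), self.counts)

    @classmethod
    def homogeneous(cls, n_types: int, count_per_type: int, affinity: float, interaction_range: float = 1.5):
        return cls(
            np.full(n_types, count_per_type, dtype=np.int64),
            np.full(n_types, float(affinity)),
            interaction_range,
        )

    @classmethod
    def none(cls, n_types: int = 1):
        """No binders at all (pure self-avoiding chain)."""
        return cls(np.zeros(n_types, dtype=np.int64), np.zeros(n_types))


@dataclass(frozen=True)
class SimulationParams:
    timestep: float = 0.01
    n_steps: int = 50_000
    friction: float = 0.5
    temperature: float = 1.0
    box_side: float | None = None  # None -> default_box_side()
    seed: int = 0
    save_stride: int = 1000

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")


@dataclass(frozen=True)
class Conformation:
    """One snapshot: bead and binder coordinates (unwrapped), box, time."""

    bead_positions: np.ndarray
    binder_positions: np.ndarray
    binder_types: np.ndarray
    box_side: float
    time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "bead_positions", np.ascontiguousarray(self.bead_positions, dtype=float))
        object.__setattr__(self, "binder_positions", np.ascontiguousarray(self.binder_positions, dtype=float))
        object.__setattr__(self, "binder_types", np.asarray(self.binder_types, dtype=np.int64))

    @property
    def n_beads(self) -> int:
        return self.bead_positions.shape[0]

    @property
    def n_binders(self) -> int:
        return self.binder_positions.shape[0]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.bead_positions, axis=0), axis=1)


@dataclass(frozen=True)
class Trajectory:
    """Frames sampled every ``save_stride`` steps, with provenance."""

    times: np.ndarray
    bead_frames: np.ndarray  # (n_frames, n_beads, 3)
    binder_frames: np.ndarray  # (n_frames, n_binders, 3)
    binder_types: np.ndarray
    box_side: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != self.bead_frames.shape[0]:
            raise ValueError("times and frames disagree in length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.bead_frames.shape[1]

    def frame(self, i: int) -> Conformation:
        return Conformation(
            self.bead_frames[i], self.binder_frames[i], self.binder_types, self.box_side, float(self.times[i])
        )

    def final(self) -> Conformation:
        return self.frame(self.n_frames - 1)


def equilibrium_bond_length() -> float:
    """Bond length at which the FENE pull balances the excluded-volume push.

    Solves FENE'(r) + WCA'(r) = 0 by bisection; this is the force-free rest
    geometry of a bonded pair.
    """
    from scipy.optimize import brentq

    def net_force(r):
        fene = -FENE_K * r / (1.0 - (r / FENE_R0) ** 2)
        sr6 = r**-6.0
        wca = 24.0 * (2.0 * sr6 * sr6 - sr6) / r if r < WCA_CUT else 0.0
        return fene + wca

    return float(brentq(net_force, 0.7, 1.12))


def default_box_side(n_beads: int, n_binders: int, volume_fraction: float = 0.1) -> float:
    """Box side giving the requested particle volume fraction, but never
    smaller than twice the expected coil size so a dilute chain does not
    interact with its own periodic images."""
    packing = ((n_beads + n_binders) * (np.pi / 6.0) / volume_fraction) ** (1.0 / 3.0)
    coil_extent = 2.0 * 2.5 * 0.45 * n_beads**0.588  # ~2x (2.5 Rg_coil)
    return float(max(packing, coil_extent, 4.0))


def build_initial_saw(
    profile: BindingProfile,
    seed: int = 0,
    binders: BinderSpec | None = None,
    box_side: float | None = None,
    max_restarts: int = 200,
) -> Conformation:
    """Grow an off-lattice self-avoiding chain and scatter binders in the box.

    Consecutive beads are placed at unit bond length in uniformly random
    directions, rejecting any placement that brings two beads closer than
    0.8 sigma; limited backtracking plus full restarts handle dead ends.
    Binders are placed uniformly in the box, also rejecting overlaps.
    Deterministic in ``seed``.
    """
    n = profile.n_beads
    if binders is None:
        binders = BinderSpec.none(profile.n_types)
    nb = binders.n_binders
    box = float(box_side) if box_side is not None else default_box_side(n, nb)
    rng = np.random.default_rng(seed)

    pos = None
    for _ in range(max_restarts):
        trial = np.zeros((n, 3))
        trial[0] = box / 2.0
        i = 1
        budget = 200 * n
        while i < n and budget > 0:
            placed = False
            for _attempt in range(80):
                budget -= 1
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                cand = trial[i - 1] + v
                d2 = np.sum((trial[:i] - cand) ** 2, axis=1)
                if d2.min() >= MIN_SEPARATION**2:
                    trial[i] = cand
                    placed = True
                    break
            if placed:
                i += 1
            else:
                i = max(1, i - 5)  # back off a few beads and regrow
        if i == n:
            pos = trial
            break
    if pos is None:
        raise RuntimeError(f"failed to grow a self-avoiding chain of {n} beads after {max_restarts} restarts")

    binder_pos = _place_binders(rng, pos, nb, box)
    return Conformation(pos, binder_pos, binders.binder_types(), box, 0.0)


def _place_binders(rng, bead_pos, nb, box, margin_center=None, extent=None):
    binder_pos = np.zeros((nb, 3))
    existing = bead_pos
    lo = np.zeros(3) if margin_center is None else margin_center - extent / 2.0
    span = box if extent is None else extent
    for k in range(nb):
        for _attempt in range(4000):
            cand = lo + rng.random(3) * span
            d2b = np.sum((existing - cand) ** 2, axis=1).min() if len(existing) else np.inf
            d2o = np.sum((binder_pos[:k] - cand) ** 2, axis=1).min() if k else np.inf
            if min(d2b, d2o) >= BINDER_MIN_SEPARATION**2:
                binder_pos[k] = cand
                break
        else:
            raise RuntimeError(
                f"could not place binder {k} without overlap; box_side={box} is likely too small"
            )
    return binder_pos


def build_initial_compact(
    profile: BindingProfile,
    seed: int = 0,
    binders: BinderSpec | None = None,
    box_side: float | None = None,
    spacing: float | None = None,
) -> Conformation:
    """Compact initial state: the chain threads a boustrophedon path on a
    cubic lattice, binders are scattered in a shell around it.

    Useful to start runs in collapsed regimes near their equilibrium instead
    of waiting out a slow coil-to-globule collapse; the stationary state of
    the dynamics does not depend on the initial condition.
    """
    n = profile.n_beads
    if binders is None:
        binders = BinderSpec.none(profile.n_types)
    nb = binders.n_binders
    a = spacing if spacing is not None else equilibrium_bond_length()
    side = int(np.ceil(n ** (1.0 / 3.0)))
    # serpentine over one layer; odd layers are traversed in reverse so that
    # consecutive path sites are always lattice neighbours
    layer = [
        (x, y)
        for y in range(side)
        for x in (range(side) if y % 2 == 0 else range(side - 1, -1, -1))
    ]
    pos = np.zeros((n, 3))
    idx = 0
    for z in range(side):
        for x, y in (layer if z % 2 == 0 else reversed(layer)):
            if idx < n:
                pos[idx] = (x * a, y * a, z * a)
                idx += 1
    extent = side * a
    box = float(box_side) if box_side is not None else extent + 6.0
    center = pos.mean(axis=0)
    pos += box / 2.0 - center
    rng = np.random.default_rng(seed)
    binder_pos = _place_binders(
        rng, pos, nb, box, margin_center=pos.mean(axis=0), extent=min(extent + 4.0, box)
    )
    return Conformation(pos, binder_pos, binders.binder_types(), box, 0.0)


def ordered_binder_capacity(n_beads: int) -> int:
    """Number of lattice binder sites in :func:`build_initial_ordered`."""
    L = max(2, int(np.ceil(n_beads ** (1.0 / 3.0))))
    K = int(np.ceil(n_beads / L**2))
    per_layer = sum(1 for i in range(L - 1) for j in range(L - 1) if (i + j) % 2 == 0)
    return (K + 1) * per_layer


def build_initial_ordered(
    profile: BindingProfile,
    seed: int = 0,
    binders: BinderSpec | None = None,
    box_side: float | None = None,
    box_margin: float = 6.0,
) -> Conformation:
    """Crystalline mixed initial state: serpentine bead layers interleaved
    with square-lattice binder layers.

    Bead layers (in-plane spacing 1 sigma) are stacked 1.6 sigma apart with
    binder layers in the gaps and on both surfaces; binders sit on
    every-other half-offset site, giving each interior binder eight cognate
    beads near the attraction minimum. Interlayer chain crossings route
    through an extra bead outside the slab face so no bond exceeds ~1.13
    sigma. This is a mechanically consistent ordered packing: at deep
    binding affinity the dynamics keep it crystalline (the ordered-globule
    branch), at moderate affinity it melts into a disordered globule.
    Binders beyond the lattice capacity are scattered in the box at random.
    """
    n = profile.n_beads
    if binders is None:
        binders = BinderSpec.none(profile.n_types)
    nb = binders.n_binders
    # stress-free spacings: bonds at the FENE+WCA rest length, rows where
    # excluded volume vanishes, binder-bead contacts at the 12-6 minimum
    ax = equilibrium_bond_length()  # along-row bond spacing
    ay = WCA_CUT  # row spacing (zero repulsion)
    contact = WCA_CUT  # target binder-bead distance
    h = float(np.sqrt(contact**2 - (ax / 2.0) ** 2 - (ay / 2.0) ** 2))
    dz = 2.0 * h
    L = max(2, int(np.ceil(n ** (1.0 / 3.0))))
    K = int(np.ceil(n / L**2))

    layer = [
        (x, y)
        for y in range(L)
        for x in (range(L) if y % 2 == 0 else range(L - 1, -1, -1))
    ]
    path = []
    for k in range(K):
        pts = layer if k % 2 == 0 else list(reversed(layer))
        if k > 0:
            # crossing bead outside the slab face, halfway between layers
            xe, ye = pts[0]
            xs = xe + 0.8 / ax if xe >= L - 1 else xe - 0.8 / ax
            path.append((xs * ax, ye * ay, (k - 0.5) * dz))
        for x, y in pts:
            path.append((x * ax, y * ay, k * dz))
    pos = np.array(path[:n])
    if len(pos) < n:  # pragma: no cover - capacity always >= n by construction
        raise RuntimeError("ordered lattice smaller than chain")

    sites = []
    for k in range(K + 1):
        z = -h + k * dz  # gap below layer 0, between layers, above layer K-1
        for i in range(L - 1):
            for j in range(L - 1):
                if (i + j) % 2 == 0:
                    sites.append(((i + 0.5) * ax, (j + 0.5) * ay, z))
    sites = np.array(sites) if sites else np.zeros((0, 3))

    extent = max(L * ay, K * dz) + 2 * h
    box = float(box_side) if box_side is not None else extent + box_margin
    shift = box / 2.0 - pos.mean(axis=0)
    pos = pos + shift
    n_lattice = min(nb, len(sites))
    binder_pos = np.zeros((nb, 3))
    binder_pos[:n_lattice] = sites[:n_lattice] + shift
    rng = np.random.default_rng(seed)
    if nb > n_lattice:
        extra = _place_binders(
            rng, np.vstack([pos, binder_pos[:n_lattice]]), nb - n_lattice, box
        )
        binder_pos[n_lattice:] = extra
    jitter = rng.normal(0.0, 1e-3, size=(n + nb, 3))  # break exact lattice symmetry
    pos += jitter[:n]
    binder_pos += jitter[n:]
    return Conformation(pos, binder_pos, binders.binder_types(), box, 0.0)


@njit(cache=True)
def _compute_forces(pos, n_beads, depth, rc_attr, box, forces):  # pragma: no cover - numba
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    rc_rep2 = WCA_CUT * WCA_CUT
    rc_attr2 = rc_attr * rc_attr
    r02 = FENE_R0 * FENE_R0
    hbox = 0.5 * box
    # FENE bonds between consecutive beads
    for i in range(n_beads - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return i  # bond beyond maximum extension: signal blow-up at bond i
        coef = -FENE_K / (1.0 - r2 / r02)
        forces[i, 0] += coef * dx
        forces[i, 1] += coef * dy
        forces[i, 2] += coef * dz
        forces[i + 1, 0] -= coef * dx
        forces[i + 1, 1] -= coef * dy
        forces[i + 1, 2] -= coef * dz
    # pairwise non-bonded
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > hbox or dx < -hbox:
                dx -= box * np.floor(dx / box + 0.5)
            if dy > hbox or dy < -hbox:
                dy -= box * np.floor(dy / box + 0.5)
            if dz > hbox or dz < -hbox:
                dz -= box * np.floor(dz / box + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_attr2:
                continue
            eps_attr = 0.0
            if i < n_beads and j >= n_beads:
                eps_attr = depth[j - n_beads, i]
            elif j < n_beads and i >= n_beads:
                eps_attr = depth[i - n_beads, j]
            if eps_attr > 0.0:
                if r2 < 0.25:
                    r2 = 0.25  # clamp to avoid force overflow on rare deep overlap
                sr2 = 1.0 / r2
                sr6 = sr2 * sr2 * sr2
                fpair = 24.0 * eps_attr * sr6 * (2.0 * sr6 - 1.0) * sr2
            else:
                if r2 >= rc_rep2:
                    continue
                if r2 < 0.25:
                    r2 = 0.25
                sr2 = 1.0 / r2
                sr6 = sr2 * sr2 * sr2
                fpair = 24.0 * sr6 * (2.0 * sr6 - 1.0) * sr2
            forces[i, 0] += fpair * dx
            forces[i, 1] += fpair * dy
            forces[i, 2] += fpair * dz
            forces[j, 0] -= fpair * dx
            forces[j, 1] -= fpair * dy
            forces[j, 2] -= fpair * dz
    return -1


@njit(cache=True)
def _run_langevin(pos, vel, n_beads, depth, rc_attr, box, dt, gamma, kT, n_steps, save_stride, seed):
    # pragma: no cover - numba
    np.random.seed(seed)
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    n_frames = n_steps // save_stride + 1
    frames = np.empty((n_frames, n, 3))
    times = np.empty(n_frames)
    frames[0] = pos
    times[0] = 0.0
    err = _compute_forces(pos, n_beads, depth, rc_attr, box, forces)
    if err >= 0:
        return frames[:1], times[:1], 0
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kT * (1.0 - c1 * c1))
    fi = 1
    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k]
                pos[i, k] += half * vel[i, k]
        if kT > 0.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * np.random.normal()
        else:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k]
        for i in range(n):
            for k in range(3):
                pos[i, k] += half * vel[i, k]
        err = _compute_forces(pos, n_beads, depth, rc_attr, box, forces)
        if err >= 0:
            return frames[:fi], times[:fi], step
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * forces[i, k]
        if step % save_stride == 0:
            ok = True
            for i in range(n):
                for k in range(3):
                    if not np.isfinite(pos[i, k]):
                        ok = False
            if not ok:
                return frames[:fi], times[:fi], step
            frames[fi] = pos
            times[fi] = step * dt
            fi += 1
    return frames[:fi], times[:fi], -1


class SimulationBlowupError(RuntimeError):
    pass


def simulate_trajectory(
    start: Conformation,
    profile: BindingProfile,
    binders: BinderSpec,
    params: SimulationParams,
) -> Trajectory:
    """Run Langevin dynamics from ``start``; deterministic in ``params.seed``.

    Raises
    ------
    SimulationBlowupError
        If any coordinate becomes non-finite or a bond exceeds its maximum
        extension (1.5 sigma); the message reports the step index and advises
        a smaller timestep.
    """
    n = profile.n_beads
    if start.n_beads != n:
        raise ValueError(f"start has {start.n_beads} beads but profile has {n}")
    if binders.n_types != profile.n_types:
        raise ValueError(f"binders cover {binders.n_types} types but profile has {profile.n_types}")
    if start.n_binders != binders.n_binders:
        raise ValueError(f"start has {start.n_binders} binders but spec requires {binders.n_binders}")
    box = start.box_side

    btypes = binders.binder_types()
    depth = binders.affinities[btypes][:, None] * (profile.abundance[btypes] > 0) * profile.abundance[btypes]
    depth = np.ascontiguousarray(depth, dtype=float)  # (n_binders, n_beads)

    pos = np.vstack([start.bead_positions, start.binder_positions]).astype(float)
    rng = np.random.default_rng(params.seed)
    if params.temperature > 0:
        vel = rng.normal(0.0, np.sqrt(params.temperature), size=pos.shape)
    else:
        vel = np.zeros_like(pos)

    kernel_seed = int(rng.integers(2**31 - 1))
    frames, times, err_step = _run_langevin(
        pos,
        vel,
        n,
        depth,
        float(binders.interaction_range),
        float(box),
        float(params.timestep),
        float(params.friction),
        float(params.temperature),
        int(params.n_steps),
        int(params.save_stride),
        kernel_seed,
    )
    if err_step >= 0:
        raise SimulationBlowupError(
            f"simulation blew up at step {err_step} (non-finite coordinate or bond > {FENE_R0} sigma); "
            f"try a smaller timestep than {params.timestep}"
        )
    times = times + start.time
    if len(times) > 1 and times[0] == times[1]:  # n_steps < save_stride edge
        times = times[:1]
        frames = frames[:1]
    return Trajectory(
        times=times,
        bead_frames=frames[:, :n, :],
        binder_frames=frames[:, n:, :],
        binder_types=btypes,
        box_side=box,
        provenance={
            "params": params,
            "binders": binders,
            "seed": params.seed,
            "n_beads": n,
        },
    )


def run_ensemble(
    profile: BindingProfile,
    binders: BinderSpec,
    params: SimulationParams,
    n_replicas: int,
    seed_list: list[int],
    *,
    start_builder=build_initial_saw,
) -> list[Trajectory]:
    """Independent replicas, one per seed; replica i depends only on seed_list[i]."""
    if len(seed_list) != n_replicas or n_replicas < 1:
        raise ValueError("need len(seed_list) == n_replicas >= 1")
    if len(set(seed_list)) != len(seed_list):
        raise ValueError("duplicate seeds would make the ensemble degenerate")
    out = []
    for s in seed_list:
        start = start_builder(profile, seed=int(s), binders=binders, box_side=params.box_side)
        p = SimulationParams(
            timestep=params.timestep,
            n_steps=params.n_steps,
            friction=params.friction,
            temperature=params.temperature,
            box_side=params.box_side,
            seed=int(s),
            save_stride=params.save_stride,
        )
        out.append(simulate_trajectory(start, profile, binders, p))
    return out


def potential_energy(conf: Conformation, profile: BindingProfile, binders: BinderSpec) -> dict:
    """Per-term potential energy of a snapshot (FENE, excluded volume,
    bead-binder attraction); mainly a diagnostic for sanity checks."""
    box = conf.box_side
    bead = conf.bead_positions
    n = conf.n_beads

    def mi(d):
        return d - box * np.floor(d / box + 0.5)

    bl = conf.bond_lengths()
    if np.any(bl >= FENE_R0):
        raise ValueError("bond beyond FENE maximum extension")
    e_fene = float(np.sum(-0.5 * FENE_K * FENE_R0**2 * np.log(1.0 - (bl / FENE_R0) ** 2)))

    allpos = np.vstack([bead, conf.binder_positions])
    m = len(allpos)
    btypes = conf.binder_types
    depth = np.zeros((conf.n_binders, n))
    if conf.n_binders:
        depth = binders.affinities[btypes][:, None] * profile.abundance[btypes]
    e_rep = 0.0
    e_att = 0.0
    rc = binders.interaction_range
    for i in range(m):
        d = mi(allpos[i + 1 :] - allpos[i])
        r = np.sqrt(np.sum(d * d, axis=1))
        for jj, rij in enumerate(r):
            j = i + 1 + jj
            eps_attr = 0.0
            if i < n <= j:
                eps_attr = depth[j - n, i]
            elif j < n <= i:
                eps_attr = depth[i - n, j]
            if eps_attr > 0:
                if rij < rc:
                    sr6 = rij**-6.0
                    rc6 = rc**-6.0
                    e_att += 4 * eps_attr * ((sr6 * sr6 - sr6) - (rc6 * rc6 - rc6))
            elif rij < WCA_CUT:
                sr6 = rij**-6.0
                e_rep += 4 * (sr6 * sr6 - sr6) + 1.0
    return {"fene": e_fene, "repulsion": float(e_rep), "attraction": float(e_att)}


def read_xyz(path, box_side: float = 1e9) -> Trajectory:
    """Read a trajectory written by :func:`write_xyz` (records starting with
    'B' are binders, their suffix is the binder type)."""
    times, bead_frames, binder_frames, binder_types = [], [], [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_total = int(lines[i].strip())
        comment = lines[i + 1]
        t = 0.0
        for tok in comment.split():
            if tok.startswith("time="):
                t = float(tok[5:])
        beads, binders_pos, btypes = [], [], []
        for rec in lines[i + 2 : i + 2 + n_total]:
            parts = rec.split()
            xyz = [float(v) for v in parts[1:4]]
            if parts[0].startswith("B"):
                binders_pos.append(xyz)
                btypes.append(int(parts[0][1:]) if parts[0][1:] else 0)
            else:
                beads.append(xyz)
        times.append(t)
        bead_frames.append(beads)
        binder_frames.append(binders_pos)
        binder_types = btypes
        i += 2 + n_total
    return Trajectory(
        times=np.array(times),
        bead_frames=np.array(bead_frames),
        binder_frames=np.array(binder_frames) if binder_frames and binder_frames[0] else np.zeros((len(times), 0, 3)),
        binder_types=np.array(binder_types or [], dtype=np.int64),
        box_side=box_side,
    )


def write_xyz(trajectory: Trajectory, path, comment_extra: str = "") -> None:
    """XYZ trajectory: bead records ('C') then binder records ('O<type>')."""
    with open(path, "w") as fh:
        for f in range(trajectory.n_frames):
            n_total = trajectory.n_beads + trajectory.binder_frames.shape[1]
            fh.write(f"{n_total}\n")
            fh.write(f"time={trajectory.times[f]:.6g} {comment_extra}\n")
            for x, y, z in trajectory.bead_frames[f]:
                fh.write(f"C {x:.5f} {y:.5f} {z:.5f}\n")
            for (x, y, z), t in zip(trajectory.binder_frames[f], trajectory.binder_types):
                fh.write(f"B{t} {x:.5f} {y:.5f} {z:.5f}\n")
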
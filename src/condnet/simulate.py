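"""Minimal NVT/NVE molecular-dynamics engine.

Two integration paths share one interface:

* a compiled fast path (:mod:`condnet._kernels`) for single-type
  Lennard-Jones systems in reduced units — used for the vapor/liquid/solid
  state-point runs;
* a generic NumPy path for bonded, multi-type, charged topologies (the
  toy condensate replicas), with a skin-buffered nonbonded pair cache.

The default thermostat is Langevin (BAOAB splitting), which is
unconditionally stable at the time steps used here and samples the same
NVT ensemble as the Nose-Hoover thermostat; a single Nose-Hoover variant
is provided for parity with common MD protocols.  With the thermostat off
the integrator is plain velocity Verlet (NVE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units as _units
from . import _kernels
from .energy import (_cached_tables, candidate_pairs, filter_excluded,
                     total_energy)
from .forcefield import ForceField
from .topology import Frame, Topology, Trajectory, mutate_neutralize  # noqa: F401


@dataclass
class SimSpec:
    """Integration parameters for one run."""

    dt: float
    n_steps: int
    thermostat: str | None = "langevin"   # "langevin" | "nose_hoover" | None
    T_target: float = 1.0
    damping: float = 0.5                  # thermostat time constant
    seed: int = 0
    dump_every: int = 100
    neighbor_skin: float = 0.4
    equil_steps: int = 0
    nlist_every: int = 10                 # generic path: pair-cache refresh

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt must be positive and n_steps >= 1")
        if self.damping <= 0:
            raise ValueError("damping must be positive")
        if self.thermostat not in ("langevin", "nose_hoover", None):
            raise ValueError(f"unknown thermostat {self.thermostat!r}")


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def initialize_configuration(topo: Topology, box, mode: str, seed: int = 0,
                             min_sep: float = 0.85,
                             max_attempts: int = 400) -> Frame:
    """Initial bead coordinates: cubic ``lattice`` or ``random_nonoverlapping``.

    ``min_sep`` is the smallest allowed minimum-image separation (same
    length units as the box).  Placement is per bead; structured molecules
    are laid out by the synthetic-data builders instead.
    """
    box = np.asarray(box, dtype=float).reshape(3)
    n = topo.n_beads
    rng = np.random.default_rng(seed)
    if mode == "lattice":
        ncell = int(np.ceil(n ** (1.0 / 3.0)))
        spacing = box / ncell
        sites = np.array([(i, j, k) for i in range(ncell)
                          for j in range(ncell) for k in range(ncell)][:n],
                         dtype=float)
        coords = sites * spacing
    elif mode == "random_nonoverlapping":
        coords = _rsa(n, box, min_sep, rng, max_attempts)
    else:
        raise ValueError(f"unknown init mode {mode!r}")
    return Frame.from_unwrapped(coords, box, time=0.0)


def _rsa(n: int, box: np.ndarray, min_sep: float, rng, max_attempts: int):
    """Random sequential addition with a periodic cell grid."""
    nc = np.maximum((box / min_sep).astype(int), 1)
    grid: dict[tuple[int, int, int], list[int]] = {}
    pts = np.empty((n, 3))
    ms2 = min_sep * min_sep
    for k in range(n):
        for _ in range(max_attempts):
            p = rng.random(3) * box
            c = tuple((p / box * nc).astype(int) % nc)
            ok = True
            for ox in (-1, 0, 1):
                for oy in (-1, 0, 1):
                    for oz in (-1, 0, 1):
                        cc = ((c[0] + ox) % nc[0], (c[1] + oy) % nc[1],
                              (c[2] + oz) % nc[2])
                        for idx in grid.get(cc, ()):
                            d = pts[idx] - p
                            d -= box * np.round(d / box)
                            if d @ d < ms2:
                                ok = False
                                break
                        if not ok:
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                pts[k] = p
                grid.setdefault(c, []).append(k)
                break
        else:
            achieved = k / float(np.prod(box))
            raise RuntimeError(
                f"random placement stalled after {k}/{n} beads "
                f"(achieved number density {achieved:.4g} at min_sep {min_sep})")
    return pts


def relax_configuration(frame: Frame, topo: Topology, ff: ForceField,
                        steps: int = 200, max_step: float = 0.5) -> Frame:
    """Displacement-capped steepest descent to remove bad contacts.

    Each iteration moves every bead along its force, with the largest
    displacement capped at ``max_step`` — the usual way of making a
    randomly assembled configuration integrable before dynamics.
    """
    x = (frame.unwrapped if frame.images is not None else frame.coords).copy()
    box = frame.box
    for _ in range(steps):
        fr = Frame.from_unwrapped(x, box)
        br = total_energy(fr, topo, ff, forces=True)
        f = br.forces
        fmax = np.abs(f).max()
        if fmax == 0:
            break
        scale = min(max_step / fmax, 1e-3)
        x += scale * f
        if not br.overlap and fmax * scale < 1e-4:
            break
    return Frame.from_unwrapped(x, box, time=frame.time)


def thermal_velocities(n: int, T: float, masses: np.ndarray, units: str,
                       rng) -> np.ndarray:
    """Maxwell-Boltzmann velocities with the center-of-mass drift removed."""
    kb = _units.boltzmann(units)
    m_eff = masses * _units.mvv_to_energy(units)
    v = rng.standard_normal((n, 3)) * np.sqrt(kb * T / m_eff)[:, None]
    v -= (m_eff[:, None] * v).sum(axis=0) / m_eff.sum()
    return v


# ---------------------------------------------------------------------------
# run dispatch
# ---------------------------------------------------------------------------


def run_nvt(frame: Frame, topo: Topology, ff: ForceField, spec: SimSpec,
            velocities: np.ndarray | None = None) -> Trajectory:
    """Integrate and return the production trajectory.

    Frames are dumped every ``spec.dump_every`` steps after
    ``spec.equil_steps`` equilibration steps.  The kinetic-temperature /
    energy log is attached as ``trajectory.thermo`` (a DataFrame).
    Identical inputs and seed give identical trajectories.
    """
    single_lj = (
        len(ff.bead_types) == 1
        and ff.units == "reduced"
        and len(topo.bonds) == 0
        and not np.any(topo.charges)
        and next(iter(ff.bead_types.values())).sigma == 1.0
        and next(iter(ff.bead_types.values())).epsilon == 1.0
    )
    if single_lj:
        return _run_lj_fast(frame, topo, ff, spec, velocities)
    return _run_generic(frame, topo, ff, spec, velocities)


def _block_size(dump_every: int, cap: int = 1000) -> int:
    if dump_every <= cap:
        return dump_every
    for k in range(-(-dump_every // cap), dump_every + 1):
        if dump_every % k == 0:
            return dump_every // k
    return dump_every


def _run_lj_fast(frame, topo, ff, spec, velocities):
    n = frame.n_beads
    rng = np.random.default_rng(spec.seed)
    x = frame.unwrapped if frame.images is not None else frame.coords
    x = np.ascontiguousarray(x, dtype=np.float64)
    box = np.ascontiguousarray(frame.box)
    if velocities is None:
        velocities = thermal_velocities(n, spec.T_target, np.ones(n),
                                        "reduced", rng)
    v = np.ascontiguousarray(velocities, dtype=np.float64)
    bt = next(iter(ff.bead_types.values()))
    rc = ff.lj_cutoff(bt, bt)
    # the compiled path integrates Langevin dynamics; the damping time
    # constant maps to friction gamma = 1/damping
    gamma = 0.0 if spec.thermostat is None else 1.0 / spec.damping
    c1 = float(np.exp(-gamma * spec.dt)) if gamma > 0 else 1.0
    c2 = float(np.sqrt((1.0 - c1 * c1) * spec.T_target)) if gamma > 0 else 0.0

    img = np.floor(x / box).astype(np.int64)
    xw = x - img * box
    ids = np.arange(n)
    empty_noise = np.empty((0, n, 3))

    def advance(steps: int) -> float:
        if gamma > 0:
            noise = rng.standard_normal((steps, n, 3))
        else:
            noise = empty_noise
        return _kernels.run_lj_block(
            xw, img, v, ids, box, spec.dt, c1, c2, noise, steps,
            rc, spec.neighbor_skin, ff.lj_shift)

    b = _block_size(spec.dump_every)
    done = 0
    while done < spec.equil_steps:
        advance(min(b, spec.equil_steps - done))
        done += b

    frames: list[Frame] = []
    rows = []
    n_dumps = spec.n_steps // spec.dump_every
    for d in range(n_dumps):
        for _ in range(spec.dump_every // b):
            epot = advance(b)
        step = (d + 1) * spec.dump_every
        t = step * spec.dt
        pos = np.empty((n, 3))
        pos[ids] = xw + img * box
        frames.append(Frame.from_unwrapped(pos, box, time=t))
        ekin = 0.5 * float((v * v).sum())
        if not np.isfinite(epot) or not np.isfinite(ekin):
            raise RuntimeError(
                f"energy diverged by step {step} (epot={epot!r}, "
                f"ekin={ekin!r}); reduce dt or relax the configuration")
        rows.append((step, t, 2.0 * ekin / (3.0 * n), epot, epot + ekin))
    rem = spec.n_steps - n_dumps * spec.dump_every
    if rem:
        advance(rem)
    traj = Trajectory(frames, frame_interval=spec.dump_every * spec.dt)
    traj.thermo = pd.DataFrame(rows, columns=["step", "time", "T_kin",
                                              "epot", "etot"])
    traj.seed = spec.seed
    return traj


def _run_generic(frame, topo, ff, spec, velocities):
    n = frame.n_beads
    rng = np.random.default_rng(spec.seed)
    tables = _cached_tables(topo, ff)
    kb = _units.boltzmann(ff.units)
    m_eff = tables.masses * _units.mvv_to_energy(ff.units)
    x = (frame.unwrapped if frame.images is not None else frame.coords).copy()
    box = frame.box
    if velocities is None:
        velocities = thermal_velocities(n, spec.T_target, tables.masses,
                                        ff.units, rng)
    v = velocities.copy()

    def refresh_pairs(xc):
        fr = Frame.from_unwrapped(xc, box)
        i, j = candidate_pairs(fr, tables, extra=spec.neighbor_skin)
        return filter_excluded(i, j, topo, ff.exclusion_depth)

    def forces(xc, pairs):
        fr = Frame.from_unwrapped(xc, box)
        br = total_energy(fr, topo, ff, forces=True, pairs=pairs)
        return br.forces, br.total

    pairs = refresh_pairs(x)
    f, epot = forces(x, pairs)

    gamma = 1.0 / spec.damping
    c1 = np.exp(-gamma * spec.dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kb * spec.T_target / m_eff)[:, None]
    half = 0.5 * spec.dt
    inv_m = (1.0 / m_eff)[:, None]

    use_langevin = spec.thermostat == "langevin"
    use_nh = spec.thermostat == "nose_hoover"
    g_dof = 3.0 * n
    Q = g_dof * kb * spec.T_target * spec.damping ** 2
    xi = 0.0

    frames: list[Frame] = []
    rows = []
    total_steps = spec.equil_steps + spec.n_steps
    for step in range(1, total_steps + 1):
        if use_nh:
            ke2 = float((m_eff * (v * v).sum(axis=1)).sum())
            xi += half * (ke2 - g_dof * kb * spec.T_target) / Q
            v *= np.exp(-half * xi)
        v += half * f * inv_m
        x += 0.5 * spec.dt * v
        if use_langevin:
            v = c1 * v + c2 * rng.standard_normal((n, 3))
        x += 0.5 * spec.dt * v
        if step % spec.nlist_every == 0:
            pairs = refresh_pairs(x)
        f, epot = forces(x, pairs)
        v += half * f * inv_m
        if use_nh:
            v *= np.exp(-half * xi)
            ke2 = float((m_eff * (v * v).sum(axis=1)).sum())
            xi += half * (ke2 - g_dof * kb * spec.T_target) / Q
        prod_step = step - spec.equil_steps
        if prod_step > 0 and prod_step % spec.dump_every == 0:
            t = prod_step * spec.dt
            frames.append(Frame.from_unwrapped(x, box, time=t))
            ekin = 0.5 * float((m_eff * (v * v).sum(axis=1)).sum())
            if not np.isfinite(epot) or not np.isfinite(ekin):
                raise RuntimeError(
                    f"energy diverged by step {step} (epot={epot!r}, "
                    f"ekin={ekin!r}); reduce dt or relax the configuration")
            rows.append((prod_step, t, 2.0 * ekin / (g_dof * kb), epot,
                         epot + ekin))
    traj = Trajectory(frames, frame_interval=spec.dump_every * spec.dt)
    traj.thermo = pd.DataFrame(rows, columns=["step", "time", "T_kin",
                                              "epot", "etot"])
    traj.seed = spec.seed
    return traj
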
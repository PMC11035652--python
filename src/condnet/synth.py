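"""Synthetic fixtures: LJ state points, lattices, toy condensates,
stochastic walks, FRAP curves, and scattering profiles.

Every generator is deterministic given its seed and returns the ground
truth it was built from, so downstream analyses can be validated
closed-loop without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcefield import (BeadType, BondClass, AngleClass, DihedralClass,
                         QuadDihedralClass, ForceField, lj_forcefield)
from .simulate import SimSpec, initialize_configuration
from .scattering import ScatteringProfile
from .frap import frap_model
from .topology import (Frame, MoleculeTemplate, Topology, Trajectory,
                       single_type_topology)

#: reduced-unit state points (density, temperature) of the three pure
#: Lennard-Jones phases used as structural references
LJ_STATE_POINTS = {
    "vapor": (0.01, 1.0),
    "liquid": (0.8, 1.0),
    "solid": (1.5, 0.758),
}

#: diameter of the pentamerization-domain bead (Å)
PD_SIGMA = 53.0


def make_lj_state(phase: str, n: int, seed: int = 0,
                  n_steps: int = 200_000, equil_steps: int = 10_000,
                  dump_every: int = 2_000):
    """Initial configuration + run parameters for a pure LJ phase.

    Vapor and liquid are placed randomly without overlaps at reduced
    densities 0.01 and 0.8; the solid starts on an FCC lattice at density
    1.5 (particle count rounded to the nearest perfect 4·c³).  The run
    spec uses dt = 0.005 τ and a 0.5 τ thermostat damping time.
    """
    if phase not in LJ_STATE_POINTS:
        raise ValueError(f"unknown phase {phase!r}")
    if n < 32:
        raise ValueError("need at least 32 particles")
    rho, temp = LJ_STATE_POINTS[phase]
    skin = {"vapor": 1.0, "liquid": 0.4, "solid": 0.35}[phase]
    if phase == "solid":
        ncell = max(2, round((n / 4) ** (1.0 / 3.0)))
        n = 4 * ncell ** 3
        box = (n / rho) ** (1.0 / 3.0)
        frame, _ = make_fcc(ncell, box / ncell)
        topo = single_type_topology(n)
    else:
        box = (n / rho) ** (1.0 / 3.0)
        topo = single_type_topology(n)
        frame = initialize_configuration(topo, [box] * 3,
                                         "random_nonoverlapping", seed=seed,
                                         min_sep=0.85 if phase == "liquid" else 0.95)
    spec = SimSpec(dt=0.005, n_steps=n_steps, thermostat="langevin",
                   T_target=temp, damping=0.5, seed=seed,
                   dump_every=dump_every, neighbor_skin=skin,
                   equil_steps=equil_steps)
    return frame, topo, spec


def make_fcc(n_cells: int, lattice_constant: float):
    """Periodic FCC crystal and its ground-truth shell structure.

    Nearest-neighbor distance a/√2 with coordination 12 (the close-packed
    reference; the testable neighbor count is shared by all close-packed
    lattices).
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells per dimension")
    a = float(lattice_constant)
    basis = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    cells = np.array([(i, j, k) for i in range(n_cells)
                      for j in range(n_cells) for k in range(n_cells)],
                     dtype=float)
    coords = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    box = np.array([n_cells * a] * 3)
    truth = {"nn_distance": a / math.sqrt(2.0), "coordination": 12,
             "second_shell": a}
    return Frame.from_unwrapped(coords, box), truth


# ---------------------------------------------------------------------------
# toy condensate
# ---------------------------------------------------------------------------

_ARM_REGIONS = (
    ("A0", -1), ("A0", -1), ("A0", -1),
    ("linker", 0), ("linker", 0),
    ("A1", -1), ("A1", -1), ("A1", -1),
    ("linker", 0), ("linker", 0),
    ("A2", -1), ("A2", -1), ("A2", -1),
)

_PEPTIDE_CHARGES = (1, 0, 1, 0, 1, 0, 1, 0, 0, 0)


def toy_forcefield() -> ForceField:
    """Force field for the reduced pentamer+peptide replica.

    Interaction strengths are package-chosen placeholders tuned only to
    produce association at the simulated temperature (the systematically
    optimized per-type parameters are not public); geometry (bead sizes,
    charges, screening) follows the coarse-grained model conventions:
    dielectric 80, κ = 0.1 Å⁻¹, LJ cutoff 2.5 σ_ij.  The PD-PD cutoff is
    capped at 75 Å so it stays inside the minimum-image radius of the
    reduced box.
    """
    beads = {
        "PD": BeadType("PD", "domain", sigma=PD_SIGMA, epsilon=0.35,
                       charge=0, mass=47544.8),
        "acid": BeadType("acid", "charged", sigma=6.0, epsilon=0.20,
                         charge=-1, mass=110.0),
        "base": BeadType("base", "charged", sigma=6.5, epsilon=0.20,
                         charge=1, mass=140.0),
        "small": BeadType("small", "small", sigma=5.0, epsilon=0.15,
                          charge=0, mass=90.0),
    }
    return ForceField(
        bead_types=beads,
        lj_cutoff_factor=2.5,
        dielectric=80.0,
        kappa=0.1,
        elec_cutoff_default=24.1,
        bonds={
            "arm": BondClass(K=10.0, b0=6.0),
            "pd_arm": BondClass(K=10.0, b0=0.5 * (PD_SIGMA + 6.0) * 0.85),
            "pep": BondClass(K=10.0, b0=6.5),
        },
        angles={
            "chain": AngleClass(K=2.0, theta0=math.pi),
        },
        dihedrals={
            "chain": DihedralClass(K=(0.3, 0.15, 0.1), phi=(0.0, 0.0, 0.0)),
        },
        quad_dihedrals={
            "arm_anchor": QuadDihedralClass(K=1.0, phi0=0.0),
        },
        units="real",
        pair_cutoff_override={frozenset(("PD",)): 75.0},
    )


def _pentamer_template(n_arms: int = 5) -> MoleculeTemplate:
    types = ["PD"]
    regions = ["PD"]
    charges = [0]
    bonds = []
    angles = []
    dihedrals = []
    arm_len = len(_ARM_REGIONS)
    for arm in range(n_arms):
        base = 1 + arm * arm_len
        for k, (reg, q) in enumerate(_ARM_REGIONS):
            types.append("acid" if q else "small")
            regions.append(reg)
            charges.append(q)
        bonds.append((0, base, "pd_arm"))
        for k in range(arm_len - 1):
            bonds.append((base + k, base + k + 1, "arm"))
        for k in range(arm_len - 2):
            angles.append((base + k, base + k + 1, base + k + 2, "chain"))
        for k in range(arm_len - 3):
            dihedrals.append((base + k, base + k + 1, base + k + 2,
                              base + k + 3, "chain"))
    return MoleculeTemplate(label="N130", bead_types=tuple(types),
                            regions=tuple(regions), charges=tuple(charges),
                            bonds=tuple(bonds), angles=tuple(angles),
                            dihedrals=tuple(dihedrals))


def _peptide_template() -> MoleculeTemplate:
    n = len(_PEPTIDE_CHARGES)
    types = tuple("base" if q else "small" for q in _PEPTIDE_CHARGES)
    regions = tuple("pep" for _ in range(n))
    bonds = tuple((k, k + 1, "pep") for k in range(n - 1))
    angles = tuple((k, k + 1, k + 2, "chain") for k in range(n - 2))
    return MoleculeTemplate(label="rpL5", bead_types=types, regions=regions,
                            charges=_PEPTIDE_CHARGES, bonds=bonds,
                            angles=angles)


def make_toy_condensate(n_pentamers: int = 12, peptides_per_pentamer: int = 15,
                        seed: int = 0, box: float | None = None):
    """Reduced pentamer:peptide condensate replica (1:15 stoichiometry).

    Each pentamer is one large excluded-volume PD bead carrying five arms
    with three acidic tracts (A0/A1/A2-like); peptides are short chains
    with +1 beads mimicking the R/K content of the ribosomal peptide.
    The default box scales the full-composition box so the PD number
    density is preserved.  Returns (topology, frame, forcefield).
    """
    if n_pentamers < 1 or peptides_per_pentamer < 1:
        raise ValueError("counts must be at least 1")
    if box is None:
        box = 338.6 * (n_pentamers / 108.0) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    n_pep = n_pentamers * peptides_per_pentamer
    topo = Topology([(_pentamer_template(), n_pentamers),
                     (_peptide_template(), n_pep)])
    ff = toy_forcefield()
    boxv = np.array([box] * 3)

    # PD centers by random sequential addition at 0.9 sigma separation
    pd_frame = initialize_configuration(single_type_topology(n_pentamers),
                                        boxv, "random_nonoverlapping",
                                        seed=seed, min_sep=0.9 * PD_SIGMA)
    coords = np.zeros((topo.n_beads, 3))
    arm_len = len(_ARM_REGIONS)
    idx = 0
    for p in range(n_pentamers):
        center = pd_frame.coords[p]
        coords[idx] = center
        idx += 1
        for arm in range(5):
            direction = _random_unit(rng)
            pos = center + direction * ff.bonds["pd_arm"].b0
            coords[idx] = pos
            idx += 1
            for k in range(1, arm_len):
                step = direction + 0.7 * _random_unit(rng)
                step /= np.linalg.norm(step)
                pos = pos + step * ff.bonds["arm"].b0
                coords[idx] = pos
                idx += 1
    pd_centers = pd_frame.coords
    keepout = 0.5 * (PD_SIGMA + 6.5)
    for _ in range(n_pep):
        pos = _sample_outside(rng, boxv, pd_centers, keepout)
        direction = _random_unit(rng)
        for k in range(len(_PEPTIDE_CHARGES)):
            coords[idx] = pos
            idx += 1
            step = direction + 0.7 * _random_unit(rng)
            step /= np.linalg.norm(step)
            pos = pos + step * ff.bonds["pep"].b0
    # push any stray bead out of the big excluded-volume spheres
    for p in range(n_pentamers):
        center = coords[topo.select(region="PD")[p]]
        d = coords - center
        d -= boxv * np.round(d / boxv)
        r = np.linalg.norm(d, axis=1)
        bad = (r < keepout * 0.95) & (r > 1e-9)
        coords[bad] = center + d[bad] / r[bad, None] * keepout
    frame = Frame.from_unwrapped(coords, boxv)
    return topo, frame, ff


def _sample_outside(rng, box, centers, keepout, max_tries: int = 200):
    for _ in range(max_tries):
        p = rng.random(3) * box
        d = centers - p
        d -= box * np.round(d / box)
        if (np.linalg.norm(d, axis=1) > keepout).all():
            return p
    return p


def _random_unit(rng) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# stochastic walks
# ---------------------------------------------------------------------------


def make_walks(kind: str, n: int, frames: int, seed: int = 0,
               dt: float = 1.0, speed: float = 1.0, D: float = 1.0,
               hurst: float = 0.25, mixture_fraction: float = 0.5,
               ) -> Trajectory:
    """Ensembles of walkers with known displacement statistics.

    kinds: ``static`` (MSD ≡ 0), ``ballistic`` (MSD = (v t)², exponent 2),
    ``brownian`` (MSD = 6 D t, exponent 1), ``subdiffusive_mixture``
    (a ``mixture_fraction`` of fractional-Gaussian-noise walkers with
    exponent 2H mixed with ballistic walkers).  The generating truth is
    attached as ``trajectory.truth``.
    """
    if frames < 3:
        raise ValueError("need at least 3 frames")
    rng = np.random.default_rng(seed)
    box = np.array([1e6] * 3)
    t = np.arange(frames) * dt
    if kind == "static":
        x = np.repeat(rng.random((1, n, 3)) * 100.0, frames, axis=0)
        truth = {"alpha": None, "msd": np.zeros(frames)}
    elif kind == "ballistic":
        v = _random_units(rng, n) * speed
        x = rng.random((1, n, 3)) * 100.0 + v[None, :, :] * t[:, None, None]
        truth = {"alpha": 2.0, "msd": (speed * t) ** 2}
    elif kind == "brownian":
        steps = rng.standard_normal((frames - 1, n, 3)) * math.sqrt(2 * D * dt)
        x = np.concatenate([np.zeros((1, n, 3)), np.cumsum(steps, axis=0)])
        x = x + rng.random((1, n, 3)) * 100.0
        truth = {"alpha": 1.0, "msd": 6.0 * D * t, "D": D}
    elif kind == "subdiffusive_mixture":
        n_sub = int(round(mixture_fraction * n))
        xs = np.empty((frames, n, 3))
        for i in range(n_sub):
            for d in range(3):
                inc = _fgn(hurst, frames - 1, rng)
                xs[:, i, d] = np.concatenate([[0.0], np.cumsum(inc)])
        v = _random_units(rng, n - n_sub) * speed
        xs[:, n_sub:, :] = v[None, :, :] * t[:, None, None]
        x = xs + rng.random((1, n, 3)) * 100.0
        truth = {"alpha_sub": 2.0 * hurst, "alpha_super": 2.0,
                 "n_sub": n_sub, "n_ballistic": n - n_sub}
    else:
        raise ValueError(f"unknown walk kind {kind!r}")
    frames_list = [Frame.from_unwrapped(x[i] + 0.5e6, box, time=float(i) * dt)
                   for i in range(frames)]
    traj = Trajectory(frames_list, frame_interval=dt)
    traj.truth = truth
    return traj


def _random_units(rng, n) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _fgn(h: float, n: int, rng) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (unit step var)."""
    k = np.arange(n + 1)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * np.abs(k) ** (2 * h)
                   + np.abs(k - 1) ** (2 * h))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)   # tiny negatives from round-off
    m = len(row)
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(lam / (2 * m)) * z)
    return w.real[:n] * math.sqrt(2.0)


# ---------------------------------------------------------------------------
# experimental fixtures
# ---------------------------------------------------------------------------


def make_frap_curves(I0: float = 0.5, I_inf: float = 1.0, t_half: float = 50.0,
                     n_replicates: int = 12, noise_sd: float = 0.02,
                     seed: int = 0, times: np.ndarray | None = None):
    """Hyperbolic recovery curves with additive Gaussian noise.

    Returns (times, intensities (R, T), truth dict).
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.linspace(0.0, 8.0 * t_half, 120)
    clean = frap_model(times, I0, I_inf, t_half)
    y = clean[None, :] + rng.standard_normal((n_replicates, len(times))) * noise_sd
    truth = {"I0": I0, "I_inf": I_inf, "t_half": t_half, "noise_sd": noise_sd}
    return times, y, truth


def make_scattering_profile(peak_lengths=(55.0, 77.0), widths=None,
                            amplitudes=None, background_exponent: float = 2.0,
                            noise: float = 0.0, q_grid=None, seed: int = 0):
    """Power-law background plus Gaussian correlation peaks at q = 2π/d.

    Returns (profile, truth) where truth holds the generating peak
    positions in both q and real space.
    """
    rng = np.random.default_rng(seed)
    if q_grid is None:
        q_grid = np.logspace(np.log10(0.006), np.log10(0.44), 300)
    q = np.asarray(q_grid, dtype=float)
    peak_q = 2.0 * np.pi / np.asarray(peak_lengths, dtype=float)
    if np.any(peak_q < q[0]) or np.any(peak_q > q[-1]):
        raise ValueError("peak lengths outside the 2π/q range of the grid")
    if widths is None:
        widths = 0.06 * peak_q
    if amplitudes is None:
        amplitudes = 1.5 * (q[len(q) // 2] / peak_q) ** background_exponent
    intensity = (q / q[0]) ** (-background_exponent)
    for c, w, a in zip(peak_q, np.atleast_1d(widths), np.atleast_1d(amplitudes)):
        intensity = intensity + a * np.exp(-0.5 * ((q - c) / w) ** 2)
    if noise > 0:
        intensity = intensity * (1.0 + noise * rng.standard_normal(len(q)))
        intensity = np.clip(intensity, 1e-12, None)
    profile = ScatteringProfile(q=q, intensity=intensity, kind="measured")
    truth = {"peak_q": peak_q, "peak_lengths": np.asarray(peak_lengths, float),
             "background_exponent": background_exponent}
    return profile, truth


def make_droplet_image(shape=(128, 128), n_droplets: int = 6,
                       radius: float = 8.0, intensity: float = 100.0,
                       background: float = 5.0, seed: int = 0) -> np.ndarray:
    """Bright disks on a dark background (a phase-separated well)."""
    rng = np.random.default_rng(seed)
    img = np.full(shape, background, dtype=float)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for _ in range(n_droplets):
        cy, cx = rng.random(2) * np.array(shape)
        img[(yy - cy) ** 2 + (xx - cx) ** 2 < radius ** 2] = intensity
    return rng.poisson(img).astype(float)
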
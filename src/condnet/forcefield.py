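"""Coarse-grained force-field data model and scalar energy terms.

The potential is a five-term decomposition

    W = W_LJ + W_el + W_b + W_theta + W_phi

with a truncated Lennard-Jones term between all bead pairs (Lorentz–
Berthelot mixing: σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_i ε_j)), a screened
Debye–Hückel electrostatic term between charged beads, harmonic bonds and
angles, and a three-term Fourier-series dihedral (plus a quadratic variant
used to keep rigid-arm geometries fixed).

The scalar functions here are the single-interaction reference
implementations; vectorized evaluation over whole frames lives in
:mod:`condnet.energy`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import units as _units

BEAD_GROUPS = ("charged", "large", "small", "domain")


@dataclass(frozen=True)
class BeadType:
    """One coarse-grained bead species.

    Residue beads fall into three groups (charged / large / small); the
    oligomerization domain of the pentamer is collapsed into one big
    excluded-volume "domain" bead.
    """

    name: str
    group: str
    sigma: float       # Å in real units, σ in reduced
    epsilon: float     # kcal/mol in real units, ε in reduced
    charge: int = 0    # elementary charges
    mass: float = 1.0  # amu in real units
    elec_cutoff: float | None = None  # Å; None -> ForceField default

    def __post_init__(self) -> None:
        if self.group not in BEAD_GROUPS:
            raise ValueError(f"unknown bead group {self.group!r}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        if self.group != "domain" and self.charge not in (-1, 0, 1):
            raise ValueError("residue bead charge must be -1, 0 or +1")


@dataclass(frozen=True)
class BondClass:
    K: float    # energy/length²
    b0: float   # length


@dataclass(frozen=True)
class AngleClass:
    K: float       # energy/rad²
    theta0: float  # rad


@dataclass(frozen=True)
class DihedralClass:
    """Three-term Fourier series: Σ_n K_n (1 − cos(nφ − φ_n))."""

    K: tuple[float, float, float]
    phi: tuple[float, float, float]


@dataclass(frozen=True)
class QuadDihedralClass:
    """Quadratic dihedral K(φ − φ0)², used to constrain rigid arms."""

    K: float
    phi0: float


@dataclass
class ForceField:
    """All interaction parameters of the coarse-grained model."""

    bead_types: dict[str, BeadType] = field(default_factory=dict)
    lj_cutoff_factor: float = 2.5
    lj_shift: bool = False          # truncated, not shifted, by default
    dielectric: float = 80.0
    kappa: float = 0.1              # inverse length
    coulomb_constant: float | None = None  # None -> unit-system default
    elec_cutoff_default: float = 24.1      # Å
    bonds: dict[str, BondClass] = field(default_factory=dict)
    angles: dict[str, AngleClass] = field(default_factory=dict)
    dihedrals: dict[str, DihedralClass] = field(default_factory=dict)
    quad_dihedrals: dict[str, QuadDihedralClass] = field(default_factory=dict)
    units: str = "real"
    #: per-(type, type) LJ cutoff overrides (unordered pairs); used e.g. to
    #: keep the huge domain-bead cutoff below the minimum-image radius of a
    #: reduced simulation box.
    pair_cutoff_override: dict[frozenset, float] = field(default_factory=dict)
    #: nonbonded exclusion policy: beads this many bonds apart (or fewer)
    #: do not interact through LJ/electrostatics. 2 means 1-2 and 1-3.
    exclusion_depth: int = 2

    def __post_init__(self) -> None:
        _units._check(self.units)
        if self.lj_cutoff_factor <= 1:
            raise ValueError("lj_cutoff_factor must exceed 1")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")

    # -- derived parameters -------------------------------------------------

    @property
    def C(self) -> float:
        if self.coulomb_constant is not None:
            return self.coulomb_constant
        return _units.coulomb_constant(self.units)

    def sigma_ij(self, a: BeadType, b: BeadType) -> float:
        return 0.5 * (a.sigma + b.sigma)

    def epsilon_ij(self, a: BeadType, b: BeadType) -> float:
        return math.sqrt(a.epsilon * b.epsilon)

    def lj_cutoff(self, a: BeadType, b: BeadType) -> float:
        key = frozenset((a.name, b.name))
        if key in self.pair_cutoff_override:
            return self.pair_cutoff_override[key]
        return self.lj_cutoff_factor * self.sigma_ij(a, b)

    def elec_cutoff(self, a: BeadType, b: BeadType) -> float:
        ca = a.elec_cutoff if a.elec_cutoff is not None else self.elec_cutoff_default
        cb = b.elec_cutoff if b.elec_cutoff is not None else self.elec_cutoff_default
        return max(ca, cb)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pair_cutoff_override"] = [
            [sorted(k), v] for k, v in self.pair_cutoff_override.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ForceField":
        d = dict(d)
        d["bead_types"] = {k: BeadType(**v) for k, v in d.get("bead_types", {}).items()}
        d["bonds"] = {k: BondClass(**v) for k, v in d.get("bonds", {}).items()}
        d["angles"] = {k: AngleClass(**v) for k, v in d.get("angles", {}).items()}
        d["dihedrals"] = {
            k: DihedralClass(K=tuple(v["K"]), phi=tuple(v["phi"]))
            for k, v in d.get("dihedrals", {}).items()
        }
        d["quad_dihedrals"] = {
            k: QuadDihedralClass(**v) for k, v in d.get("quad_dihedrals", {}).items()
        }
        d["pair_cutoff_override"] = {
            frozenset(k): v for k, v in d.get("pair_cutoff_override", [])
        }
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ForceField":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# scalar energy terms
# ---------------------------------------------------------------------------


def lj_pair_energy(r: float, type_i: BeadType, type_j: BeadType, ff: ForceField) -> float:
    """Truncated 12-6 Lennard-Jones pair energy.

    Zero at and beyond the pair cutoff (``lj_cutoff_factor`` × σ_ij unless
    overridden); truncated without shift unless ``ff.lj_shift`` is set.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    rc = ff.lj_cutoff(type_i, type_j)
    if r >= rc:
        return 0.0
    sig = ff.sigma_ij(type_i, type_j)
    eps = ff.epsilon_ij(type_i, type_j)
    sr6 = (sig / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    if ff.lj_shift:
        src6 = (sig / rc) ** 6
        e -= 4.0 * eps * (src6 * src6 - src6)
    return e


def debye_huckel_energy(r: float, q_i: float, q_j: float, ff: ForceField,
                        cutoff: float | None = None) -> float:
    """Screened Coulomb pair energy C·q_i·q_j/(ε r)·exp(−κ r), truncated."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    rc = cutoff if cutoff is not None else ff.elec_cutoff_default
    if r >= rc or q_i == 0 or q_j == 0:
        return 0.0
    return ff.C * q_i * q_j / (ff.dielectric * r) * math.exp(-ff.kappa * r)


def harmonic_bond_energy(b: float, klass: str, ff: ForceField) -> float:
    """K(b − b0)² for the named bond class."""
    if b <= 0:
        raise ValueError("bond length must be positive")
    try:
        c = ff.bonds[klass]
    except KeyError:
        raise KeyError(f"unknown bond class {klass!r}") from None
    return c.K * (b - c.b0) ** 2


def harmonic_angle_energy(theta: float, klass: str, ff: ForceField) -> float:
    """K(θ − θ0)² for the named angle class."""
    if not 0.0 <= theta <= math.pi:
        raise ValueError("angle must lie in [0, pi]")
    try:
        c = ff.angles[klass]
    except KeyError:
        raise KeyError(f"unknown angle class {klass!r}") from None
    return c.K * (theta - c.theta0) ** 2


def fourier_dihedral_energy(phi: float, klass: str, ff: ForceField) -> float:
    """Σ_{n=1..3} K_n (1 − cos(nφ − φ_n)) at the instantaneous dihedral φ."""
    try:
        c = ff.dihedrals[klass]
    except KeyError:
        raise KeyError(f"unknown dihedral class {klass!r}") from None
    return sum(
        k * (1.0 - math.cos((n + 1) * phi - p))
        for n, (k, p) in enumerate(zip(c.K, c.phi))
    )


def quad_dihedral_energy(phi: float, klass: str, ff: ForceField) -> float:
    """Quadratic dihedral K(φ − φ0)², wrapping φ − φ0 to (−π, π]."""
    try:
        c = ff.quad_dihedrals[klass]
    except KeyError:
        raise KeyError(f"unknown quad dihedral class {klass!r}") from None
    d = (phi - c.phi0 + math.pi) % (2.0 * math.pi) - math.pi
    return c.K * d * d


def lj_forcefield(sigma: float = 1.0, epsilon: float = 1.0,
                  cutoff_factor: float = 2.5, shift: bool = False) -> ForceField:
    """Single-bead-type reduced-unit Lennard-Jones force field."""
    bt = BeadType(name="LJ", group="small", sigma=sigma, epsilon=epsilon,
                  charge=0, mass=1.0)
    return ForceField(bead_types={"LJ": bt}, lj_cutoff_factor=cutoff_factor,
                      lj_shift=shift, units="reduced", dielectric=1.0,
                      kappa=0.0)
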
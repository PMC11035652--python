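"""Molecular topology and trajectory containers.

A :class:`Topology` is a flat, array-centric description of a periodic
system: every bead has a type name, a region label (e.g. ``A1`` for an
acidic tract, ``PD`` for the pentamerization domain, ``pep`` for peptide
beads), a molecule id and a charge.  Bonded terms are stored as global
index tuples with class names resolved against a
:class:`~condnet.forcefield.ForceField`.

A :class:`Frame` stores wrapped coordinates plus optional integer image
flags; a :class:`Trajectory` is an ordered sequence of frames with a fixed
frame interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass(frozen=True)
class MoleculeTemplate:
    """Per-molecule bead sequence and bonded terms (local indices)."""

    label: str
    bead_types: tuple[str, ...]
    regions: tuple[str, ...]
    charges: tuple[int, ...]
    bonds: tuple[tuple[int, int, str], ...] = ()
    angles: tuple[tuple[int, int, int, str], ...] = ()
    dihedrals: tuple[tuple[int, int, int, int, str], ...] = ()
    quad_dihedrals: tuple[tuple[int, int, int, int, str], ...] = ()

    def __post_init__(self) -> None:
        n = len(self.bead_types)
        if len(self.regions) != n or len(self.charges) != n:
            raise ValueError("regions/charges length must match bead count")
        for terms, width in ((self.bonds, 2), (self.angles, 3),
                             (self.dihedrals, 4), (self.quad_dihedrals, 4)):
            for t in terms:
                if any(not 0 <= i < n for i in t[:width]):
                    raise ValueError(f"bonded index out of range in {t}")

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)


class Topology:
    """Flattened multi-molecule topology."""

    def __init__(self, molecules: list[tuple[MoleculeTemplate, int]]):
        """Build from a list of (template, count) pairs."""
        types: list[str] = []
        regions: list[str] = []
        charges: list[float] = []
        mol_id: list[int] = []
        mol_labels: list[str] = []
        bonds, bond_classes = [], []
        angles, angle_classes = [], []
        dihedrals, dihedral_classes = [], []
        quads, quad_classes = [], []

        mol = 0
        offset = 0
        for tmpl, count in molecules:
            for _ in range(count):
                types.extend(tmpl.bead_types)
                regions.extend(tmpl.regions)
                charges.extend(tmpl.charges)
                mol_id.extend([mol] * tmpl.n_beads)
                mol_labels.append(tmpl.label)
                for i, j, c in tmpl.bonds:
                    bonds.append((i + offset, j + offset))
                    bond_classes.append(c)
                for i, j, k, c in tmpl.angles:
                    angles.append((i + offset, j + offset, k + offset))
                    angle_classes.append(c)
                for i, j, k, l, c in tmpl.dihedrals:
                    dihedrals.append((i + offset, j + offset, k + offset, l + offset))
                    dihedral_classes.append(c)
                for i, j, k, l, c in tmpl.quad_dihedrals:
                    quads.append((i + offset, j + offset, k + offset, l + offset))
                    quad_classes.append(c)
                offset += tmpl.n_beads
                mol += 1

        self.bead_types = np.asarray(types, dtype=object)
        self.regions = np.asarray(regions, dtype=object)
        self.charges = np.asarray(charges, dtype=float)
        self.mol_id = np.asarray(mol_id, dtype=np.int64)
        self.mol_labels = mol_labels
        self.bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)
        self.bond_classes = bond_classes
        self.angles = np.asarray(angles, dtype=np.int64).reshape(-1, 3)
        self.angle_classes = angle_classes
        self.dihedrals = np.asarray(dihedrals, dtype=np.int64).reshape(-1, 4)
        self.dihedral_classes = dihedral_classes
        self.quad_dihedrals = np.asarray(quads, dtype=np.int64).reshape(-1, 4)
        self.quad_dihedral_classes = quad_classes

    @classmethod
    def from_arrays(cls, bead_types, mol_id, charges=None, regions=None,
                    mol_labels=None, bonds=None, bond_classes=None,
                    angles=None, angle_classes=None,
                    dihedrals=None, dihedral_classes=None) -> "Topology":
        """Build directly from flat arrays (e.g. a parsed data file)."""
        topo = cls.__new__(cls)
        topo.bead_types = np.asarray(bead_types, dtype=object)
        n = len(topo.bead_types)
        topo.mol_id = np.asarray(mol_id, dtype=np.int64)
        topo.charges = (np.zeros(n) if charges is None
                        else np.asarray(charges, dtype=float))
        topo.regions = (np.asarray(["?"] * n, dtype=object) if regions is None
                        else np.asarray(regions, dtype=object))
        nmol = int(topo.mol_id.max()) + 1 if n else 0
        topo.mol_labels = (["mol"] * nmol if mol_labels is None
                           else list(mol_labels))
        topo.bonds = (np.empty((0, 2), np.int64) if bonds is None
                      else np.asarray(bonds, np.int64).reshape(-1, 2))
        topo.bond_classes = list(bond_classes or [])
        topo.angles = (np.empty((0, 3), np.int64) if angles is None
                       else np.asarray(angles, np.int64).reshape(-1, 3))
        topo.angle_classes = list(angle_classes or [])
        topo.dihedrals = (np.empty((0, 4), np.int64) if dihedrals is None
                          else np.asarray(dihedrals, np.int64).reshape(-1, 4))
        topo.dihedral_classes = list(dihedral_classes or [])
        topo.quad_dihedrals = np.empty((0, 4), np.int64)
        topo.quad_dihedral_classes = []
        return topo

    # -- basic queries ------------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.bead_types)

    @property
    def n_molecules(self) -> int:
        return len(self.mol_labels)

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def select(self, region: str | None = None, mol_label: str | None = None,
               charge_sign: int | None = None) -> np.ndarray:
        """Global bead indices matching all given filters."""
        mask = np.ones(self.n_beads, dtype=bool)
        if region is not None:
            mask &= self.regions == region
        if mol_label is not None:
            labels = np.asarray(self.mol_labels, dtype=object)[self.mol_id]
            mask &= labels == mol_label
        if charge_sign is not None:
            mask &= np.sign(self.charges).astype(int) == charge_sign
        return np.flatnonzero(mask)

    def molecule_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.mol_labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    # -- mutation -----------------------------------------------------------

    def neutralize(self, region: str) -> "Topology":
        """Copy of this topology with charges in the named region zeroed.

        Mirrors the charge-neutralization mutants: everything but the
        selected region's charges is unchanged.
        """
        idx = np.flatnonzero(self.regions == region)
        if idx.size == 0:
            raise KeyError(f"unknown region {region!r}")
        import copy

        topo = copy.copy(self)
        topo.__dict__.pop("_energy_cache", None)  # parameter tables are stale
        topo.charges = self.charges.copy()
        topo.charges[idx] = 0.0
        return topo


def mutate_neutralize(topo: Topology, region: str) -> Topology:
    """Functional alias for :meth:`Topology.neutralize`."""
    return topo.neutralize(region)


def single_type_topology(n: int, type_name: str = "LJ") -> Topology:
    """N independent single-bead molecules (atomic fluids, LJ systems)."""
    tmpl = MoleculeTemplate(label=type_name, bead_types=(type_name,),
                            regions=(type_name,), charges=(0,))
    return Topology([(tmpl, n)])


# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """One snapshot: wrapped coordinates in an orthorhombic periodic box."""

    coords: np.ndarray            # (N, 3) wrapped positions
    box: np.ndarray               # (3,) edge lengths
    images: np.ndarray | None = None  # (N, 3) integer image flags
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edges must be positive")
        if self.images is not None:
            self.images = np.asarray(self.images, dtype=np.int64)
            if self.images.shape != self.coords.shape:
                raise ValueError("images must match coords shape")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    @property
    def unwrapped(self) -> np.ndarray:
        """Unwrapped coordinates (requires image flags)."""
        if self.images is None:
            raise ValueError("frame has no image flags; cannot unwrap")
        return self.coords + self.images * self.box

    @classmethod
    def from_unwrapped(cls, coords: np.ndarray, box, time: float = 0.0) -> "Frame":
        coords = np.asarray(coords, dtype=float)
        box = np.asarray(box, dtype=float).reshape(3)
        images = np.floor(coords / box).astype(np.int64)
        return cls(coords=coords - images * box, box=box, images=images, time=time)


class Trajectory:
    """Time-ordered sequence of frames with constant particle count."""

    def __init__(self, frames: list[Frame], frame_interval: float | None = None):
        if not frames:
            raise ValueError("trajectory needs at least one frame")
        n = frames[0].n_beads
        times = [f.time for f in frames]
        if any(f.n_beads != n for f in frames):
            raise ValueError("particle count changes across frames")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frames must be strictly time-ordered")
        self.frames = frames
        if frame_interval is None and len(frames) > 1:
            frame_interval = times[1] - times[0]
        self.frame_interval = frame_interval

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_beads(self) -> int:
        return self.frames[0].n_beads

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def unwrapped_array(self) -> np.ndarray:
        """(frames, N, 3) unwrapped coordinates; errors without image flags."""
        if any(f.images is None for f in self.frames):
            raise ValueError(
                "trajectory is wrapped-only (no image flags); displacement "
                "analysis would alias across the periodic box")
        return np.stack([f.unwrapped for f in self.frames])

    def wrapped_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])
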
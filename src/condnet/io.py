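"""File formats, replicate aggregation, and run configuration.

Trajectories round-trip through the plain-text LAMMPS dump dialect
(``id mol type x y z ix iy iz``) and XYZ; force-field/topology
configuration is structured JSON; tabular results are written as
delimited text with ``#``-prefixed metadata headers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import Frame, Topology, Trajectory


class DumpFormatError(ValueError):
    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


def write_dump(traj: Trajectory, path, topo: Topology | None = None,
               type_map: dict[str, int] | None = None) -> None:
    """Write a LAMMPS-style text dump (wrapped coords + image flags)."""
    path = Path(path)
    n = traj.n_beads
    if topo is not None:
        names = sorted(set(map(str, topo.bead_types)))
        tmap = type_map or {nm: i + 1 for i, nm in enumerate(names)}
        types = np.array([tmap[str(t)] for t in topo.bead_types])
        mols = topo.mol_id + 1
    else:
        types = np.ones(n, dtype=int)
        mols = np.arange(1, n + 1)
    with path.open("w") as fh:
        for fi, fr in enumerate(traj.frames):
            step = int(round(fr.time / traj.frame_interval)) \
                if traj.frame_interval else fi
            img = fr.images if fr.images is not None else np.zeros((n, 3), int)
            fh.write("ITEM: TIMESTEP\n%d\n" % step)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % n)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write("0.0 %.10g\n" % fr.box[d])
            fh.write("ITEM: ATOMS id mol type x y z ix iy iz\n")
            for i in range(n):
                fh.write("%d %d %d %.10g %.10g %.10g %d %d %d\n" % (
                    i + 1, mols[i], types[i], fr.coords[i, 0], fr.coords[i, 1],
                    fr.coords[i, 2], img[i, 0], img[i, 1], img[i, 2]))


def read_dump(path, frame_interval: float | None = None) -> Trajectory:
    """Read a LAMMPS text dump; atoms re-sorted by id, ids 1-based.

    Frames without image-flag columns are loaded but the trajectory is
    flagged ``wrapped_only`` (displacement analysis will refuse it).
    Malformed input raises :class:`DumpFormatError` with a line number.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    mols = types = None
    wrapped_only = False
    i = 0
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            raise DumpFormatError("expected ITEM: TIMESTEP", i + 1)
        try:
            step = int(lines[i + 1])
            if not lines[i + 2].startswith("ITEM: NUMBER OF ATOMS"):
                raise ValueError
            n = int(lines[i + 3])
            if not lines[i + 4].startswith("ITEM: BOX BOUNDS"):
                raise ValueError
            box = np.empty(3)
            for d in range(3):
                lo, hi = map(float, lines[i + 5 + d].split()[:2])
                box[d] = hi - lo
        except (ValueError, IndexError):
            raise DumpFormatError("malformed frame header", i + 1) from None
        header = lines[i + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise DumpFormatError("expected ITEM: ATOMS", i + 9)
        cols = header.split()[2:]
        need = ["id", "x", "y", "z"]
        if any(c not in cols for c in need):
            raise DumpFormatError(f"dump must contain columns {need}", i + 9)
        has_img = all(c in cols for c in ("ix", "iy", "iz"))
        wrapped_only |= not has_img
        ci = {c: k for k, c in enumerate(cols)}
        ids = np.empty(n, dtype=int)
        xyz = np.empty((n, 3))
        img = np.zeros((n, 3), dtype=np.int64) if has_img else None
        mol_arr = np.zeros(n, dtype=int)
        type_arr = np.ones(n, dtype=int)
        for k in range(n):
            ln = i + 9 + k
            try:
                parts = lines[ln].split()
                ids[k] = int(parts[ci["id"]])
                xyz[k] = [float(parts[ci["x"]]), float(parts[ci["y"]]),
                          float(parts[ci["z"]])]
                if has_img:
                    img[k] = [int(parts[ci["ix"]]), int(parts[ci["iy"]]),
                              int(parts[ci["iz"]])]
                if "mol" in ci:
                    mol_arr[k] = int(parts[ci["mol"]])
                if "type" in ci:
                    type_arr[k] = int(parts[ci["type"]])
            except (ValueError, IndexError):
                raise DumpFormatError("malformed atom record", ln + 1) from None
        order = np.argsort(ids, kind="stable")
        frames.append(Frame(coords=xyz[order], box=box,
                            images=None if img is None else img[order],
                            time=float(step) * (frame_interval or 1.0)))
        if mols is None:
            mols, types = mol_arr[order], type_arr[order]
        i += 9 + n
    traj = Trajectory(frames, frame_interval=frame_interval)
    traj.wrapped_only = wrapped_only
    traj.mol_ids = mols
    traj.type_ids = types
    return traj


def write_xyz(traj: Trajectory, path, names=None) -> None:
    path = Path(path)
    n = traj.n_beads
    if names is None:
        names = ["X"] * n
    with path.open("w") as fh:
        for fr in traj.frames:
            fh.write("%d\ntime=%.10g\n" % (n, fr.time))
            for i in range(n):
                fh.write("%s %.10g %.10g %.10g\n" % (
                    names[i], fr.coords[i, 0], fr.coords[i, 1], fr.coords[i, 2]))


def read_xyz(path, box, frame_interval: float = 1.0) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    box = np.asarray(box, dtype=float).reshape(3)
    frames = []
    i = 0
    t = 0.0
    while i < len(lines):
        n = int(lines[i])
        xyz = np.array([[float(v) for v in lines[i + 2 + k].split()[1:4]]
                        for k in range(n)])
        frames.append(Frame(coords=np.mod(xyz, box), box=box, time=t))
        t += frame_interval
        i += 2 + n
    return Trajectory(frames, frame_interval=frame_interval)


def read_lammps_data(path) -> tuple[Topology, Frame]:
    """Minimal LAMMPS data-file importer (Atoms full style + bonded sections).

    Bead types become names ``t<k>``; bond/angle/dihedral classes become
    ``bond<k>``/``angle<k>``/``dihedral<k>``, to be resolved against a
    force field built separately.
    """
    lines = Path(path).read_text().splitlines()
    counts = {}
    box = np.empty(3)
    sections: dict[str, list[str]] = {}
    current = None
    for raw in lines[1:]:
        ln = raw.split("#")[0].strip()
        if not ln:
            continue
        lower = ln.lower()
        if lower.endswith(("atoms", "bonds", "angles", "dihedrals")) and \
                ln.split()[0].isdigit():
            counts[lower.split()[-1]] = int(ln.split()[0])
        elif "xlo" in lower or "ylo" in lower or "zlo" in lower:
            lo, hi = map(float, ln.split()[:2])
            box[("x" in lower) * 0 + ("y" in lower) * 1 + ("z" in lower) * 2] = hi - lo
        elif ln.split()[0] in ("Masses", "Atoms", "Bonds", "Angles",
                               "Dihedrals", "Velocities", "Pair", "Bond",
                               "Angle", "Dihedral"):
            current = ln.split()[0]
            sections[current] = []
        elif current:
            sections[current].append(ln)

    atoms = sorted((ln.split() for ln in sections.get("Atoms", [])),
                   key=lambda p: int(p[0]))
    n = len(atoms)
    mol = np.array([int(p[1]) - 1 for p in atoms])
    typ = np.array([f"t{p[2]}" for p in atoms], dtype=object)
    q = np.array([float(p[3]) for p in atoms])
    xyz = np.array([[float(p[4]), float(p[5]), float(p[6])] for p in atoms])

    def bonded(name, width, prefix):
        rows = [ln.split() for ln in sections.get(name, [])]
        idx = np.array([[int(v) - 1 for v in r[2:2 + width]] for r in rows],
                       dtype=np.int64).reshape(-1, width)
        classes = [f"{prefix}{r[1]}" for r in rows]
        return idx, classes

    bonds, bond_classes = bonded("Bonds", 2, "bond")
    angles, angle_classes = bonded("Angles", 3, "angle")
    dihedrals, dihedral_classes = bonded("Dihedrals", 4, "dihedral")
    topo = Topology.from_arrays(typ, mol, charges=q, bonds=bonds,
                                bond_classes=bond_classes, angles=angles,
                                angle_classes=angle_classes,
                                dihedrals=dihedrals,
                                dihedral_classes=dihedral_classes)
    return topo, Frame.from_unwrapped(xyz, box)


# ---------------------------------------------------------------------------


def aggregate_replicates(curves, abscissae=None):
    """Pointwise mean and SEM (= sd/√n) across replicate curves.

    ``curves``: list of 1-D arrays on aligned abscissae; if ``abscissae``
    is given (list of x-arrays), alignment is checked explicitly.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 replicates")
    if abscissae is not None:
        x0 = np.asarray(abscissae[0])
        for x in abscissae[1:]:
            if not np.allclose(x0, np.asarray(x)):
                raise ValueError("replicate abscissae are misaligned")
    mat = np.vstack([np.asarray(c, dtype=float) for c in curves])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return mean, sem


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


@dataclass
class RunConfig:
    """Reproducible stage parameters; defaults mirror the study protocol."""

    seed: int = 0
    replicates: int = 5
    dr: float = 0.5                 # Å, condensate-scale RDF bin
    lj_dr: float = 0.025            # σ, reduced-unit RDF bin
    last_frames: int = 1000         # analysis window (scaled at reduced length)
    smooth_window: int = 5
    r2_threshold: float = 0.99
    phase_threshold: float = 0.10
    n_particles: int = 2000
    n_steps: int = 200_000
    equil_steps: int = 10_000
    dump_every: int = 2_000
    dt: float = 0.005
    damping: float = 0.5

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def run_log(config: RunConfig, extra: dict | None = None) -> dict:
    """Provenance record: config hash, seeds, library versions."""
    import scipy
    import numba

    log = {"config_hash": config.config_hash(), "seed": config.seed,
           "numpy": np.__version__, "scipy": scipy.__version__,
           "pandas": pd.__version__, "numba": numba.__version__}
    log.update(extra or {})
    return log
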
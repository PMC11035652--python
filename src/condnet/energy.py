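"""Vectorized frame-level energies and analytic forces.

Evaluates the five-term coarse-grained potential (truncated LJ, screened
Debye-Hückel electrostatics, harmonic bonds/angles, Fourier/quadratic
dihedrals) over a periodic frame, with minimum-image convention and a
configurable bonded-exclusion policy (beads within ``ff.exclusion_depth``
bonds of each other skip the nonbonded terms; the default, depth 2,
excludes 1-2 and 1-3 pairs).

Two nonbonded enumeration paths are provided: a cell/tree-based candidate
search (default) and an all-pairs brute-force path used as the oracle in
tests; they agree to round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .forcefield import ForceField
from .topology import Frame, Topology

#: pair separations below this fraction of σ_ij are flagged as overlaps
OVERLAP_FRACTION = 0.05


@dataclass
class EnergyBreakdown:
    lj: float
    el: float
    bond: float
    angle: float
    dihedral: float
    forces: np.ndarray | None = None
    overlap: bool = False

    @property
    def total(self) -> float:
        return self.lj + self.el + self.bond + self.angle + self.dihedral


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Nearest-image displacement vectors for an orthorhombic box."""
    return d - box * np.round(d / box)


def _scatter_pair_forces(f, i, j, fv):
    """Accumulate ±fv onto rows i/j (bincount is much faster than add.at)."""
    n = f.shape[0]
    for c in range(3):
        f[:, c] += np.bincount(i, weights=fv[:, c], minlength=n)
        f[:, c] -= np.bincount(j, weights=fv[:, c], minlength=n)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------


class _Tables:
    """Per-type-pair parameter matrices resolved from a force field."""

    def __init__(self, topo: Topology, ff: ForceField):
        names = sorted({str(t) for t in topo.bead_types})
        missing = [n for n in names if n not in ff.bead_types]
        if missing:
            raise KeyError(f"bead types {missing} absent from force field")
        self.type_names = names
        index = {n: i for i, n in enumerate(names)}
        self.type_idx = np.array([index[str(t)] for t in topo.bead_types],
                                 dtype=np.int64)
        nt = len(names)
        self.sigma = np.zeros((nt, nt))
        self.eps = np.zeros((nt, nt))
        self.rc_lj = np.zeros((nt, nt))
        self.rc_el = np.zeros((nt, nt))
        for a in range(nt):
            for b in range(nt):
                ta, tb = ff.bead_types[names[a]], ff.bead_types[names[b]]
                self.sigma[a, b] = ff.sigma_ij(ta, tb)
                self.eps[a, b] = ff.epsilon_ij(ta, tb)
                self.rc_lj[a, b] = ff.lj_cutoff(ta, tb)
                self.rc_el[a, b] = ff.elec_cutoff(ta, tb)
        self.charges = topo.charges
        self.masses = np.array(
            [ff.bead_types[str(t)].mass for t in topo.bead_types])


def _cached_tables(topo: Topology, ff: ForceField) -> "_Tables":
    cache = topo.__dict__.setdefault("_energy_cache", {})
    key = ("tables", id(ff))
    if key not in cache:
        cache[key] = _Tables(topo, ff)
    return cache[key]


def _cached_exclusions(topo: Topology, depth: int) -> np.ndarray:
    """Sorted packed (i*N+j) keys of excluded pairs, cached on the topology."""
    cache = topo.__dict__.setdefault("_energy_cache", {})
    key = ("excl", depth)
    if key not in cache:
        keys = exclusion_keys(topo, depth)
        cache[key] = np.sort(np.fromiter(keys, dtype=np.int64, count=len(keys)))
    return cache[key]


def filter_excluded(i: np.ndarray, j: np.ndarray, topo: Topology,
                    depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Drop pairs within ``depth`` bonds of each other."""
    if depth <= 0 or len(topo.bonds) == 0 or i.size == 0:
        return i, j
    excl = _cached_exclusions(topo, depth)
    if excl.size == 0:
        return i, j
    keys = i * topo.n_beads + j
    pos = np.searchsorted(excl, keys)
    pos = np.clip(pos, 0, excl.size - 1)
    keep = excl[pos] != keys
    return i[keep], j[keep]


def exclusion_keys(topo: Topology, depth: int) -> set[int]:
    """Set of packed (i, j) keys for pairs within `depth` bonds."""
    n = topo.n_beads
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in topo.bonds:
        adj[i].append(int(j))
        adj[j].append(int(i))
    keys: set[int] = set()
    for start in range(n):
        seen = {start: 0}
        frontier = [start]
        for d in range(1, depth + 1):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in seen:
                        seen[v] = d
                        nxt.append(v)
                        if start < v:
                            keys.add(start * n + v)
                        elif v < start:
                            keys.add(v * n + start)
            frontier = nxt
    return keys


# ---------------------------------------------------------------------------
# nonbonded candidate pairs
# ---------------------------------------------------------------------------


def _brute_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=1)
    return i.astype(np.int64), j.astype(np.int64)


def candidate_pairs(frame: Frame, tables: _Tables, method: str = "tree",
                    extra: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Candidate nonbonded (i, j) pairs, i < j, superset of all in-cutoff pairs.

    Types whose cutoffs approach the minimum-image radius (large domain
    beads in a reduced box) are handled by explicit pairing against all
    beads; the rest go through a periodic KD-tree query.
    """
    n = frame.n_beads
    if method == "brute" or n < 40:
        return _brute_pairs(n)
    box = frame.box
    rc_any = np.maximum(tables.rc_lj, tables.rc_el)
    r_safe = 0.45 * box.min()
    # greedily promote types to "big" (explicit all-pair handling) until
    # the remaining type pairs fit a periodic tree query
    nt = rc_any.shape[0]
    big = np.zeros(nt, dtype=bool)
    while True:
        rest = np.flatnonzero(~big)
        if rest.size == 0:
            break
        sub = rc_any[np.ix_(rest, rest)] + extra
        worst = sub.max(axis=1)
        if worst.max() <= r_safe:
            break
        big[rest[np.argmax(worst)]] = True
    big_types = np.flatnonzero(big)
    is_big = np.isin(tables.type_idx, big_types)
    small_idx = np.flatnonzero(~is_big)
    big_idx = np.flatnonzero(is_big)

    pairs_i: list[np.ndarray] = []
    pairs_j: list[np.ndarray] = []
    if small_idx.size > 1:
        rest = np.flatnonzero(~big)
        sub = rc_any[np.ix_(rest, rest)]
        radius = float(sub.max()) + extra if sub.size else 0.0
        if radius > 0:
            wrapped = np.mod(frame.coords[small_idx], box)
            tree = cKDTree(wrapped, boxsize=box)
            p = tree.query_pairs(r=radius * (1 + 1e-12), output_type="ndarray")
            if p.size:
                gi = small_idx[p[:, 0]]
                gj = small_idx[p[:, 1]]
                lo, hi = np.minimum(gi, gj), np.maximum(gi, gj)
                pairs_i.append(lo)
                pairs_j.append(hi)
    if big_idx.size:
        bi = np.repeat(big_idx, n)
        bj = np.tile(np.arange(n), big_idx.size)
        keep = bi != bj
        lo = np.minimum(bi[keep], bj[keep])
        hi = np.maximum(bi[keep], bj[keep])
        pairs_i.append(lo)
        pairs_j.append(hi)
    if not pairs_i:
        return (np.empty(0, dtype=np.int64),) * 2
    i = np.concatenate(pairs_i)
    j = np.concatenate(pairs_j)
    # de-duplicate (big-big pairs can appear once per direction)
    key = i * n + j
    _, uniq = np.unique(key, return_index=True)
    return i[uniq], j[uniq]


# ---------------------------------------------------------------------------
# energy + forces
# ---------------------------------------------------------------------------


def total_energy(frame: Frame, topo: Topology, ff: ForceField,
                 method: str = "tree", forces: bool = False,
                 pairs: tuple[np.ndarray, np.ndarray] | None = None,
                 ) -> EnergyBreakdown:
    """Five-component energy decomposition (and optionally analytic forces).

    Pairwise terms use the minimum-image convention; bonded neighbors up to
    ``ff.exclusion_depth`` bonds apart are excluded from LJ and
    electrostatics.  Overlapping beads (r below a small fraction of σ_ij)
    are flagged and evaluated at a clamped separation so the energy stays
    finite.
    """
    if frame.n_beads != topo.n_beads:
        raise ValueError("frame/topology bead counts differ")
    tables = _cached_tables(topo, ff)
    box = frame.box
    x = frame.coords
    f = np.zeros_like(x) if forces else None

    if pairs is None:
        i, j = candidate_pairs(frame, tables, method=method)
        i, j = filter_excluded(i, j, topo, ff.exclusion_depth)
    else:
        # caller-supplied pairs are already exclusion-filtered
        i, j = pairs
    overlap = False
    e_lj = e_el = 0.0
    if i.size:
        ti, tj = tables.type_idx[i], tables.type_idx[j]
        d = minimum_image(x[i] - x[j], box)
        r = np.linalg.norm(d, axis=1)
        sig = tables.sigma[ti, tj]
        floor = OVERLAP_FRACTION * sig
        bad = r < floor
        if np.any(bad):
            overlap = True
            r = np.where(bad, floor, r)

        # LJ
        rc = tables.rc_lj[ti, tj]
        m = r < rc
        if np.any(m):
            eps = tables.eps[ti, tj][m]
            sr6 = (sig[m] / r[m]) ** 6
            e = 4.0 * eps * (sr6 * sr6 - sr6)
            if ff.lj_shift:
                src6 = (sig[m] / rc[m]) ** 6
                e -= 4.0 * eps * (src6 * src6 - src6)
            e_lj = float(e.sum())
            if forces:
                # dU/dr = -24 eps (2 sr12 - sr6) / r
                dudr = -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r[m]
                fv = (-dudr / r[m])[:, None] * d[m]
                _scatter_pair_forces(f, i[m], j[m], fv)

        # Debye-Hückel
        qq = tables.charges[i] * tables.charges[j]
        me = (r < tables.rc_el[ti, tj]) & (qq != 0)
        if np.any(me):
            rm = r[me]
            e = ff.C * qq[me] / (ff.dielectric * rm) * np.exp(-ff.kappa * rm)
            e_el = float(e.sum())
            if forces:
                dudr = -e * (1.0 / rm + ff.kappa)
                fv = (-dudr / rm)[:, None] * d[me]
                _scatter_pair_forces(f, i[me], j[me], fv)

    e_bond = _bond_term(x, box, topo, ff, f)
    e_angle = _angle_term(x, box, topo, ff, f)
    e_dih = _dihedral_term(x, box, topo, ff, f)

    return EnergyBreakdown(lj=e_lj, el=e_el, bond=e_bond, angle=e_angle,
                           dihedral=e_dih, forces=f, overlap=overlap)


def pair_forces(frame: Frame, topo: Topology, ff: ForceField,
                method: str = "tree") -> np.ndarray:
    """Per-bead force vectors, the exact negative gradient of total_energy."""
    return total_energy(frame, topo, ff, method=method, forces=True).forces


def _bond_term(x, box, topo: Topology, ff: ForceField, f) -> float:
    if len(topo.bonds) == 0:
        return 0.0
    K = np.array([ff.bonds[c].K for c in topo.bond_classes])
    b0 = np.array([ff.bonds[c].b0 for c in topo.bond_classes])
    i, j = topo.bonds[:, 0], topo.bonds[:, 1]
    d = minimum_image(x[i] - x[j], box)
    b = np.linalg.norm(d, axis=1)
    e = K * (b - b0) ** 2
    if f is not None:
        dudb = 2.0 * K * (b - b0)
        fv = (-dudb / b)[:, None] * d
        np.add.at(f, i, fv)
        np.add.at(f, j, -fv)
    return float(e.sum())


def _angle_term(x, box, topo: Topology, ff: ForceField, f) -> float:
    if len(topo.angles) == 0:
        return 0.0
    K = np.array([ff.angles[c].K for c in topo.angle_classes])
    t0 = np.array([ff.angles[c].theta0 for c in topo.angle_classes])
    i, j, k = topo.angles.T
    u = minimum_image(x[i] - x[j], box)
    v = minimum_image(x[k] - x[j], box)
    ru = np.linalg.norm(u, axis=1)
    rv = np.linalg.norm(v, axis=1)
    uh = u / ru[:, None]
    vh = v / rv[:, None]
    c = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    e = K * (theta - t0) ** 2
    if f is not None:
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-16))
        dudt = 2.0 * K * (theta - t0)
        dti = (c[:, None] * uh - vh) / (ru * s)[:, None]
        dtk = (c[:, None] * vh - uh) / (rv * s)[:, None]
        np.add.at(f, i, -dudt[:, None] * dti)
        np.add.at(f, k, -dudt[:, None] * dtk)
        np.add.at(f, j, dudt[:, None] * (dti + dtk))
    return float(e.sum())


def dihedral_angle(x, box, quad: np.ndarray) -> np.ndarray:
    """Signed dihedral angles for (M, 4) index rows, in (−π, π]."""
    i, j, k, l = quad.T
    b1 = minimum_image(x[j] - x[i], box)
    b2 = minimum_image(x[k] - x[j], box)
    b3 = minimum_image(x[l] - x[k], box)
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    r2 = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(m, n), b2) / r2
    c = np.einsum("ij,ij->i", m, n)
    return np.arctan2(y, c)


def _dihedral_gradients(x, box, quad):
    """dφ/dr for each of the four sites; returns (phi, gi, gj, gk, gl)."""
    i, j, k, l = quad.T
    b1 = minimum_image(x[j] - x[i], box)
    b2 = minimum_image(x[k] - x[j], box)
    b3 = minimum_image(x[l] - x[k], box)
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    r2 = np.linalg.norm(b2, axis=1)
    y = np.einsum("ij,ij->i", np.cross(m, n), b2) / r2
    c = np.einsum("ij,ij->i", m, n)
    phi = np.arctan2(y, c)
    m2 = np.einsum("ij,ij->i", m, m)
    n2 = np.einsum("ij,ij->i", n, n)
    gi = -(r2 / m2)[:, None] * m
    gl = (r2 / n2)[:, None] * n
    p = np.einsum("ij,ij->i", b1, b2) / r2**2
    q = np.einsum("ij,ij->i", b3, b2) / r2**2
    gj = -(1.0 + p)[:, None] * gi + q[:, None] * gl
    gk = p[:, None] * gi - (1.0 + q)[:, None] * gl
    return phi, gi, gj, gk, gl


def _dihedral_term(x, box, topo: Topology, ff: ForceField, f) -> float:
    e_total = 0.0
    if len(topo.dihedrals):
        K = np.array([ff.dihedrals[c].K for c in topo.dihedral_classes])  # (M,3)
        P = np.array([ff.dihedrals[c].phi for c in topo.dihedral_classes])
        if f is None:
            phi = dihedral_angle(x, box, topo.dihedrals)
        else:
            phi, gi, gj, gk, gl = _dihedral_gradients(x, box, topo.dihedrals)
        ns = np.arange(1, 4)[None, :]
        e = (K * (1.0 - np.cos(ns * phi[:, None] - P))).sum(axis=1)
        e_total += float(e.sum())
        if f is not None:
            dudphi = (K * ns * np.sin(ns * phi[:, None] - P)).sum(axis=1)
            idx = topo.dihedrals
            for col, g in zip(idx.T, (gi, gj, gk, gl)):
                np.add.at(f, col, -dudphi[:, None] * g)
    if len(topo.quad_dihedrals):
        K = np.array([ff.quad_dihedrals[c].K for c in topo.quad_dihedral_classes])
        phi0 = np.array([ff.quad_dihedrals[c].phi0
                         for c in topo.quad_dihedral_classes])
        if f is None:
            phi = dihedral_angle(x, box, topo.quad_dihedrals)
        else:
            phi, gi, gj, gk, gl = _dihedral_gradients(x, box, topo.quad_dihedrals)
        d = (phi - phi0 + np.pi) % (2.0 * np.pi) - np.pi
        e_total += float((K * d * d).sum())
        if f is not None:
            dudphi = 2.0 * K * d
            idx = topo.quad_dihedrals
            for col, g in zip(idx.T, (gi, gj, gk, gl)):
                np.add.at(f, col, -dudphi[:, None] * g)
    return e_total
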
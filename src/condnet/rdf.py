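"""Radial distribution functions, coordination numbers, and potentials of
mean force.

g(r) is the pair-correlation function normalized to an ideal gas at the
global number density of the partner set; the running coordination number

    n(r) = 4 pi rho \\int_0^r g(s) s^2 ds

counts partners within radius r, and its value at the first minimum of
g(r) is the nearest-neighbor coordination number (≈12-13 for a
Lennard-Jones liquid, ≈4 for the pentamer network fluid).  Histograms use
half-open bins [r, r+dr) with centers at r + dr/2, under the minimum-image
convention; pair counting is exact (dual-tree counting on the periodic
box), matching a brute-force histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .topology import Frame, Trajectory


class NoMinimumError(ValueError):
    """g(r) has no resolvable first minimum after its first maximum."""


@dataclass
class RDFResult:
    r: np.ndarray              # bin centers
    g: np.ndarray
    dr: float
    rho: float                 # number density of set B
    set_a: str = "all"
    set_b: str = "all"
    sem: np.ndarray | None = None
    n_frames: int = 1

    @property
    def n_cumulative(self) -> np.ndarray:
        """Running coordination number n(r) at the outer bin edges."""
        return _coordination_curve(self.r, self.g, self.dr, self.rho)


@dataclass
class PMFProfile:
    r: np.ndarray
    w: np.ndarray              # NaN where g == 0
    temperature: float


def _coordination_curve(r, g, dr, rho) -> np.ndarray:
    integrand = g * r * r
    # trapezoid from r=0 (integrand 0) through successive bin centers
    xs = np.concatenate([[0.0], r])
    ys = np.concatenate([[0.0], integrand])
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (ys[1:] + ys[:-1]) * np.diff(xs))])
    return 4.0 * np.pi * rho * cum[1:]


def compute_rdf(traj, set_a=None, set_b=None, dr: float = 0.05,
                r_max: float | None = None, frames=None,
                set_a_label: str = "all", set_b_label: str = "all",
                ) -> RDFResult:
    """Radial distribution function between two bead selections.

    Parameters
    ----------
    traj : Trajectory or Frame
    set_a, set_b : integer index arrays (None means all beads); identical
        sets exclude self-pairs, disjoint sets pool all cross pairs
        (composite selections are a linear superposition of pair
        distributions); partially overlapping sets are rejected.
    dr : bin width.
    r_max : histogram range; must not exceed half the smallest box edge.
    frames : optional selection (slice or index list) of frames.
    """
    frames_list = _as_frames(traj, frames)
    box = frames_list[0].box
    if r_max is None:
        r_max = 0.5 * float(box.min())
    if r_max > 0.5 * float(box.min()) * (1 + 1e-9):
        raise ValueError(
            f"r_max {r_max} exceeds half the smallest box edge "
            f"{0.5 * box.min()}; refusing to truncate silently")
    n = frames_list[0].n_beads
    ia = np.arange(n) if set_a is None else np.asarray(set_a, dtype=np.int64)
    ib = np.arange(n) if set_b is None else np.asarray(set_b, dtype=np.int64)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("selections must be non-empty")
    identical = ia.size == ib.size and np.array_equal(np.sort(ia), np.sort(ib))
    if not identical and np.intersect1d(ia, ib).size:
        raise ValueError("partially overlapping selections are not supported")

    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    nbins = len(edges) - 1
    counts = np.zeros(nbins)
    vol = float(np.prod(box))
    for fr in frames_list:
        pa = np.mod(fr.coords[ia], box)
        pb = np.mod(fr.coords[ib], box)
        ta = cKDTree(pa, boxsize=box)
        tb = ta if identical else cKDTree(pb, boxsize=box)
        cum = ta.count_neighbors(tb, edges[1:])
        if identical:
            cum = cum - ia.size  # remove self pairs (r = 0)
        counts += np.diff(np.concatenate([[0], cum]))

    nf = len(frames_list)
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    npartner = ib.size - 1 if identical else ib.size
    ideal = ia.size * npartner / vol * shell
    g = counts / (nf * ideal)
    centers = edges[:-1] + 0.5 * dr
    rho = ib.size / vol
    return RDFResult(r=centers, g=g, dr=dr, rho=rho, n_frames=nf,
                     set_a=set_a_label, set_b=set_b_label)


def _as_frames(traj, frames) -> list[Frame]:
    if isinstance(traj, Frame):
        return [traj]
    fl = list(traj.frames if isinstance(traj, Trajectory) else traj)
    if frames is not None:
        if isinstance(frames, slice):
            fl = fl[frames]
        else:
            fl = [fl[i] for i in np.atleast_1d(frames)]
    if not fl:
        raise ValueError("no frames selected")
    return fl


def smooth_moving_average(y: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with edge shrinkage."""
    if window <= 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window) / window
    pad = window // 2
    yp = np.pad(np.asarray(y, dtype=float), pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")


def first_minimum(rdf: RDFResult, smooth_window: int = 5,
                  peak_prominence: float = 0.05,
                  min_prominence: float = 0.005) -> float:
    """r of the first local minimum of g(r) after its first maximum.

    The curve is smoothed with a centered moving average before extremum
    detection.  The first maximum must be a genuine structural peak
    (prominence above ``peak_prominence``); the subsequent minimum only
    needs ``min_prominence``, so that a dilute phase whose g(r) decays
    almost monotonically after its contact peak still yields a cutoff at
    its first dip.  Structureless profiles raise
    :class:`NoMinimumError` instead of returning a silent default.
    """
    from scipy.signal import find_peaks

    g = smooth_moving_average(rdf.g, smooth_window)
    maxima, _ = find_peaks(g, prominence=peak_prominence)
    if maxima.size == 0:
        raise NoMinimumError("g(r) has no peak; cannot locate a first minimum")
    first_max = maxima[0]
    minima, _ = find_peaks(-g[first_max:], prominence=min_prominence)
    if minima.size == 0:
        raise NoMinimumError("g(r) has no local minimum after its first peak")
    return float(rdf.r[first_max + minima[0]])


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """n = 4 pi rho \\int_0^{r_cut} g(r) r^2 dr (trapezoidal on the bins)."""
    if r_cut < rdf.r[0] or r_cut > rdf.r[-1] + 0.5 * rdf.dr:
        raise ValueError("r_cut outside the histogram range")
    mask = rdf.r <= r_cut
    xs = np.concatenate([[0.0], rdf.r[mask], [r_cut]])
    gi = np.interp(r_cut, rdf.r, rdf.g)
    ys = np.concatenate([[0.0], (rdf.g * rdf.r ** 2)[mask], [gi * r_cut ** 2]])
    integral = np.trapezoid(ys, xs)
    return float(4.0 * np.pi * rdf.rho * integral)


def pmf_from_rdf(rdf: RDFResult, T: float, kb: float = 1.0) -> PMFProfile:
    """Boltzmann inversion w(r) = -k_B T ln g(r), NaN-masked where g = 0."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    with np.errstate(divide="ignore"):
        w = np.where(rdf.g > 0, -kb * T * np.log(np.where(rdf.g > 0, rdf.g, 1.0)),
                     np.nan)
    return PMFProfile(r=rdf.r.copy(), w=w, temperature=T)


def brute_force_rdf(frame: Frame, set_a, set_b, dr: float,
                    r_max: float) -> np.ndarray:
    """O(N^2) single-frame pair histogram (test oracle): raw bin counts."""
    ia = np.asarray(set_a, dtype=np.int64)
    ib = np.asarray(set_b, dtype=np.int64)
    identical = ia.size == ib.size and np.array_equal(np.sort(ia), np.sort(ib))
    d = frame.coords[ia][:, None, :] - frame.coords[ib][None, :, :]
    d -= frame.box * np.round(d / frame.box)
    r = np.sqrt((d ** 2).sum(axis=-1)).ravel()
    if identical:
        r = r[r > 0]
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    counts, _ = np.histogram(r, bins=edges)
    return counts.astype(float)
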
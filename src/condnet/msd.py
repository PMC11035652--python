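"""Mean squared displacements and anomalous-diffusion regime analysis.

The MSD is doubly averaged: for each window length m, displacements are
averaged over all (frames − m) start frames, then over all selected
particles,

    MSD(m) = (1/N) Σ_i (1/(T−m)) Σ_k |r_i(k+m) − r_i(k)|²,

with T the frame count.  Super- and sub-diffusive regimes are
characterized by power-law exponents fitted on log MSD vs log t; the
diffusive window is the contiguous region where a purely proportional
MSD ∝ t model fits with R² above threshold, and the crossover time t_D is
the median lag time inside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .topology import Trajectory


class NoDiffusiveRegime(ValueError):
    """No lag window fits a purely diffusive MSD ∝ t model."""


@dataclass
class MSDResult:
    lags: np.ndarray           # integer window lengths m = 0..T-1
    times: np.ndarray          # m * frame_interval
    msd: np.ndarray
    selection: str = "all"
    per_particle: np.ndarray | None = None   # (T, n_sel) per-particle curves
    particle_ids: np.ndarray | None = None


@dataclass
class RegimeFit:
    window: tuple[float, float]
    alpha: float
    prefactor: float
    r_squared: float
    t_D: float | None = None

    def t_prime(self, t) -> np.ndarray:
        """Lag times normalized by the diffusive crossover time."""
        if self.t_D is None:
            raise ValueError("fit carries no diffusive timescale")
        return np.asarray(t) / self.t_D


def compute_msd(traj: Trajectory, selection=None, per_particle: bool = False,
                selection_label: str = "all") -> MSDResult:
    """Window-averaged MSD of the selected particles.

    Requires unwrapped coordinates (image flags); a trajectory without
    them is rejected rather than silently producing wrap artifacts.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames")
    x = traj.unwrapped_array()
    if selection is not None:
        sel = np.asarray(selection, dtype=np.int64)
        x = x[:, sel, :]
    else:
        sel = np.arange(x.shape[1])
    T = x.shape[0]
    dtf = traj.frame_interval if traj.frame_interval else 1.0
    msd = np.zeros(T)
    per = np.zeros((T, x.shape[1])) if per_particle else None
    for m in range(1, T):
        d = x[m:] - x[:-m]
        sq = (d * d).sum(axis=2)        # (T-m, n)
        per_part = sq.mean(axis=0)       # window average per particle
        if per_particle:
            per[m] = per_part
        msd[m] = per_part.mean()
    return MSDResult(lags=np.arange(T), times=np.arange(T) * dtf, msd=msd,
                     selection=selection_label, per_particle=per,
                     particle_ids=sel)


def msd_oracle(x: np.ndarray) -> np.ndarray:
    """Naive triple-loop MSD of an (T, N, 3) array (test oracle)."""
    T, n, _ = x.shape
    out = np.zeros(T)
    for m in range(1, T):
        acc = 0.0
        for i in range(n):
            s = 0.0
            for k in range(T - m):
                d = x[k + m, i] - x[k, i]
                s += float(d @ d)
            acc += s / (T - m)
        out[m] = acc / n
    return out


def fit_exponent(msd: MSDResult, window: tuple[float, float],
                 curve: np.ndarray | None = None) -> RegimeFit:
    """Power-law exponent from a least-squares line on log msd vs log t."""
    y_all = msd.msd if curve is None else curve
    t = msd.times
    mask = (t >= window[0]) & (t <= window[1]) & (t > 0) & (y_all > 0)
    if mask.sum() < 5:
        raise ValueError(
            f"fewer than 5 usable lags in window {window}; cannot fit")
    lt = np.log(t[mask])
    ly = np.log(y_all[mask])
    slope, intercept = np.polyfit(lt, ly, 1)
    pred = slope * lt + intercept
    ss_res = float(((ly - pred) ** 2).sum())
    ss_tot = float(((ly - ly.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegimeFit(window=window, alpha=float(slope),
                     prefactor=float(np.exp(intercept)), r_squared=r2)


def _proportional_r2(t: np.ndarray, y: np.ndarray) -> float:
    """R² of the through-origin model y = c t."""
    c = float((t * y).sum() / (t * t).sum())
    res = y - c * t
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return 1.0 - float((res * res).sum()) / ss_tot


def find_diffusive_window(msd: MSDResult, width_factor: float = 1.5,
                          r2_threshold: float = 0.99,
                          min_points: int = 5) -> RegimeFit:
    """Locate the lag window best described by simple diffusion.

    Sliding windows spanning a fixed factor in lag time are scored by the
    R² of an MSD ∝ t fit; the contiguous run of passing windows containing
    the best one defines the diffusive region, and t_D is the median lag
    time within it.  Raises :class:`NoDiffusiveRegime` when nothing
    passes (e.g. purely ballistic motion).
    """
    t = msd.times
    y = msd.msd
    usable = np.flatnonzero((t > 0) & (y > 0))
    if usable.size < 20:
        raise ValueError("need at least 20 usable lags")
    scores = []
    spans = []
    for s in usable:
        hi = t[s] * width_factor
        win = usable[(t[usable] >= t[s]) & (t[usable] <= hi)]
        if win.size < min_points or t[win[-1]] < hi * 0.999:
            continue
        scores.append(_proportional_r2(t[win], y[win]))
        spans.append((s, win[-1]))
    if not scores:
        raise ValueError("trajectory too short for the requested window width")
    scores = np.asarray(scores)
    passing = scores >= r2_threshold
    if not passing.any():
        raise NoDiffusiveRegime(
            f"best proportional-fit R² {scores.max():.4f} below threshold "
            f"{r2_threshold}")
    best = int(np.argmax(scores))
    lo = best
    while lo > 0 and passing[lo - 1]:
        lo -= 1
    hi = best
    while hi < len(scores) - 1 and passing[hi + 1]:
        hi += 1
    i0 = spans[lo][0]
    i1 = spans[hi][1]
    window = (float(t[i0]), float(t[i1]))
    region = usable[(usable >= i0) & (usable <= i1)]
    t_d = float(np.median(t[region]))
    fit = fit_exponent(msd, window)
    fit.t_D = t_d
    fit.r_squared = float(scores[best])
    return fit


def default_regime_windows(msd: MSDResult,
                           early_frac: float = 0.07,
                           late_frac: float = 0.5,
                           ) -> tuple[tuple[float, float], tuple[float, float]]:
    """Early (super-diffusive) and late (sub-diffusive) fit windows.

    Scaled analogs of fitting the first ~30 ps and everything past
    ~400 ps of a few-ns trajectory: the first ``early_frac`` of lag times
    and the last ``late_frac``.
    """
    tmax = msd.times[-1]
    dt0 = msd.times[1]
    return (dt0, max(early_frac * tmax, 6 * dt0)), (late_frac * tmax, tmax)


def exponent_histogram(traj: Trajectory, selection=None,
                       windows=None) -> pd.DataFrame:
    """Per-particle power-law exponents in the regime windows.

    Fits each particle's own window-averaged MSD in the early and late
    windows.  Failures (static particles, non-positive MSD) are recorded
    as NaN rather than aborting the ensemble; negative exponents are kept
    (they reflect fit uncertainty, not physics).
    """
    msd = compute_msd(traj, selection=selection, per_particle=True)
    if windows is None:
        windows = default_regime_windows(msd)
    rows = []
    for col, pid in enumerate(msd.particle_ids):
        row = {"particle": int(pid)}
        for name, win in zip(("alpha_early", "alpha_late"), windows):
            try:
                fit = fit_exponent(msd, win, curve=msd.per_particle[:, col])
                row[name] = fit.alpha
            except ValueError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("particle")
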
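"""Small-angle-scattering utilities: Debye form factors and peak analysis.

The unit-cross-section form factor of a rigid particle is the
orientationally averaged Debye sum

    P(q) = (1/N²) Σ_ij sin(q r_ij)/(q r_ij),

normalized so P(q→0) = 1.  Correlation peaks in measured I(q) profiles
are located either from the curvature of log I vs log q (derivative
method) or by fitting a power-law background plus Gaussian components
(multi-Gaussian method); peak positions map to real-space lengths through
the Bragg-like relation d = 2π/q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, savgol_filter


@dataclass
class ScatteringProfile:
    q: np.ndarray              # inverse length, strictly increasing
    intensity: np.ndarray
    uncertainty: np.ndarray | None = None
    kind: str = "measured"     # "measured" I(q) or "computed" P(q)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.kind == "computed" and np.any(self.intensity < -1e-12):
            raise ValueError("computed P(q) must be non-negative")


@dataclass
class PeakSet:
    q: np.ndarray
    prominence: np.ndarray
    method: str

    @property
    def d(self) -> np.ndarray:
        """Real-space correlation lengths d = 2π/q."""
        return 2.0 * np.pi / self.q

    def __len__(self) -> int:
        return len(self.q)


def form_factor(coords: np.ndarray, q_grid: np.ndarray,
                chunk: int = 2_000_000) -> ScatteringProfile:
    """Orientationally averaged unit-cross-section Debye form factor."""
    x = np.asarray(coords, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 1:
        raise ValueError("coords must be (N, 3) with N >= 1")
    if np.any(q <= 0):
        raise ValueError("q must be positive")
    n = x.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    p = np.zeros_like(q)
    for s in range(0, len(iu), max(chunk // max(len(q), 1), 1)):
        sl = slice(s, s + max(chunk // max(len(q), 1), 1))
        r = np.linalg.norm(x[iu[sl]] - x[ju[sl]], axis=1)
        qr = q[:, None] * r[None, :]
        p += np.sinc(qr / np.pi).sum(axis=1)
    p = (n + 2.0 * p) / n ** 2   # i = j terms contribute 1 each
    return ScatteringProfile(q=q, intensity=p, kind="computed")


def detect_peaks(profile: ScatteringProfile, method: str = "derivative",
                 prominence: float | None = None, smooth_frac: float = 0.03,
                 n_components: int | None = None) -> PeakSet:
    """Locate correlation peaks in a scattering profile.

    derivative
        Interpolates log I onto a uniform log q grid, Savitzky-Golay
        smooths, and finds prominent minima of the second derivative
        (negative-curvature bumps).  A featureless power law (linear in
        log-log) has zero curvature and yields an empty PeakSet.
    multi_gauss
        Fits A q^{-p} plus Gaussian components, seeded by the derivative
        method (or ``n_components``); returns the fitted centers.
    """
    if len(profile.q) < 20:
        raise ValueError("need at least 20 points")
    if np.any(profile.intensity <= 0):
        raise ValueError("peak detection expects positive intensities")
    if method == "derivative":
        return _detect_derivative(profile, prominence, smooth_frac)
    if method == "multi_gauss":
        return _detect_multigauss(profile, prominence, smooth_frac,
                                  n_components)
    raise ValueError(f"unknown method {method!r}")


def _loglog_curvature(profile, smooth_frac):
    x = np.log(profile.q)
    y = np.log(profile.intensity)
    m = len(x)
    xu = np.linspace(x[0], x[-1], m)
    yu = np.interp(xu, x, y)
    win = max(5, int(smooth_frac * m) | 1)
    if win >= m:
        win = (m - 1) | 1
    ys = savgol_filter(yu, win, polyorder=3)
    dx = xu[1] - xu[0]
    d2 = savgol_filter(yu, win, polyorder=3, deriv=2, delta=dx)
    return xu, yu, ys, d2


def _detect_derivative(profile, prominence, smooth_frac) -> PeakSet:
    xu, yu, ys, d2 = _loglog_curvature(profile, smooth_frac)
    m = len(xu)
    if prominence is None:
        # adaptive floor: well above the round-off/noise curvature level
        mad = np.median(np.abs(d2 - np.median(d2))) * 1.4826
        prominence = max(8.0 * mad, 0.05 * max(-d2.min(), 0.0), 1e-8)
    idx, props = find_peaks(-d2, prominence=prominence)
    keep = d2[idx] < 0
    # drop Savitzky-Golay edge artifacts
    edge = max(3, int(0.06 * m))
    keep &= (idx >= edge) & (idx < m - edge)
    idx = idx[keep]
    if idx.size == 0:
        return PeakSet(q=np.empty(0), prominence=np.empty(0),
                       method="derivative")
    proms = props["prominences"][keep]
    centers = np.array([_refine_center(xu, yu, ys, d2, p) for p in idx])
    order = np.argsort(centers)
    return PeakSet(q=np.exp(centers[order]), prominence=proms[order],
                   method="derivative")


def _refine_center(xu, yu, ys, d2, p) -> float:
    """Refine a curvature detection to the bump apex.

    The negative-curvature region around ``p`` brackets the bump (its
    endpoints sit at the inflections); the bracket is then extended
    downhill to the surrounding valley floors, stopping before any
    neighboring bump.  Within that bracket the apex of the profile is
    taken with a parabolic vertex fit; if the profile is monotone there
    (a weak shoulder on a steep background) the apex of the
    chord-subtracted residual is used instead.
    """
    m = len(xu)
    a = p
    while a > 0 and d2[a - 1] < 0:
        a -= 1
    b = p
    while b < m - 1 and d2[b + 1] < 0:
        b += 1
    if b - a < 2:
        return float(xu[p])
    while a > 0 and ys[a - 1] < ys[a]:
        a -= 1
    while b < m - 1 and ys[b + 1] < ys[b]:
        b += 1
    seg = yu[a:b + 1]
    k = int(np.argmax(seg))
    if k == 0 or k == b - a:
        # monotone segment: weak shoulder; subtract the chord baseline
        base = seg[0] + (seg[-1] - seg[0]) * (xu[a:b + 1] - xu[a]) / (xu[b] - xu[a])
        seg = seg - base
        k = int(np.argmax(seg))
    j = a + k
    if 0 < k < b - a:
        y0, y1, y2 = seg[k - 1], seg[k], seg[k + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return float(xu[j] + 0.5 * (y0 - y2) / denom * (xu[1] - xu[0]))
    return float(xu[j])


def _detect_multigauss(profile, prominence, smooth_frac, n_components):
    seed = _detect_derivative(profile, prominence, smooth_frac)
    centers = list(seed.q)
    if n_components is not None:
        centers = centers[:n_components]
        while len(centers) < n_components:
            centers.append(float(np.sqrt(profile.q[0] * profile.q[-1])))
    if not centers:
        return PeakSet(q=np.empty(0), prominence=np.empty(0),
                       method="multi_gauss")
    q = profile.q
    y = profile.intensity
    k = len(centers)

    def model(qv, *p):
        a, pexp = p[0], p[1]
        out = a * qv ** (-pexp)
        for i in range(k):
            amp, c, w = p[2 + 3 * i: 5 + 3 * i]
            out = out + amp * np.exp(-0.5 * ((qv - c) / w) ** 2)
        return out

    bg0 = y[-1] * q[-1] ** 2
    p0 = [bg0, 2.0]
    lb = [0.0, 0.0]
    ub = [np.inf, 6.0]
    for c in centers:
        amp0 = max(float(np.interp(c, q, y)), 1e-12)
        p0 += [amp0, c, 0.05 * c]
        lb += [0.0, 0.5 * c, 0.005 * c]
        ub += [np.inf, 2.0 * c, 0.5 * c]
    popt, _ = curve_fit(model, q, y, p0=p0, bounds=(lb, ub), maxfev=40000)
    fitted = np.array(sorted(popt[3::3]))
    amps = np.array([popt[2 + 3 * i] for i in np.argsort(popt[3::3])])
    return PeakSet(q=fitted, prominence=amps, method="multi_gauss")
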
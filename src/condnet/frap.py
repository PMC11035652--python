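"""FRAP recovery-curve fitting.

Single-species hyperbolic recovery model

    I(t) = (I0 + I_inf · t/t_half) / (1 + t/t_half)

where I0 is the normalized intensity immediately after the bleach, I_inf
the recovered plateau, and t_half the recovery half-time; by construction
I(t_half) = (I0 + I_inf)/2.  Replicate curves can be fitted jointly with
per-replicate amplitudes and a shared t_half (the protocol used when many
droplets are bleached in one experiment), and intensities may first be
normalized by a global-photobleaching reference trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


@dataclass
class FRAPFit:
    I0: np.ndarray             # per replicate
    I_inf: np.ndarray          # per replicate
    t_half: float
    t_half_se: float
    I0_se: np.ndarray
    I_inf_se: np.ndarray
    cov: np.ndarray
    residuals: np.ndarray
    n_replicates: int

    def predict(self, t, replicate: int = 0) -> np.ndarray:
        return frap_model(np.asarray(t), self.I0[replicate],
                          self.I_inf[replicate], self.t_half)


def frap_model(t, I0: float, I_inf: float, t_half: float) -> np.ndarray:
    x = np.asarray(t, dtype=float) / t_half
    return (I0 + I_inf * x) / (1.0 + x)


def fit_frap(times, intensities, reference=None) -> FRAPFit:
    """Nonlinear least-squares fit of the hyperbolic recovery model.

    Parameters
    ----------
    times : (T,) sample times, non-negative.
    intensities : (T,) single curve or (R, T) replicate stack; replicates
        share t_half (grouped fit) with free per-replicate I0 and I_inf.
    reference : optional (T,) global-photobleaching trace; intensities are
        divided by it before fitting.
    """
    t = np.asarray(times, dtype=float)
    y = np.atleast_2d(np.asarray(intensities, dtype=float))
    if t.ndim != 1 or y.shape[1] != t.size:
        raise ValueError("times and intensities shapes disagree")
    if t.size < 6:
        raise ValueError("need at least 6 time points")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if reference is not None:
        ref = np.asarray(reference, dtype=float)
        if np.any(ref <= 0):
            raise ValueError("reference trace must be positive")
        y = y / ref
    nrep = y.shape[0]

    # parameters: [I0_r..., Iinf_r..., log(t_half)]
    p0 = np.concatenate([y[:, 0], y[:, -1],
                         [np.log(max(np.median(t[t > 0]), 1e-6))]])

    def resid(p):
        i0 = p[:nrep]
        iinf = p[nrep:2 * nrep]
        th = np.exp(p[-1])
        return (frap_model(t[None, :].repeat(nrep, 0).ravel(),
                           np.repeat(i0, t.size), np.repeat(iinf, t.size), th)
                - y.ravel())

    sol = least_squares(resid, p0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(
            f"FRAP fit failed: {sol.message}; final residual norm "
            f"{np.linalg.norm(sol.fun):.3g}")
    dof = max(y.size - sol.x.size, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
    except np.linalg.LinAlgError:
        cov = np.full((sol.x.size, sol.x.size), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    th = float(np.exp(sol.x[-1]))
    # delta method for t_half = exp(p)
    th_se = float(se[-1] * th)
    return FRAPFit(I0=sol.x[:nrep].copy(), I_inf=sol.x[nrep:2 * nrep].copy(),
                   t_half=th, t_half_se=th_se,
                   I0_se=se[:nrep].copy(), I_inf_se=se[nrep:2 * nrep].copy(),
                   cov=cov, residuals=sol.fun.reshape(y.shape),
                   n_replicates=nrep)
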
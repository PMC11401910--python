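"""Hill-equation fits to binding titrations.

The isotherm is ``S_obs = S_U + (S_B - S_U)/(1 + (Kd_app/[L])^n)`` with
unbound/bound signal plateaus S_U and S_B, apparent dissociation constant
Kd_app (same units as [L], microM by convention here) and Hill coefficient
n.  Fitting is unweighted nonlinear least squares in linear signal space;
Kd_app and n are kept positive by fitting their logarithms internally and
reported on the natural scale with delta-method standard errors from the
local curvature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["hill_model", "fit_hill", "HillFitResult"]


def hill_model(L, S_U: float, S_B: float, Kd_app: float, n: float):
    """Hill isotherm evaluated at ligand concentration(s) ``L``."""
    L = np.asarray(L, dtype=float)
    return S_U + (S_B - S_U) / (1.0 + (Kd_app / L) ** n)


@dataclass
class HillFitResult:
    S_U: float
    S_B: float
    Kd_app: float
    n: float
    se: dict = field(default_factory=dict)      # parameter -> standard error
    rss: float = 0.0                            # residual sum of squares
    rmsd: float = 0.0
    converged: bool = True
    warnings: list = field(default_factory=list)

    def predict(self, L):
        return hill_model(L, self.S_U, self.S_B, self.Kd_app, self.n)

    def to_dict(self) -> dict:
        return {
            "S_U": self.S_U, "S_B": self.S_B, "Kd_app": self.Kd_app,
            "n": self.n, "se": dict(self.se), "rss": self.rss,
            "rmsd": self.rmsd, "converged": self.converged,
            "warnings": list(self.warnings),
        }


def _auto_init(conc: np.ndarray, signal: np.ndarray):
    order = np.argsort(conc)
    c, s = conc[order], signal[order]
    s_u = float(np.mean(s[:max(1, len(s) // 8)]))
    s_b = float(np.mean(s[-max(1, len(s) // 8):]))
    half = 0.5 * (s_u + s_b)
    # first crossing of the half-signal level
    sign = np.sign(s - half)
    cross = np.nonzero(np.diff(sign) != 0)[0]
    kd = float(np.sqrt(c[cross[0]] * c[cross[0] + 1])) if cross.size \
        else float(np.sqrt(c[0] * c[-1]))
    return s_u, s_b, kd, 1.0


def fit_hill(concentrations, signals, init="auto") -> HillFitResult:
    """Fit the Hill isotherm; never silent about trouble.

    ``init`` is either ``"auto"`` (plateaus from the extreme concentrations,
    Kd from the half-signal crossing, n = 1) or a tuple
    ``(S_U, S_B, Kd_app, n)``.  Warnings are recorded on the result for
    sparse designs (< 5 points) and for an unconstrained upper plateau
    (no data beyond Kd_app); non-convergence sets ``converged=False``.
    """
    conc = np.asarray(concentrations, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if conc.size != sig.size:
        raise ValueError("concentrations and signals differ in length")
    if conc.size < 4:
        raise ValueError("need at least 4 titration points")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    notes = []
    if conc.size < 5:
        notes.append("fewer than 5 points: transition poorly constrained")

    p0 = _auto_init(conc, sig) if init == "auto" else tuple(init)
    s_u0, s_b0, kd0, n0 = p0
    theta0 = [s_u0, s_b0, np.log(max(kd0, 1e-12)), np.log(n0)]

    def model_log(L, s_u, s_b, log_kd, log_n):
        return hill_model(L, s_u, s_b, np.exp(log_kd), np.exp(log_n))

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theta, cov = curve_fit(model_log, conc, sig, p0=theta0,
                                   maxfev=20000)
    except RuntimeError:
        converged = False
        theta, cov = np.asarray(theta0), np.full((4, 4), np.nan)

    s_u, s_b = float(theta[0]), float(theta[1])
    kd, n = float(np.exp(theta[2])), float(np.exp(theta[3]))
    diag = np.diag(cov)
    if np.any(~np.isfinite(diag)):
        notes.append("singular curvature: standard errors unreliable")
    se_theta = np.sqrt(np.abs(diag))
    se = {
        "S_U": float(se_theta[0]),
        "S_B": float(se_theta[1]),
        "Kd_app": float(kd * se_theta[2]),   # delta method on log-scale SE
        "n": float(n * se_theta[3]),
    }
    resid = sig - hill_model(conc, s_u, s_b, kd, n)
    rss = float(np.sum(resid ** 2))
    if conc.max() < kd:
        notes.append("no plateau at high concentration: S_B unconstrained")
        converged = converged and False
    return HillFitResult(S_U=s_u, S_B=s_b, Kd_app=kd, n=n, se=se, rss=rss,
                         rmsd=float(np.sqrt(rss / conc.size)),
                         converged=converged, warnings=notes)
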
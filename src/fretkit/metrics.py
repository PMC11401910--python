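"""Raw and corrected FRET efficiency/stoichiometry and the burst filters.

Per burst the background-subtracted counts are

``F_xy = n_xy - rate_xy * duration`` (floored at 0),

giving the proximity ratio ``E_raw = F_DA/(F_DD+F_DA)`` and raw
stoichiometry ``S_raw = (F_DD+F_DA)/(F_DD+F_DA+F_AA)``.  The consensus
correction chain removes donor leakage ``lk`` and acceptor direct
excitation ``dir`` from the FRET signal and rescales by the detection
factor ``gamma`` and excitation factor ``beta``:

``F_DA' = F_DA - lk*F_DD - dir*F_AA``
``E = F_DA' / (F_DA' + gamma*F_DD)``
``S = (F_DA' + gamma*F_DD) / (F_DA' + gamma*F_DD + F_AA/beta)``

Corrected E and S are *not* clipped to [0, 1]: shot noise legitimately
carries them slightly outside.

The ALEX-2CDE score flags bursts whose donor-excitation and
acceptor-excitation photons are segregated in time (acceptor bleaching,
blinking, multi-molecule events).  With the exponential kernel density
``KDE_X(t) = sum_{j in X} exp(-|t - t_j|/tau)`` evaluated over a burst's
Dex and Aex photon sets, the score is

``ALEX-2CDE = 100 - 50*(BR_DA + BR_AD)``
``BR_DA = (1/N_Dex) * sum_{j in Aex} KDE_Dex(t_j)/KDE_Aex(t_j)``
``BR_AD = (1/N_Aex) * sum_{i in Dex} KDE_Aex(t_i)/KDE_Dex(t_i)``

Well-mixed bursts score near 0; fully segregated bursts approach 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import BackgroundEstimate
from .photons import PhotonStream, SLOT_AEX, SLOT_DEX

__all__ = ["CorrectionSet", "raw_es", "corrected_es", "alex_2cde",
           "filter_bursts", "compute_metrics", "histogram_mode"]


@dataclass
class CorrectionSet:
    """Crosstalk/detection corrections: leakage, direct excitation, gamma, beta."""

    lk: float = 0.14
    dir: float = 0.14
    gamma: float = 1.0
    beta: float = 1.4

    def __post_init__(self) -> None:
        if self.lk < 0 or self.dir < 0:
            raise ValueError("lk and dir must be >= 0")
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be positive")

    @classmethod
    def neutral(cls) -> "CorrectionSet":
        return cls(lk=0.0, dir=0.0, gamma=1.0, beta=1.0)


def _bg_counts(bursts: pd.DataFrame, bg: BackgroundEstimate):
    seg = bursts["segment"].to_numpy()
    dur = bursts["duration"].to_numpy()
    f_dd = np.maximum(bursts["n_dd"].to_numpy() - bg.rates["dex_d"][seg] * dur, 0.0)
    f_da = np.maximum(bursts["n_da"].to_numpy() - bg.rates["dex_a"][seg] * dur, 0.0)
    f_aa = np.maximum(bursts["n_aa"].to_numpy() - bg.rates["aex_a"][seg] * dur, 0.0)
    return f_dd, f_da, f_aa


def raw_es(bursts: pd.DataFrame, bg: BackgroundEstimate):
    """Uncorrected (E_raw, S_raw) per burst; NaN where the Dex signal vanishes."""
    f_dd, f_da, f_aa = _bg_counts(bursts, bg)
    dex = f_dd + f_da
    with np.errstate(divide="ignore", invalid="ignore"):
        e_raw = np.where(dex > 0, f_da / dex, np.nan)
        s_raw = np.where(dex + f_aa > 0, dex / (dex + f_aa), np.nan)
    return e_raw, s_raw


def corrected_es(bursts: pd.DataFrame, bg: BackgroundEstimate,
                 c: CorrectionSet):
    """Corrected (E, S) per burst via the consensus correction chain."""
    f_dd, f_da, f_aa = _bg_counts(bursts, bg)
    f_da_c = f_da - c.lk * f_dd - c.dir * f_aa
    dex_c = f_da_c + c.gamma * f_dd
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(dex_c != 0, f_da_c / dex_c, np.nan)
        s_den = dex_c + f_aa / c.beta
        s = np.where(s_den != 0, dex_c / s_den, np.nan)
    return e, s


# ---------------------------------------------------------------------------
# ALEX-2CDE
# ---------------------------------------------------------------------------

def _kde_sums(t_query: np.ndarray, t_source: np.ndarray, tau: float) -> np.ndarray:
    """KDE of the source photon set at each query time (self terms included
    when the arrays share elements)."""
    if t_source.size == 0:
        return np.zeros(t_query.size)
    out = np.empty(t_query.size)
    for lo in range(0, t_query.size, 512):  # chunked: bounds memory at ~512*n
        q = t_query[lo:lo + 512, None]
        out[lo:lo + 512] = np.exp(-np.abs(q - t_source[None, :]) / tau).sum(axis=1)
    return out


def alex_2cde(stream: PhotonStream, bursts: pd.DataFrame,
              kde_tau: float = 100e-6) -> np.ndarray:
    """ALEX-2CDE score per burst (100.0 when one excitation slot is empty)."""
    times = stream.times
    slots = stream.slots
    scores = np.empty(len(bursts))
    t_start = bursts["t_start"].to_numpy()
    t_stop = bursts["t_stop"].to_numpy()
    lo = np.searchsorted(times, t_start, side="left")
    hi = np.searchsorted(times, t_stop, side="right")
    for k in range(len(bursts)):
        sl = slice(lo[k], hi[k])
        t = times[sl]
        s = slots[sl]
        t_dex = t[s == SLOT_DEX]
        t_aex = t[s == SLOT_AEX]
        if t_dex.size == 0 or t_aex.size == 0:
            scores[k] = 100.0
            continue
        kde_dex_at_aex = _kde_sums(t_aex, t_dex, kde_tau)
        kde_aex_at_aex = _kde_sums(t_aex, t_aex, kde_tau)
        kde_aex_at_dex = _kde_sums(t_dex, t_aex, kde_tau)
        kde_dex_at_dex = _kde_sums(t_dex, t_dex, kde_tau)
        br_da = np.sum(kde_dex_at_aex / kde_aex_at_aex) / t_dex.size
        br_ad = np.sum(kde_aex_at_dex / kde_dex_at_dex) / t_aex.size
        scores[k] = 100.0 - 50.0 * (br_da + br_ad)
    return scores


# ---------------------------------------------------------------------------
# Filters and the combined metrics table
# ---------------------------------------------------------------------------

def filter_bursts(metrics: pd.DataFrame, s_min: float = 0.3,
                  s_max: float = 0.7, cde_max: float = 95.0) -> pd.DataFrame:
    """Apply the stoichiometry-range and ALEX-2CDE filters.

    Adds boolean ``passed`` and a semicolon-joined ``reason`` column; the
    2CDE cutoff is inclusive (score == cde_max is kept).  Filters commute:
    the verdict is independent of application order.
    """
    if s_min >= s_max:
        raise ValueError("s_min must be < s_max")
    out = metrics.copy()
    s = out["s_corr"].to_numpy()
    cde = out["alex2cde"].to_numpy()
    reasons = []
    for k in range(len(out)):
        r = []
        if np.isnan(s[k]):
            r.append("undefined_s")
        elif not (s_min <= s[k] <= s_max):
            r.append("s_range")
        if cde[k] > cde_max:
            r.append("alex2cde")
        if np.isnan(out["e_corr"].iloc[k]):
            r.append("no_dex_signal")
        reasons.append(";".join(r))
    out["reason"] = reasons
    out["passed"] = [r == "" for r in reasons]
    return out


def compute_metrics(stream: PhotonStream, bursts: pd.DataFrame,
                    bg: BackgroundEstimate, c: CorrectionSet,
                    kde_tau: float = 100e-6) -> pd.DataFrame:
    """Burst table annotated with E_raw/S_raw, corrected E/S and ALEX-2CDE."""
    out = bursts.copy()
    out["e_raw"], out["s_raw"] = raw_es(bursts, bg)
    out["e_corr"], out["s_corr"] = corrected_es(bursts, bg, c)
    out["alex2cde"] = alex_2cde(stream, bursts, kde_tau) if len(bursts) \
        else np.empty(0)
    return out


def histogram_mode(values, bin_width: float = 0.02,
                   lo: float = -0.2, hi: float = 1.2) -> float:
    """Centre of the most populated histogram bin (NaNs ignored)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(v, bins=edges)
    k = int(np.argmax(counts))
    return float(edges[k] + bin_width / 2)
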
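"""Dynamics detection: burst variance analysis (BVA) and lifetime FRET-lines.

BVA
---
Within each burst the Dex-slot photons are segmented, in time order, into
consecutive non-overlapping windows of ``window_n`` (default 5) photons;
trailing remainder photons are discarded.  Each window's acceptor fraction
is its A-channel count over ``window_n``; the burst statistic ``s_i`` is
the *population* standard deviation of those fractions.  For a
conformationally static molecule the window counts are binomial, so the
expected standard deviation is ``sqrt(E*(1-E)/window_n)`` — the static
line.  Excess ``s_i`` in intermediate-E_raw bins reveals interconversion
on the burst (~ms) timescale.  BVA deliberately uses raw, non-background-
subtracted, uncorrected acceptor fractions: the shot-noise null is
binomial in raw counts.

Because ``s_i`` is a standard deviation estimated from ``k = floor(N/5)``
windows, its mean under the static null is ``sigma*sqrt((k-1)/k)`` to
first order — slightly below the line for small bursts.  The binned means
are therefore reported together with a Monte-Carlo null band
(:func:`bva_null_band`) matched per burst in window count and acceptor
fraction; per-bin agreement should be judged against that band, not the
bare curve.

Lifetimes
---------
The apparent donor lifetime of a burst, tau_D(A), is the mean microtime of
its Dex-slot donor-channel photons minus the IRF mean delay.  The
donor-only lifetime tau_D(0) pools the same estimator over bursts with
S above a threshold (default 0.9).  In the E-vs-tau plane static molecules
fall on ``E = 1 - tau/tau_D0`` while molecules exchanging between two
states (lifetimes tau_1, tau_2) trace the dynamic line
``E(tau_bar) = 1 - tau_1*tau_2 / (tau_D0*(tau_1 + tau_2 - tau_bar))``,
which passes through both state points and lies above the static line
between them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .photons import DONOR, PhotonStream, SLOT_DEX

__all__ = [
    "bva_burst", "bva", "bva_static_expectation", "bva_bin", "bva_null_band",
    "burst_lifetime", "burst_lifetimes", "donor_only_lifetime",
    "static_fret_line", "dynamic_fret_line", "fret_lines",
]


# ---------------------------------------------------------------------------
# BVA
# ---------------------------------------------------------------------------

def bva_burst(acceptor: np.ndarray, window_n: int = 5) -> float:
    """``s_i`` of one burst from its time-ordered Dex-photon acceptor flags.

    Requires at least two full windows; raises ``ValueError`` otherwise.
    """
    acceptor = np.asarray(acceptor)
    k = acceptor.size // window_n
    if k < 2:
        raise ValueError(
            f"need >= {2 * window_n} Dex photons for BVA, got {acceptor.size}")
    frac = acceptor[:k * window_n].reshape(k, window_n).mean(axis=1)
    return float(np.std(frac))  # population standard deviation


def bva(stream: PhotonStream, bursts: pd.DataFrame,
        window_n: int = 5) -> pd.DataFrame:
    """Per-burst BVA table: raw proximity ratio ``e_raw``, ``s_i`` and the
    number of full windows.  Bursts with fewer than two windows are
    excluded (reason recorded)."""
    times = stream.times
    slots = stream.slots
    dets = stream.detectors
    lo = np.searchsorted(times, bursts["t_start"].to_numpy(), side="left")
    hi = np.searchsorted(times, bursts["t_stop"].to_numpy(), side="right")
    rows = []
    for k in range(len(bursts)):
        sl = slice(lo[k], hi[k])
        dex = slots[sl] == SLOT_DEX
        acc = (dets[sl][dex] != DONOR)
        n_win = acc.size // window_n
        if n_win < 2:
            rows.append((np.nan, np.nan, n_win, "too_few_windows"))
            continue
        e_raw = float(acc.mean())
        rows.append((e_raw, bva_burst(acc, window_n), n_win, ""))
    out = pd.DataFrame(rows, columns=["e_raw", "s_i", "n_windows", "reason"])
    out.index = bursts.index
    return out


def bva_static_expectation(e, window_n: int = 5):
    """Static (shot-noise) line: ``sqrt(E*(1-E)/window_n)``."""
    e = np.asarray(e, dtype=float)
    return np.sqrt(np.clip(e * (1.0 - e), 0.0, None) / window_n)


def _bin_index(e_raw: np.ndarray, bin_width: float) -> np.ndarray:
    # the 1e-9 guard keeps exact bin-edge values (0.15/0.05 = 2.999...)
    # in their half-open upper bin
    return np.clip(np.floor(e_raw / bin_width + 1e-9).astype(int), 0,
                   int(np.ceil(1.0 / bin_width)) - 1)


def bva_bin(per_burst: pd.DataFrame, bin_width: float = 0.05,
            window_n: int = 5) -> pd.DataFrame:
    """Mean ``s_i`` per half-open E_raw bin of width ``bin_width``.

    Empty bins are emitted with count 0; each row carries the bin centre,
    the static expectation at the centre and the empirical SE of the mean.
    """
    n_bins = int(np.ceil(1.0 / bin_width))
    ok = per_burst["s_i"].notna().to_numpy()
    e = per_burst["e_raw"].to_numpy()[ok]
    s = per_burst["s_i"].to_numpy()[ok]
    idx = _bin_index(e, bin_width)
    rows = []
    for b in range(n_bins):
        centre = (b + 0.5) * bin_width
        sel = s[idx == b]
        mean = float(sel.mean()) if sel.size else np.nan
        se = float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else np.nan
        rows.append((centre, mean, sel.size,
                     float(bva_static_expectation(centre, window_n)), se))
    return pd.DataFrame(rows, columns=[
        "bin_centre", "mean_s_i", "n_bursts", "static_sigma", "se_mean"])


def bva_null_band(per_burst: pd.DataFrame, bin_width: float = 0.05,
                  window_n: int = 5, n_rep: int = 300,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Binomial Monte-Carlo null for the binned mean ``s_i``.

    For every burst, ``n_rep`` replicates draw its ``n_windows`` window
    acceptor counts from Binomial(window_n, e_raw) and recompute ``s_i``;
    the per-bin mean over bursts then yields the null mean and SD of the
    binned statistic, matched to the data in burst sizes and bin
    occupancy.  This is the shot-noise band against which excess variance
    is judged.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    ok = per_burst["s_i"].notna().to_numpy()
    e = per_burst["e_raw"].to_numpy()[ok]
    k = per_burst["n_windows"].to_numpy()[ok].astype(int)
    idx = _bin_index(e, bin_width)
    n_bins = int(np.ceil(1.0 / bin_width))
    mu = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    for b in np.unique(idx):
        sel = np.nonzero(idx == b)[0]
        if sel.size == 0:
            continue
        # one big draw: (n_rep, total windows of the bin)
        k_b = k[sel]
        p = np.repeat(e[sel], k_b)
        draws = rng.binomial(window_n, p, size=(n_rep, p.size)) / window_n
        edges = np.concatenate(([0], np.cumsum(k_b)))
        s_rep = np.empty((n_rep, sel.size))
        for j in range(sel.size):
            s_rep[:, j] = draws[:, edges[j]:edges[j + 1]].std(axis=1)
        bin_means = s_rep.mean(axis=1)
        mu[b] = bin_means.mean()
        sd[b] = bin_means.std(ddof=1)
    centres = (np.arange(n_bins) + 0.5) * bin_width
    return pd.DataFrame({"bin_centre": centres, "null_mean": mu, "null_sd": sd})


# ---------------------------------------------------------------------------
# Lifetimes
# ---------------------------------------------------------------------------

def burst_lifetime(nanotimes_ns: np.ndarray, irf_mean_ns: float,
                   min_photons: int = 10) -> float:
    """Mean Dex/D microtime minus the IRF mean, in ns.

    Negative estimates are returned as-is (flag downstream, never clip).
    """
    nt = np.asarray(nanotimes_ns, dtype=float)
    if nt.size < min_photons:
        raise ValueError(
            f"need >= {min_photons} donor photons for a lifetime, got {nt.size}")
    return float(nt.mean() - irf_mean_ns)


def burst_lifetimes(stream: PhotonStream, bursts: pd.DataFrame,
                    irf_mean_ns: float, min_photons: int = 10) -> pd.DataFrame:
    """Per-burst tau_D(A) table (NaN + reason where too few donor photons)."""
    times = stream.times
    dexd = stream.mask_dex_d
    nano_ns = stream.nanotime_ns()
    lo = np.searchsorted(times, bursts["t_start"].to_numpy(), side="left")
    hi = np.searchsorted(times, bursts["t_stop"].to_numpy(), side="right")
    rows = []
    for k in range(len(bursts)):
        sl = slice(lo[k], hi[k])
        nt = nano_ns[sl][dexd[sl]]
        if nt.size < min_photons:
            rows.append((np.nan, nt.size, "too_few_photons"))
        else:
            tau = burst_lifetime(nt, irf_mean_ns, min_photons)
            rows.append((tau, nt.size, "negative" if tau < 0 else ""))
    out = pd.DataFrame(rows, columns=["tau_da_ns", "n_photons", "reason"])
    out.index = bursts.index
    return out


def donor_only_lifetime(stream: PhotonStream, bursts: pd.DataFrame,
                        s_values: np.ndarray, irf_mean_ns: float,
                        s_threshold: float = 0.9,
                        min_bursts: int = 10) -> float:
    """tau_D(0): pooled mean Dex/D microtime of bursts with S > threshold."""
    sel = np.asarray(s_values) > s_threshold
    if sel.sum() < min_bursts:
        raise ValueError(
            f"only {int(sel.sum())} bursts with S > {s_threshold} "
            f"(need >= {min_bursts})")
    chosen = bursts.loc[sel]
    times = stream.times
    dexd = stream.mask_dex_d
    nano_ns = stream.nanotime_ns()
    lo = np.searchsorted(times, chosen["t_start"].to_numpy(), side="left")
    hi = np.searchsorted(times, chosen["t_stop"].to_numpy(), side="right")
    pooled = [nano_ns[l:h][dexd[l:h]] for l, h in zip(lo, hi)]
    nt = np.concatenate(pooled) if pooled else np.empty(0)
    if nt.size == 0:
        raise ValueError("no Dex/D photons in donor-only bursts")
    return float(nt.mean() - irf_mean_ns)


# ---------------------------------------------------------------------------
# FRET lines
# ---------------------------------------------------------------------------

def static_fret_line(tau_ns, tau_d0_ns: float):
    """Static line ``E = 1 - tau/tau_D0``."""
    if tau_d0_ns <= 0:
        raise ValueError("tau_D0 must be positive")
    return 1.0 - np.asarray(tau_ns, dtype=float) / tau_d0_ns

def dynamic_fret_line(tau_bar_ns, tau1_ns: float, tau2_ns: float,
                      tau_d0_ns: float):
    """Two-state dynamic line
    ``E = 1 - tau1*tau2/(tau_D0*(tau1+tau2-tau_bar))``; passes exactly
    through both state points.  Degenerate tau1 == tau2 collapses to the
    single state point (raises ``ValueError``)."""
    if not (0 < tau1_ns < tau_d0_ns and 0 < tau2_ns < tau_d0_ns):
        raise ValueError("state lifetimes must lie in (0, tau_D0)")
    if tau1_ns == tau2_ns:
        raise ValueError("degenerate states: tau1 == tau2 (static point)")
    tau_bar = np.asarray(tau_bar_ns, dtype=float)
    return 1.0 - (tau1_ns * tau2_ns) / (tau_d0_ns * (tau1_ns + tau2_ns - tau_bar))


def fret_lines(tau_d0_ns: float, states: tuple[float, float],
               n_points: int = 200) -> pd.DataFrame:
    """Sampled static and dynamic lines for plotting/serialisation.

    The static line is sampled on tau in [0, tau_D0]; the dynamic line on
    tau_bar between the two state lifetimes.
    """
    tau1, tau2 = states
    tau_static = np.linspace(0.0, tau_d0_ns, n_points)
    lo, hi = min(tau1, tau2), max(tau1, tau2)
    tau_dyn = np.linspace(lo, hi, n_points)
    return pd.DataFrame({
        "tau_static_ns": tau_static,
        "e_static": static_fret_line(tau_static, tau_d0_ns),
        "tau_dynamic_ns": tau_dyn,
        "e_dynamic": dynamic_fret_line(tau_dyn, tau1, tau2, tau_d0_ns),
    })
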
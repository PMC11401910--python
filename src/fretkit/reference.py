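"""Brute-force reference implementations for validation.

These re-implement the burst search, the ALEX-2CDE kernel sums and the BVA
window scan as plain python loops, straight from their definitions and
sharing no code with the vectorised production paths.  They are quadratic
or worse and exist so that the fast implementations can be checked for
exact agreement on small inputs.
"""

from __future__ import annotations

import math

import numpy as np

from .bursts import BackgroundEstimate
from .photons import PhotonStream

__all__ = ["brute_force_bursts", "alex_2cde_brute", "bva_windows_brute"]


def brute_force_bursts(stream: PhotonStream, bg: BackgroundEstimate,
                       threshold_factor: float = 3.0, min_size: int = 50,
                       window_m: int = 10, mode: str = "and"):
    """Burst boundaries as (first, last) positions within the Dex photon
    subsequence, by direct enumeration of every sliding window."""
    slots = stream.pie.slot(stream.nanotimes)
    times = stream.times
    t = [times[i] for i in range(len(stream)) if slots[i] == 0]
    a = [int(stream.detectors[i] != 0) for i in range(len(stream))
         if slots[i] == 0]
    n = len(t)
    m = window_m
    if n < m:
        return []
    hot = [False] * (n - m + 1)
    for i in range(n - m + 1):
        span = t[i + m - 1] - t[i]
        n_a = sum(a[i:i + m])
        n_d = m - n_a
        seg = int(bg.segment_of([t[i]])[0])
        if span <= 0:
            hot[i] = True
            continue
        if mode == "and":
            hot[i] = (n_d / span > threshold_factor * bg.rates["dex_d"][seg]
                      and n_a / span > threshold_factor * bg.rates["dex_a"][seg])
        else:
            total_bg = bg.rates["dex_d"][seg] + bg.rates["dex_a"][seg]
            hot[i] = m / span > threshold_factor * total_bg
    # runs of hot start photons -> candidates [start, stop + m - 1]
    cand = []
    i = 0
    while i <= n - m:
        if hot[i]:
            j = i
            while j + 1 <= n - m and hot[j + 1]:
                j += 1
            lo, hi = i, j + m - 1
            if cand and lo <= cand[-1][1]:
                cand[-1] = (cand[-1][0], max(cand[-1][1], hi))
            else:
                cand.append((lo, hi))
            i = j + 1
        else:
            i += 1
    return [(lo, hi) for lo, hi in cand if hi - lo + 1 >= min_size]


def alex_2cde_brute(t_dex, t_aex, tau: float) -> float:
    """ALEX-2CDE of one burst by direct double summation."""
    if len(t_dex) == 0 or len(t_aex) == 0:
        return 100.0

    def kde(t0, ts):
        return sum(math.exp(-abs(t0 - tj) / tau) for tj in ts)

    br_da = sum(kde(tj, t_dex) / kde(tj, t_aex) for tj in t_aex) / len(t_dex)
    br_ad = sum(kde(ti, t_aex) / kde(ti, t_dex) for ti in t_dex) / len(t_aex)
    return 100.0 - 50.0 * (br_da + br_ad)


def bva_windows_brute(acceptor, window_n: int = 5) -> float:
    """Population SD of consecutive-window acceptor fractions, by loop."""
    fracs = []
    i = 0
    while i + window_n <= len(acceptor):
        fracs.append(sum(acceptor[i:i + window_n]) / window_n)
        i += window_n
    if len(fracs) < 2:
        raise ValueError("need at least two full windows")
    mean = sum(fracs) / len(fracs)
    return math.sqrt(sum((f - mean) ** 2 for f in fracs) / len(fracs))
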
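"""Background estimation and dual-channel sliding-window burst search.

Background is re-estimated independently for every 60 s segment of the
acquisition (last segment may be shorter) and separately for the three
analysed photon streams (Dex/D, Dex/A, Aex/A).  Within a segment the rate
is the maximum-likelihood exponential fit to the inter-photon delays that
exceed an automatically chosen threshold, which excludes burst photons:
starting from twice the mean delay, the tail rate and the threshold
(2 / rate) are re-fit until the threshold is stable to 1%.  Segments with
fewer than 50 photons fall back to the plain mean rate.

Burst search follows the dual-channel reading of "3x the background signal
in the donor and acceptor channels": over the combined Dex-slot photon
sequence, the window of ``window_m`` consecutive photons *starting* at
photon ``i`` is *hot* when the local donor-photon rate exceeds
``threshold_factor`` times the segment's Dex/D background rate AND the
local acceptor-photon rate exceeds ``threshold_factor`` times the Dex/A
background rate.  A maximal run of consecutive hot start photons
``[a, b]`` yields the candidate burst ``[a, b + window_m - 1]`` (the
photons of the last hot window belong to the burst); overlapping
candidates are merged, and candidates with fewer than ``min_size`` Dex
photons are discarded.  Anchoring hotness at the window *start* splits
bursts at photon-free gaps: the windows beginning near the end of a
transit span the gap to the next one and are cold.  ``mode="any"``
instead thresholds the total Dex rate against the summed background
(single-stream search).  Non-overlapping candidates are never merged,
however close.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photons import PhotonStream

__all__ = ["BackgroundEstimate", "estimate_background", "search_bursts",
           "BURST_COLUMNS"]

STREAM_KEYS = ("dex_d", "dex_a", "aex_a")

BURST_COLUMNS = ["i_start", "i_stop", "t_start", "t_stop", "duration",
                 "n_dd", "n_da", "n_aa", "segment"]


@dataclass
class BackgroundEstimate:
    """Per-segment, per-stream background rates (counts/s)."""

    segment_edges: np.ndarray          # (n_seg + 1,) seconds
    rates: dict                        # key -> (n_seg,) counts/s
    counts: dict                       # key -> (n_seg,) photons used in fit

    @property
    def n_segments(self) -> int:
        return len(self.segment_edges) - 1

    def segment_of(self, times) -> np.ndarray:
        """Segment index for each time (clipped to valid segments)."""
        idx = np.searchsorted(self.segment_edges, np.asarray(times), side="right") - 1
        return np.clip(idx, 0, self.n_segments - 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg in range(self.n_segments):
            for key in self.rates:
                rows.append({
                    "segment": seg,
                    "t_start": self.segment_edges[seg],
                    "t_stop": self.segment_edges[seg + 1],
                    "stream": key,
                    "rate": self.rates[key][seg],
                    "n_photons": self.counts[key][seg],
                })
        return pd.DataFrame(rows)


def _tail_mle_rate(times: np.ndarray, span: float,
                   min_photons: int = 50, rel_tol: float = 0.01,
                   max_iter: int = 100) -> float:
    """Background rate from the exponential tail of inter-photon delays.

    Iterates threshold <- 2/rate, rate <- 1/mean(delay - threshold | delay >
    threshold) (exponential memorylessness) until stable.  Falls back to the
    mean rate when the segment is too sparse for a tail fit.
    """
    n = times.size
    if n == 0 or span <= 0:
        return 0.0
    if n < min_photons:
        return n / span
    delays = np.diff(times)
    if delays.size == 0 or delays.max() == 0:
        return n / span
    thr = 2.0 * delays.mean()
    rate = n / span
    for _ in range(max_iter):
        tail = delays[delays > thr]
        if tail.size < 10:
            return n / span
        rate = 1.0 / float(np.mean(tail - thr))
        new_thr = 2.0 / rate
        if abs(new_thr - thr) <= rel_tol * thr:
            break
        thr = new_thr
    return rate


def estimate_background(stream: PhotonStream,
                        segment_s: float = 60.0) -> BackgroundEstimate:
    """Per-60-s-segment background rates for the Dex/D, Dex/A, Aex/A streams."""
    if segment_s <= 0:
        raise ValueError("segment_s must be positive")
    if len(stream) == 0:
        raise ValueError("empty photon stream")
    duration = max(stream.duration, float(stream.times[-1]))
    n_seg = max(int(np.ceil(duration / segment_s)), 1)
    edges = np.minimum(np.arange(n_seg + 1) * segment_s, duration)
    edges[-1] = duration

    masks = {"dex_d": stream.mask_dex_d, "dex_a": stream.mask_dex_a,
             "aex_a": stream.mask_aex_a}
    times = stream.times
    rates = {}
    counts = {}
    for key, mask in masks.items():
        t = times[mask]
        r = np.zeros(n_seg)
        c = np.zeros(n_seg, dtype=np.int64)
        for seg in range(n_seg):
            lo, hi = edges[seg], edges[seg + 1]
            sel = t[(t >= lo) & (t < hi)] if seg < n_seg - 1 else t[(t >= lo) & (t <= hi)]
            c[seg] = sel.size
            r[seg] = _tail_mle_rate(sel, hi - lo)
        rates[key] = r
        counts[key] = c
    return BackgroundEstimate(segment_edges=edges, rates=rates, counts=counts)


def search_bursts(stream: PhotonStream, bg: BackgroundEstimate,
                  threshold_factor: float = 3.0, min_size: int = 50,
                  window_m: int = 10, mode: str = "and") -> pd.DataFrame:
    """Locate single-molecule bursts (one row per accepted burst).

    Returns a DataFrame with columns ``i_start``/``i_stop`` (indices of the
    burst's first/last Dex photon in the full stream), start/stop times and
    duration in seconds, the Dex-slot channel counts ``n_dd``/``n_da``, the
    Aex/A count over the burst's time span ``n_aa``, and the background
    segment index.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    if min_size < window_m:
        raise ValueError("min_size must be >= window_m")
    if mode not in ("and", "any"):
        raise ValueError("mode must be 'and' or 'any'")

    dex_mask = stream.mask_dex
    dex_idx = np.nonzero(dex_mask)[0]
    empty = pd.DataFrame(columns=BURST_COLUMNS).astype(
        {c: float for c in BURST_COLUMNS} | {k: np.int64 for k in
         ("i_start", "i_stop", "n_dd", "n_da", "n_aa", "segment")})
    n = dex_idx.size
    if n < window_m:
        return empty

    times = stream.times
    t = times[dex_idx]
    is_a = (stream.detectors[dex_idx] != 0)
    m = window_m

    # window start photons 0 .. n-m; counts via cumulative sums
    ca = np.concatenate(([0], np.cumsum(is_a.astype(np.int64))))
    starts = np.arange(n - m + 1)
    span = t[starts + m - 1] - t[starts]
    n_a = ca[starts + m] - ca[starts]
    n_d = m - n_a
    seg = bg.segment_of(t[starts])
    bg_d = bg.rates["dex_d"][seg]
    bg_a = bg.rates["dex_a"][seg]
    with np.errstate(divide="ignore", invalid="ignore"):
        rate_d = np.where(span > 0, n_d / span, np.inf)
        rate_a = np.where(span > 0, n_a / span, np.inf)
        rate_tot = np.where(span > 0, m / span, np.inf)
    if mode == "and":
        hot_win = (rate_d > threshold_factor * bg_d) & \
                  (rate_a > threshold_factor * bg_a)
    else:
        hot_win = rate_tot > threshold_factor * (bg_d + bg_a)

    if not hot_win.any():
        return empty

    # maximal runs of consecutive hot window-start photons
    d = np.diff(hot_win.astype(np.int8))
    run_start = np.nonzero(d == 1)[0] + 1
    run_stop = np.nonzero(d == -1)[0]
    if hot_win[0]:
        run_start = np.concatenate(([0], run_start))
    if hot_win[-1]:
        run_stop = np.concatenate((run_stop, [hot_win.size - 1]))
    # each run [a, b] covers photons [a, b + m - 1]; merge overlaps
    cand = []
    for a, b in zip(run_start, run_stop + m - 1):
        if cand and a <= cand[-1][1]:
            cand[-1][1] = max(cand[-1][1], b)
        else:
            cand.append([a, b])

    aex_times = times[stream.mask_aex_a]
    rows = []
    cum_a = ca
    for lo, hi in cand:
        n_tot = hi - lo + 1
        if n_tot < min_size:
            continue
        n_da = int(cum_a[hi + 1] - cum_a[lo])
        n_dd = int(n_tot - n_da)
        t0, t1 = float(t[lo]), float(t[hi])
        n_aa = int(np.searchsorted(aex_times, t1, side="right")
                   - np.searchsorted(aex_times, t0, side="left"))
        rows.append((int(dex_idx[lo]), int(dex_idx[hi]), t0, t1, t1 - t0,
                     n_dd, n_da, n_aa, int(bg.segment_of(t0))))
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=BURST_COLUMNS)
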
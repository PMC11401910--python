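"""Core photon-stream container for PIE/ALEX single-molecule FRET data.

A measurement is a list of detected photons, each carrying

* a *macrotime* (``timestamps``): laboratory-clock arrival expressed in
  integer units of the excitation sync period,
* a *microtime* (``nanotimes``): TCSPC delay after the sync pulse in
  integer TCSPC bins,
* a *detector* (``detectors``): spectral channel, donor or acceptor.

Under pulsed interleaved excitation (PIE) the microtime also encodes which
laser excited the molecule: photons whose nanotime falls in the
donor-excitation window belong to the Dex slot, photons in the
acceptor-excitation window to the Aex slot.  The :class:`PIEScheme` holds
those windows; every downstream stage (burst search, E/S, BVA, lifetimes)
works on the slot/channel partition defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DONOR",
    "ACCEPTOR",
    "SLOT_DEX",
    "SLOT_AEX",
    "SLOT_NONE",
    "PIEScheme",
    "PhotonStream",
    "StreamError",
]

#: Detector codes for the two spectral channels.
DONOR: int = 0
ACCEPTOR: int = 1

#: Excitation-slot codes returned by :meth:`PIEScheme.slot`.
SLOT_DEX: int = 0
SLOT_AEX: int = 1
SLOT_NONE: int = -1


class StreamError(ValueError):
    """Raised when a photon stream violates its structural invariants."""


@dataclass(frozen=True)
class PIEScheme:
    """Excitation-slot assignment by TCSPC microtime.

    Parameters
    ----------
    dex_window, aex_window:
        Half-open ``[lo, hi)`` intervals in TCSPC bins assigning photons to
        the donor- and acceptor-excitation slots.  They must be disjoint and
        lie within ``[0, n_bins)``.
    n_bins:
        Number of TCSPC bins per alternation period.

    The defaults describe a 100 ns alternation period sampled in 2000 bins
    of 50 ps, split 50:50 between donor and acceptor excitation.
    """

    dex_window: tuple[int, int] = (0, 1000)
    aex_window: tuple[int, int] = (1000, 2000)
    n_bins: int = 2000

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("dex_window", self.dex_window),
                               ("aex_window", self.aex_window)):
            if not (0 <= lo < hi <= self.n_bins):
                raise StreamError(
                    f"{name}={lo, hi} is empty or outside [0, {self.n_bins})")
        d0, d1 = self.dex_window
        a0, a1 = self.aex_window
        if max(d0, a0) < min(d1, a1):
            raise StreamError("dex_window and aex_window overlap")

    def slot(self, nanotimes: np.ndarray) -> np.ndarray:
        """Map TCSPC bins to {SLOT_DEX, SLOT_AEX, SLOT_NONE}."""
        nt = np.asarray(nanotimes)
        out = np.full(nt.shape, SLOT_NONE, dtype=np.int8)
        d0, d1 = self.dex_window
        a0, a1 = self.aex_window
        out[(nt >= d0) & (nt < d1)] = SLOT_DEX
        out[(nt >= a0) & (nt < a1)] = SLOT_AEX
        return out


@dataclass
class PhotonStream:
    """Time-stamped, channel- and excitation-slot-labelled photon records.

    ``timestamps`` are non-decreasing integers in units of
    ``1 / clock_rate`` seconds; ``nanotimes`` are TCSPC bins of width
    ``tcspc_unit`` seconds; ``detectors`` holds :data:`DONOR` /
    :data:`ACCEPTOR` codes.  Photons whose nanotime falls outside both PIE
    windows are carried in the container but excluded from every analysis.
    """

    timestamps: np.ndarray
    nanotimes: np.ndarray
    detectors: np.ndarray
    clock_rate: float = 1e7          # Hz; one tick per 100 ns sync period
    tcspc_unit: float = 50e-12       # s per TCSPC bin
    pie: PIEScheme = field(default_factory=PIEScheme)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.nanotimes = np.asarray(self.nanotimes, dtype=np.int32)
        self.detectors = np.asarray(self.detectors, dtype=np.uint8)

    # -- validation ------------------------------------------------------
    def validate(self) -> "PhotonStream":
        n = len(self.timestamps)
        if len(self.nanotimes) != n or len(self.detectors) != n:
            raise StreamError(
                f"array lengths differ: timestamps={n}, "
                f"nanotimes={len(self.nanotimes)}, detectors={len(self.detectors)}")
        if n > 1:
            bad = np.nonzero(np.diff(self.timestamps) < 0)[0]
            if bad.size:
                raise StreamError(
                    f"timestamps not non-decreasing at index {int(bad[0]) + 1}")
        if n and self.nanotimes.size:
            if self.nanotimes.min() < 0 or self.nanotimes.max() >= self.pie.n_bins:
                raise StreamError("nanotimes outside [0, n_bins)")
        if self.clock_rate <= 0 or self.tcspc_unit <= 0:
            raise StreamError("clock_rate and tcspc_unit must be positive")
        return self

    # -- basic views -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def times(self) -> np.ndarray:
        """Macrotime in seconds."""
        return self.timestamps / self.clock_rate

    @property
    def duration(self) -> float:
        """Acquisition duration in seconds (metadata, else last photon)."""
        if "duration_s" in self.meta:
            return float(self.meta["duration_s"])
        return float(self.times[-1]) if len(self) else 0.0

    @property
    def slots(self) -> np.ndarray:
        return self.pie.slot(self.nanotimes)

    # Masks for the three streams every analysis consumes.
    @property
    def mask_dex_d(self) -> np.ndarray:
        return (self.slots == SLOT_DEX) & (self.detectors == DONOR)

    @property
    def mask_dex_a(self) -> np.ndarray:
        return (self.slots == SLOT_DEX) & (self.detectors == ACCEPTOR)

    @property
    def mask_dex(self) -> np.ndarray:
        return self.slots == SLOT_DEX

    @property
    def mask_aex_a(self) -> np.ndarray:
        return (self.slots == SLOT_AEX) & (self.detectors == ACCEPTOR)

    def select(self, mask: np.ndarray) -> "PhotonStream":
        """Sub-stream of the photons where ``mask`` is True."""
        return replace(
            self,
            timestamps=self.timestamps[mask],
            nanotimes=self.nanotimes[mask],
            detectors=self.detectors[mask],
            meta=dict(self.meta),
        )

    def nanotime_ns(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Microtimes in nanoseconds, measured from the start of the photon's
        own excitation window (so Dex and Aex photons are comparable)."""
        nt = self.nanotimes if mask is None else self.nanotimes[mask]
        slots = self.pie.slot(nt)
        origin = np.where(slots == SLOT_AEX, self.pie.aex_window[0],
                          self.pie.dex_window[0])
        # bin centres: a photon in bin b arrived in [b, b+1) bin widths
        return (nt - origin + 0.5) * (self.tcspc_unit * 1e9)
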
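"""Run configuration for the burst-analysis pipeline.

Defaults are the values used throughout: donor leakage 0.14, direct
excitation 0.14, gamma 1.0, beta 1.4; 60 s background segments; burst
search at 3x background with a 50-photon minimum; stoichiometry filter
[0.3, 0.7]; ALEX-2CDE cutoff 95; BVA with 5-photon windows and 0.05-wide
E_raw bins; donor-only selection at S > 0.9.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .metrics import CorrectionSet

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    corrections: CorrectionSet = field(default_factory=CorrectionSet)
    bg_segment_s: float = 60.0       # background re-estimated per segment
    threshold_factor: float = 3.0    # burst search: local rate > factor * bg
    min_size: int = 50               # minimum n_DD + n_DA per burst
    window_m: int = 10               # photons per sliding rate window
    search_mode: str = "and"         # "and": dual-channel Dex search; "any": single-stream
    s_min: float = 0.3
    s_max: float = 0.7
    cde_max: float = 95.0            # ALEX-2CDE cutoff (inclusive)
    kde_tau_s: float = 100e-6        # ALEX-2CDE kernel time constant
    bva_window: int = 5
    bva_bin_width: float = 0.05
    donor_only_s_min: float = 0.9    # S threshold selecting donor-only bursts
    lifetime_min_photons: int = 10   # Dex/D photons required for a burst lifetime
    irf_mean_ns: float = 2.0         # instrument-response mean delay

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "corrections" in d and isinstance(d["corrections"], dict):
            d["corrections"] = CorrectionSet(**d["corrections"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))
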
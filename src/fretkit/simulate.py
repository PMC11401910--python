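"""Ground-truth generators: PIE photon streams, NMR peak-table pairs and
Hill-shaped titrations.

Photon-stream model
-------------------
Freely diffusing, doubly labelled molecules at ~pM concentration transit the
confocal volume one at a time.  A transit is modelled as a rectangular-rate
emission window of exponentially distributed duration (mean ``transit_mean``)
rather than a full 3-D diffusion path: the burst-analysis stages consume only
count statistics, which this preserves at a fraction of the cost.  Within a
transit the molecule interconverts between two FRET states (efficiencies
``E1``/``E2``) as a continuous-time Markov chain with rates ``k12``/``k21``.

Detected count rates are built so that the consensus correction chain is
exactly invertible in expectation.  With donor-excitation photon budget
``R = peak_rate`` and corrections ``(lk, dir, gamma, beta)``:

* Dex/D channel:  ``R * (1 - E)``
* Dex/A channel:  ``gamma*R*E  +  lk*R*(1-E)  +  dir*rate_AA``
* Aex/A channel:  ``rate_AA = beta*gamma*R*(1-S_true)/S_true``

so that ``F_DA' = F_DA - lk*F_DD - dir*F_AA`` recovers the true FRET signal,
``E = F_DA'/(F_DA' + gamma*F_DD)`` recovers the state efficiency and
``S = (F_DA'+gamma*F_DD)/(F_DA'+gamma*F_DD+F_AA/beta)`` recovers ``S_true``.

Microtimes of Dex/D photons are ``irf_mean + Exp(tau_D0*(1-E_state))``;
acceptor-emission photons decay with ``tau_A``.  Background is homogeneous
Poisson per channel/slot with microtimes uniform over the slot window.
The instrument response is a pure mean delay (the downstream lifetime
estimator uses only the IRF mean); a Gaussian width is available via
``irf_sigma_ns``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import CorrectionSet
from .photons import ACCEPTOR, DONOR, PIEScheme, PhotonStream

__all__ = [
    "TwoStateModel",
    "NMRSyntheticSpec",
    "simulate_photon_stream",
    "simulate_nmr_pair",
    "simulate_binding_curve",
    "NMR_DOMAINS",
]


# ---------------------------------------------------------------------------
# Photon-stream model
# ---------------------------------------------------------------------------

@dataclass
class TwoStateModel:
    """Ground-truth parameters of the two-state photon-stream simulator.

    Rates are in s^-1, durations in seconds, lifetimes in ns.  ``bg_rates``
    maps the three analysed streams (``"dex_d"``, ``"dex_a"``, ``"aex_a"``)
    to background count rates in counts/s.
    """

    E1: float = 0.45
    E2: float = 0.45
    k12: float = 0.0
    k21: float = 0.0
    S_true: float = 0.5
    tau_D0: float = 4.0              # donor-only lifetime (ns)
    tau_A: float = 1.5               # acceptor-emission decay (ns)
    burst_rate: float = 20.0         # molecule transits per second
    transit_mean: float = 1e-3       # mean transit duration (s)
    peak_rate: float = 150e3         # donor-excitation photon budget (counts/s)
    bg_rates: dict = field(default_factory=lambda: {
        "dex_d": 1500.0, "dex_a": 800.0, "aex_a": 1200.0})
    corrections: CorrectionSet = field(default_factory=CorrectionSet)
    irf_mean: float = 2.0            # IRF mean delay (ns)
    irf_sigma_ns: float = 0.0        # optional Gaussian IRF width (ns)
    pie: PIEScheme = field(default_factory=PIEScheme)
    clock_rate: float = 1e7          # macrotime ticks/s (one tick per period)
    tcspc_unit: float = 50e-12       # s per TCSPC bin
    seed: int = 0

    def validate(self) -> "TwoStateModel":
        if not (0.0 <= self.E1 <= 1.0 and 0.0 <= self.E2 <= 1.0):
            raise ValueError("E1, E2 must lie in [0, 1]")
        if self.k12 < 0 or self.k21 < 0:
            raise ValueError("exchange rates must be >= 0")
        if not (0.0 < self.S_true < 1.0):
            raise ValueError("S_true must lie in (0, 1)")
        if min(self.tau_D0, self.tau_A) <= 0:
            raise ValueError("lifetimes must be positive")
        if min(self.transit_mean, self.peak_rate) <= 0 or self.burst_rate < 0:
            raise ValueError("transit_mean, peak_rate must be positive")
        if any(r < 0 for r in self.bg_rates.values()):
            raise ValueError("background rates must be >= 0")
        return self

    @property
    def occupancy1(self) -> float:
        """Stationary probability of state 1 (k21/(k12+k21); 1 if static)."""
        ktot = self.k12 + self.k21
        return self.k21 / ktot if ktot > 0 else 1.0


def _markov_segments(rng, n_transits, durations, k12, k21, p1):
    """Piecewise-constant state trajectories for all transits at once.

    Returns arrays (transit_id, seg_offset, seg_dur, seg_state) where
    seg_offset is the segment start relative to its transit.
    """
    state = (rng.random(n_transits) >= p1).astype(np.int8)  # 0 = state 1
    if k12 == 0.0 and k21 == 0.0:
        return (np.arange(n_transits), np.zeros(n_transits),
                durations.copy(), state)
    k_out = np.array([k12, k21])  # escape rate from state 0 (=1) / 1 (=2)
    tid = np.arange(n_transits)
    remaining = durations.copy()
    offset = np.zeros(n_transits)
    out_tid, out_off, out_dur, out_state = [], [], [], []
    while tid.size:
        rates = k_out[state]
        with np.errstate(divide="ignore"):
            dwell = np.where(rates > 0,
                             rng.exponential(1.0, tid.size) / np.maximum(rates, 1e-300),
                             np.inf)
        seg = np.minimum(dwell, remaining)
        out_tid.append(tid.copy())
        out_off.append(offset.copy())
        out_dur.append(seg)
        out_state.append(state.copy())
        cont = dwell < remaining
        tid, offset, remaining = tid[cont], offset[cont] + seg[cont], remaining[cont] - seg[cont]
        state = 1 - state[cont]
    return (np.concatenate(out_tid), np.concatenate(out_off),
            np.concatenate(out_dur), np.concatenate(out_state))


def simulate_photon_stream(model: TwoStateModel, duration: float, *,
                           rng: np.random.Generator | None = None,
                           return_truth: bool = False):
    """Simulate a PIE/ALEX photon stream of ``duration`` seconds.

    Returns a :class:`~fretkit.photons.PhotonStream` sorted by macrotime
    (ties broken by microtime).  With ``return_truth=True`` also returns a
    dict of ground-truth quantities (transit times, state occupancy, the
    model parameters) for sidecar serialisation and testing.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    model.validate()
    rng = np.random.default_rng(model.seed) if rng is None else rng
    pie = model.pie
    bin_ns = model.tcspc_unit * 1e9
    c = model.corrections

    # --- transit windows: sequential, non-overlapping ------------------
    if model.burst_rate > 0:
        n_guess = int(duration * model.burst_rate * 1.5) + 64
        gaps = rng.exponential(1.0 / model.burst_rate, n_guess)
        durs = rng.exponential(model.transit_mean, n_guess)
        starts = np.cumsum(gaps) + np.concatenate(([0.0], np.cumsum(durs[:-1])))
        keep = starts < duration
        starts, durs = starts[keep], durs[keep]
        durs = np.minimum(durs, duration - starts)
    else:
        starts = durs = np.empty(0)
    n_transits = starts.size

    # --- state trajectory ----------------------------------------------
    tid, off, seg_dur, seg_state = _markov_segments(
        rng, n_transits, durs, model.k12, model.k21, model.occupancy1)
    seg_start = starts[tid] + off if n_transits else np.empty(0)
    E_seg = np.where(seg_state == 0, model.E1, model.E2)

    # --- per-stream emission rates (see module docstring) ---------------
    R = model.peak_rate
    rate_aa = c.beta * c.gamma * R * (1.0 - model.S_true) / model.S_true
    rate_dd = R * (1.0 - E_seg)
    rate_da = c.gamma * R * E_seg + c.lk * R * (1.0 - E_seg) + c.dir * rate_aa

    times, dets, nanos = [], [], []

    def _emit(rates, seg_sel, window, det, decay_tau_ns):
        """Draw Poisson photons for one stream; decay_tau_ns is per-photon."""
        counts = rng.poisson(rates * seg_dur[seg_sel]) if np.ndim(rates) \
            else rng.poisson(rates * seg_dur[seg_sel])
        rep = np.repeat(np.arange(counts.size), counts)
        n = rep.size
        if n == 0:
            return
        t = seg_start[seg_sel][rep] + rng.random(n) * seg_dur[seg_sel][rep]
        tau = decay_tau_ns[rep] if np.ndim(decay_tau_ns) else np.full(n, decay_tau_ns)
        delay = model.irf_mean + np.where(tau > 0, rng.exponential(1.0, n) * tau, 0.0)
        if model.irf_sigma_ns > 0:
            delay = np.maximum(delay + rng.normal(0, model.irf_sigma_ns, n), 0.0)
        lo, hi = window
        bins = lo + np.minimum((delay / bin_ns).astype(np.int64), hi - lo - 1)
        times.append(t)
        dets.append(np.full(n, det, dtype=np.uint8))
        nanos.append(bins)

    if n_transits:
        all_seg = slice(None)
        tau_dd = model.tau_D0 * (1.0 - E_seg)
        _emit(rate_dd, all_seg, pie.dex_window, DONOR, tau_dd)
        _emit(rate_da, all_seg, pie.dex_window, ACCEPTOR, model.tau_A)
        _emit(np.full(seg_dur.size, rate_aa), all_seg, pie.aex_window,
              ACCEPTOR, model.tau_A)

    # --- background: homogeneous Poisson per channel/slot ----------------
    bg_streams = {
        "dex_d": (pie.dex_window, DONOR),
        "dex_a": (pie.dex_window, ACCEPTOR),
        "aex_a": (pie.aex_window, ACCEPTOR),
    }
    for key, (window, det) in bg_streams.items():
        rate = model.bg_rates.get(key, 0.0)
        n = rng.poisson(rate * duration)
        if n == 0:
            continue
        times.append(rng.random(n) * duration)
        dets.append(np.full(n, det, dtype=np.uint8))
        nanos.append(rng.integers(window[0], window[1], n))

    if times:
        t = np.concatenate(times)
        det = np.concatenate(dets)
        nano = np.concatenate(nanos).astype(np.int32)
    else:
        t = np.empty(0)
        det = np.empty(0, dtype=np.uint8)
        nano = np.empty(0, dtype=np.int32)

    ts = np.floor(t * model.clock_rate).astype(np.int64)
    order = np.lexsort((nano, ts))
    stream = PhotonStream(
        timestamps=ts[order], nanotimes=nano[order], detectors=det[order],
        clock_rate=model.clock_rate, tcspc_unit=model.tcspc_unit, pie=pie,
        meta={"duration_s": float(duration), "comment": "fretkit synthetic"},
    ).validate()

    if not return_truth:
        return stream
    occ1 = (float(seg_dur[seg_state == 0].sum() / seg_dur.sum())
            if n_transits and seg_dur.sum() > 0 else float("nan"))
    truth = {
        "n_transits": int(n_transits),
        "transit_start_s": starts,
        "transit_duration_s": durs,
        "state1_time_fraction": occ1,
        "model": dataclasses.asdict(model),
    }
    return stream, truth


# ---------------------------------------------------------------------------
# NMR peak-table pairs
# ---------------------------------------------------------------------------

NMR_DOMAINS = ("core-N", "P1", "P2", "core-C")


@dataclass
class NMRSyntheticSpec:
    """Planted-perturbation spec for an apo/bound methyl peak-table pair.

    ``hotspot_residues`` lose intensity in the bound state by the factor
    ``attenuation``; ``conf_residues`` get chemical-shift changes
    ``(dH, dC)`` ppm (a conformational-change signature).  Additive Gaussian
    noise at the ``noise_floor`` scale corrupts both tables, emulating the
    spectrum noise floor.
    """

    n_residues: int = 40
    hotspot_residues: frozenset = frozenset()
    attenuation: float = 0.4
    conf_residues: frozenset = frozenset()
    dH: float = 0.02
    dC: float = 0.1
    noise_floor: float = 0.05
    base_intensity: float = 1.0
    seed: int = 0

    def validate(self) -> "NMRSyntheticSpec":
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if not (0.0 < self.attenuation < 1.0):
            raise ValueError("attenuation must lie in (0, 1)")
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be positive")
        residues = set(range(1, self.n_residues + 1))
        for name, ids in (("hotspot_residues", self.hotspot_residues),
                          ("conf_residues", self.conf_residues)):
            if not set(ids) <= residues:
                raise ValueError(f"{name} outside residue range 1..{self.n_residues}")
        return self


def simulate_nmr_pair(spec: NMRSyntheticSpec,
                      *, rng: np.random.Generator | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (apo, bound) peak tables with planted perturbations.

    Columns follow the on-disk peak-table layout: residue, residue_type,
    wH_ppm, wC_ppm, intensity, noise_floor, domain, flags.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_residues
    residues = np.arange(1, n + 1)
    rtype = np.where(rng.random(n) < 0.67, "Ile", "Met")  # ~29 Ile / 14 Met
    domain = np.array(NMR_DOMAINS)[
        np.minimum((4 * (residues - 1)) // n, 3)]
    wH = rng.uniform(0.2, 1.4, n).round(3)
    wC = rng.uniform(10.0, 25.0, n).round(3)
    apo_int = spec.base_intensity * rng.lognormal(0.0, 0.25, n)

    is_hot = np.isin(residues, list(spec.hotspot_residues))
    is_conf = np.isin(residues, list(spec.conf_residues))
    bound_int = apo_int * np.where(is_hot, spec.attenuation, 1.0)

    apo_noisy = np.maximum(apo_int + rng.normal(0, spec.noise_floor, n), 0.0)
    bound_noisy = np.maximum(bound_int + rng.normal(0, spec.noise_floor, n), 0.0)

    def _table(intensity, wH_t, wC_t, flags):
        return pd.DataFrame({
            "residue": residues,
            "residue_type": rtype,
            "wH_ppm": wH_t,
            "wC_ppm": wC_t,
            "intensity": intensity,
            "noise_floor": spec.noise_floor,
            "domain": domain,
            "flags": flags,
        })

    apo = _table(apo_noisy, wH, wC, [""] * n)
    bound_flags = np.where(bound_noisy < spec.noise_floor,
                           "broadened_below_noise", "")
    bound = _table(bound_noisy,
                   np.where(is_conf, wH + spec.dH, wH),
                   np.where(is_conf, wC + spec.dC, wC),
                   bound_flags)
    return apo, bound


# ---------------------------------------------------------------------------
# Hill-shaped titrations
# ---------------------------------------------------------------------------

def simulate_binding_curve(S_U: float, S_B: float, Kd_app: float, n: float,
                           concentrations, noise_cv: float = 0.0,
                           seed: int | None = None,
                           *, rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Titration table from the Hill isotherm with multiplicative noise.

    ``signal = [S_U + (S_B-S_U)/(1+(Kd_app/L)^n)] * (1 + noise_cv*N(0,1))``.
    Returns a DataFrame with columns ``concentration_uM`` and ``signal``.
    """
    from .hill import hill_model  # local import to avoid a cycle

    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("concentrations must be non-empty")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if Kd_app <= 0 or n <= 0:
        raise ValueError("Kd_app and n must be positive")
    rng = np.random.default_rng(seed) if rng is None else rng
    signal = hill_model(conc, S_U, S_B, Kd_app, n)
    if noise_cv > 0:
        signal = signal * (1.0 + noise_cv * rng.normal(0.0, 1.0, conc.size))
    return pd.DataFrame({"concentration_uM": conc, "signal": signal})
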
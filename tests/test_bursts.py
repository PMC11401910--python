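"""Background estimation and burst search against first principles."""

import numpy as np
import pytest

import fretkit
from fretkit import PhotonStream
from fretkit.reference import brute_force_bursts
from fretkit.studies import nominal_background


def _stream_from(times, det, nano=None, duration=None):
    times = np.asarray(times, dtype=float)
    det = np.asarray(det, dtype=np.uint8)
    if nano is None:
        nano = np.where(det == 0, 100, 150).astype(np.int32)  # all Dex slot
    ts = np.floor(times * 1e7).astype(np.int64)
    order = np.lexsort((nano, ts))
    return PhotonStream(ts[order], np.asarray(nano, np.int32)[order],
                        det[order],
                        meta={"duration_s": duration or float(times.max())}
                        ).validate()


def test_background_rate_recovered_for_pure_poisson(rng):
    rate = 1000.0
    t = np.sort(rng.uniform(0, 60.0, rng.poisson(rate * 60)))
    det = (rng.random(t.size) < 0.5).astype(np.uint8)
    stream = _stream_from(t, det, duration=60.0)
    bg = fretkit.estimate_background(stream, 60.0)
    total = bg.rates["dex_d"][0] + bg.rates["dex_a"][0]
    assert total == pytest.approx(rate, abs=3 * rate / np.sqrt(t.size * 0.1))


def test_empty_segment_reports_zero_rate():
    t = np.sort(np.random.default_rng(1).uniform(0, 55.0, 2000))
    stream = _stream_from(t, np.zeros(t.size), duration=120.0)
    bg = fretkit.estimate_background(stream, 60.0)
    assert bg.n_segments == 2
    assert bg.rates["dex_d"][1] == 0.0 and bg.counts["dex_d"][1] == 0


def test_background_robust_to_bursts_via_delay_threshold():
    # bursty stream atop 500 cps background: estimate within 10% of 500
    for seed in range(5):
        model = fretkit.TwoStateModel(
            seed=seed, bg_rates={"dex_d": 500.0, "dex_a": 0.0, "aex_a": 0.0})
        stream = fretkit.simulate_photon_stream(model, 60.0)
        bg = fretkit.estimate_background(stream, 60.0)
        assert bg.rates["dex_d"][0] == pytest.approx(500.0, rel=0.10)


def test_single_planted_burst_found_with_most_of_its_photons(rng):
    bg_rate = 100.0
    t_bg = np.sort(rng.uniform(0, 10.0, rng.poisson(2 * bg_rate * 10)))
    d_bg = (rng.random(t_bg.size) < 0.5).astype(np.uint8)
    t_b = np.sort(rng.uniform(5.0, 5.0 + 200 / (20 * 2 * bg_rate), 200))
    d_b = (rng.random(200) < 0.5).astype(np.uint8)
    t = np.concatenate([t_bg, t_b])
    stream = _stream_from(t, np.concatenate([d_bg, d_b]), duration=10.0)
    bg = fretkit.estimate_background(stream, segment_s=10.0)
    bursts = fretkit.search_bursts(stream, bg, min_size=50)
    assert len(bursts) == 1
    assert bursts["n_dd"].item() + bursts["n_da"].item() >= 180


@pytest.mark.parametrize("n_photons,accepted", [(49, 0), (50, 1)])
def test_min_size_boundary(n_photons, accepted, rng):
    t = np.sort(rng.uniform(1.0, 1.001, n_photons))
    det = np.tile([0, 1], n_photons)[:n_photons]
    stream = _stream_from(t, det, duration=2.0)
    bursts = fretkit.search_bursts(stream, nominal_background(2.0),
                                   min_size=50)
    assert len(bursts) == accepted


def test_raising_thresholds_never_grows_the_selection():
    # raising threshold_factor can split a burst in two (both above
    # min_size), so the monotone quantity is the accepted photon coverage,
    # not the burst count; min_size only discards, so its count is monotone
    model = fretkit.TwoStateModel(seed=20)
    stream = fretkit.simulate_photon_stream(model, 20.0)
    bg = fretkit.estimate_background(stream)
    cover_prev = np.inf
    for factor in (2.0, 3.0, 5.0, 10.0):
        b = fretkit.search_bursts(stream, bg, threshold_factor=factor)
        cover = int((b["i_stop"] - b["i_start"] + 1).sum())
        assert cover <= cover_prev
        cover_prev = cover
    n_prev = np.inf
    for min_size in (20, 50, 100, 200):
        n = len(fretkit.search_bursts(stream, bg, min_size=min_size))
        assert n <= n_prev
        n_prev = n


def test_bursts_are_disjoint_and_ordered(static_run):
    b = static_run["bursts"]
    assert (b["i_start"].to_numpy()[1:] > b["i_stop"].to_numpy()[:-1]).all()
    assert (b["duration"] > 0).all()
    assert (b["n_dd"] + b["n_da"] >= 50).all()


def test_search_matches_brute_force_reference():
    for seed in range(5):
        model = fretkit.TwoStateModel(seed=seed, burst_rate=40.0)
        stream = fretkit.simulate_photon_stream(model, 2.5)
        bg = fretkit.estimate_background(stream, segment_s=2.5)
        for mode in ("and", "any"):
            bursts = fretkit.search_bursts(stream, bg, mode=mode)
            ref = brute_force_bursts(stream, bg, mode=mode)
            dex_idx = np.nonzero(stream.mask_dex)[0]
            got = [(int(np.searchsorted(dex_idx, lo)),
                    int(np.searchsorted(dex_idx, hi)))
                   for lo, hi in zip(bursts["i_start"], bursts["i_stop"])]
            assert got == ref


def test_search_input_validation(static_run):
    stream, bg = static_run["stream"], static_run["bg"]
    with pytest.raises(ValueError):
        fretkit.search_bursts(stream, bg, threshold_factor=0.0)
    with pytest.raises(ValueError):
        fretkit.search_bursts(stream, bg, min_size=5, window_m=10)
    with pytest.raises(ValueError):
        fretkit.estimate_background(stream, segment_s=0.0)
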
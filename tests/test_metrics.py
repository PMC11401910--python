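"""E/S arithmetic, correction chain, ALEX-2CDE and the burst filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fretkit
from fretkit import CorrectionSet, PhotonStream
from fretkit.bursts import BackgroundEstimate
from fretkit.metrics import alex_2cde, corrected_es, filter_bursts, raw_es
from fretkit.reference import alex_2cde_brute


def _bg(rates=(0.0, 0.0, 0.0), duration=1.0):
    keys = ("dex_d", "dex_a", "aex_a")
    return BackgroundEstimate(np.array([0.0, duration]),
                              {k: np.array([float(r)])
                               for k, r in zip(keys, rates)},
                              {k: np.array([0]) for k in keys})


def _bursts(n_dd, n_da, n_aa, duration=0.001):
    return pd.DataFrame({"i_start": [0], "i_stop": [1], "t_start": [0.0],
                         "t_stop": [duration], "duration": [duration],
                         "n_dd": [n_dd], "n_da": [n_da], "n_aa": [n_aa],
                         "segment": [0]})


@pytest.mark.parametrize("counts,expected", [
    ((50, 0, 0), (0.0, 1.0)),
    ((25, 25, 50), (0.5, 0.5)),
])
def test_raw_es_closed_forms(counts, expected):
    e, s = raw_es(_bursts(*counts), _bg())
    assert e[0] == pytest.approx(expected[0], abs=1e-12)
    assert s[0] == pytest.approx(expected[1], abs=1e-12)


def test_raw_es_background_subtraction_worked_example():
    # 60/40 counts, 1000 cps background in each Dex stream, 10 ms burst
    e, _ = raw_es(_bursts(60, 40, 0, duration=0.010),
                  _bg((1000.0, 1000.0, 0.0)))
    assert e[0] == pytest.approx((40 - 10) / (50 + 30), abs=1e-12)


def test_corrected_es_worked_example():
    c = CorrectionSet(lk=0.14, dir=0.14, gamma=1.0, beta=1.4)
    e, s = corrected_es(_bursts(100, 64, 100), _bg(), c)
    assert e[0] == pytest.approx(36 / 136, abs=1e-12)
    assert s[0] == pytest.approx(136 / (136 + 100 / 1.4), abs=1e-12)


@given(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500))
def test_neutral_corrections_equal_raw(n_dd, n_da, n_aa):
    b = _bursts(n_dd, n_da, n_aa)
    e_raw, s_raw = raw_es(b, _bg())
    e, s = corrected_es(b, _bg(), CorrectionSet.neutral())
    np.testing.assert_allclose(e, e_raw, atol=1e-14)
    np.testing.assert_allclose(s, s_raw, atol=1e-14)


def test_corrected_e_decreases_with_leakage_and_direct_excitation():
    b = _bursts(100, 64, 100)
    prev = np.inf
    for lk in (0.0, 0.1, 0.2):
        e, _ = corrected_es(b, _bg(), CorrectionSet(lk=lk, dir=0.0))
        assert e[0] < prev
        prev = e[0]
    prev = np.inf
    for dr in (0.0, 0.1, 0.2):
        e, _ = corrected_es(b, _bg(), CorrectionSet(lk=0.0, dir=dr))
        assert e[0] < prev
        prev = e[0]


# -- ALEX-2CDE ---------------------------------------------------------------

def _burst_stream(t_dex, t_aex):
    t = np.concatenate([t_dex, t_aex])
    nano = np.concatenate([np.full(len(t_dex), 100),
                           np.full(len(t_aex), 1500)]).astype(np.int32)
    det = np.concatenate([np.zeros(len(t_dex)),
                          np.ones(len(t_aex))]).astype(np.uint8)
    ts = np.floor(np.asarray(t) * 1e7).astype(np.int64)
    order = np.lexsort((nano, ts))
    stream = PhotonStream(ts[order], nano[order], det[order],
                          meta={"duration_s": float(t.max()) + 1e-3})
    bursts = pd.DataFrame({"t_start": [0.0], "t_stop": [float(t.max())],
                           "duration": [float(t.max())]})
    return stream.validate(), bursts


def test_alternating_well_mixed_burst_scores_low():
    t = np.arange(200) * 20e-6
    stream, bursts = _burst_stream(t[::2], t[1::2])
    score = alex_2cde(stream, bursts)[0]
    assert score < 30


def test_segregated_burst_scores_above_cutoff():
    # all Aex photons precede all Dex photons (acceptor-bleach surrogate)
    t_aex = np.arange(100) * 20e-6
    t_dex = 5e-3 + np.arange(100) * 20e-6
    stream, bursts = _burst_stream(t_dex, t_aex)
    assert alex_2cde(stream, bursts)[0] > 95


def test_score_is_invariant_under_time_translation(rng):
    t_dex = np.sort(rng.uniform(0, 2e-3, 80))
    t_aex = np.sort(rng.uniform(0, 2e-3, 120))
    s1 = alex_2cde_brute(t_dex, t_aex, 100e-6)
    s2 = alex_2cde_brute(t_dex + 5.0, t_aex + 5.0, 100e-6)
    assert s1 == pytest.approx(s2, abs=1e-9)


def test_alex_2cde_matches_brute_force_reference(rng):
    for _ in range(5):
        t_dex = np.sort(rng.uniform(0, 3e-3, rng.integers(20, 120)))
        t_aex = np.sort(rng.uniform(0, 3e-3, rng.integers(20, 120)))
        stream, bursts = _burst_stream(t_dex, t_aex)
        fast = alex_2cde(stream, bursts)[0]
        # feed the brute-force reference the stream's own (clock-quantised)
        # times so both paths see identical inputs
        slow = alex_2cde_brute(stream.times[stream.mask_dex],
                               stream.times[stream.mask_aex_a], 100e-6)
        assert fast == pytest.approx(slow, rel=1e-9)


def test_burst_without_aex_photons_gets_maximal_score_and_reason():
    t_dex = np.arange(100) * 20e-6
    stream, bursts = _burst_stream(t_dex, [])
    bursts = bursts.assign(i_start=0, i_stop=99, n_dd=60, n_da=40, n_aa=0,
                           segment=0)
    metrics = fretkit.compute_metrics(stream, bursts, _bg(), CorrectionSet())
    assert metrics["alex2cde"].item() == 100.0
    out = filter_bursts(metrics)
    assert not out["passed"].item()
    assert "alex2cde" in out["reason"].item()


# -- filters -----------------------------------------------------------------

def _metrics(s_values, scores):
    n = len(s_values)
    return pd.DataFrame({"e_corr": [0.5] * n, "s_corr": s_values,
                         "alex2cde": scores})


def test_filter_boundaries():
    out = filter_bursts(_metrics([0.71, 0.5, 0.3, 0.299], [10, 95, 95.1, 10]))
    assert list(out["passed"]) == [False, True, False, False]
    assert out["reason"].iloc[0] == "s_range"
    assert out["reason"].iloc[2] == "alex2cde"


def test_filter_composition_is_order_independent():
    m = _metrics([0.2, 0.5, 0.8, 0.6], [10, 99, 10, 50])
    a = filter_bursts(m)
    # apply in the other order: 2CDE first (via permissive S), then S
    b1 = filter_bursts(m, s_min=-np.inf, s_max=np.inf)
    keep = b1[b1["passed"]]
    b2 = filter_bursts(keep, s_min=0.3, s_max=0.7)
    assert set(b2[b2["passed"]].index) == set(a[a["passed"]].index)


def test_filter_rejects_bad_range(static_run):
    with pytest.raises(ValueError):
        filter_bursts(_metrics([0.5], [10]), s_min=0.7, s_max=0.3)


def test_donor_only_population_mostly_rejected():
    model = fretkit.TwoStateModel(E1=0.0, E2=0.0, S_true=0.97, seed=30)
    stream = fretkit.simulate_photon_stream(model, 20.0)
    bg = fretkit.estimate_background(stream)
    bursts = fretkit.search_bursts(stream, bg)
    assert len(bursts) > 50
    out = filter_bursts(fretkit.compute_metrics(stream, bursts, bg,
                                                model.corrections))
    assert (~out["passed"]).mean() >= 0.99


def test_histogram_mode_picks_densest_bin(rng):
    v = np.concatenate([rng.normal(0.45, 0.05, 3000),
                        rng.normal(0.8, 0.15, 500)])
    assert fretkit.histogram_mode(v, 0.02) == pytest.approx(0.45, abs=0.021)
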
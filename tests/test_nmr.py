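"""Intensity ratios, CSPs, Z-scores and the perturbation-mapping chain."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fretkit.nmr import (csp, handle_broadened, intensity_ratio,
                         map_perturbations, zscores)
from fretkit.simulate import NMRSyntheticSpec, simulate_nmr_pair


def test_intensity_ratio_identity():
    assert intensity_ratio(3.0, 3.0, 0.0, 0.0) == (1.0, 0.0)


def test_intensity_ratio_error_forms_worked_example():
    r, dr = intensity_ratio(100.0, 50.0, 10.0, 5.0, mode="as_printed")
    assert r == pytest.approx(0.5, abs=1e-12)
    assert dr == pytest.approx(0.5 * np.sqrt(0.1) + np.sqrt(0.1), abs=1e-12)
    _, dq = intensity_ratio(100.0, 50.0, 10.0, 5.0, mode="quadrature")
    assert dq == pytest.approx(0.5 * np.sqrt(0.02), abs=1e-12)


def test_intensity_ratio_rejects_nonpositive_apo():
    with pytest.raises(ValueError):
        intensity_ratio(0.0, 1.0, 0.1, 0.1)
    with pytest.raises(ValueError):
        intensity_ratio(1.0, 1.0, 0.1, 0.1, mode="nope")


def test_csp_closed_forms():
    assert csp(0.0, 0.0) == 0.0
    assert csp(-0.07, 0.0) == pytest.approx(0.07, abs=1e-15)
    assert csp(0.02, 0.2) == pytest.approx(
        np.sqrt(0.02**2 + (0.251 * 0.2)**2), abs=1e-15)


@given(st.floats(-1, 1), st.floats(-5, 5))
def test_csp_is_sign_invariant_and_nonnegative(dh, dc):
    assert csp(dh, dc) == pytest.approx(csp(-dh, -dc), abs=1e-12)
    assert csp(dh, dc) >= 0


def test_zscores_closed_form_and_errors():
    z = zscores([1.0, 2.0, 3.0])
    np.testing.assert_allclose(z, [-1.224744871391589, 0.0,
                                   1.224744871391589], atol=1e-12)
    with pytest.raises(ValueError):
        zscores([2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        zscores([1.0])


@given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
def test_zscore_normalisation_identity(values):
    x = np.asarray(values)
    if x.std() < 1e-6:
        return
    z = zscores(x)
    assert abs(z.mean()) < 1e-9
    assert z.std() == pytest.approx(1.0, abs=1e-9)


def test_broadened_rule_substitutes_noise_floor():
    assert handle_broadened(0.05, 0.1) == (0.1, True)
    assert handle_broadened(0.2, 0.1) == (0.2, False)
    assert handle_broadened(0.2, 0.1, flagged=True) == (0.1, True)


def _pair(seed=1, **kw):
    spec = NMRSyntheticSpec(seed=seed, **kw)
    return simulate_nmr_pair(spec)


def test_identical_tables_have_no_significant_residues():
    apo, _ = _pair(noise_floor=1e-9)
    records, summary = map_perturbations(apo, apo.copy())
    np.testing.assert_allclose(records["R"], 1.0, atol=1e-12)
    np.testing.assert_allclose(records["CSP"], 0.0, atol=1e-12)
    assert not records["significant"].any()
    assert summary["n_significant"].sum() == 0


def test_perturbation_table_z_identity_and_asterisks():
    apo, bound = _pair(seed=3, hotspot_residues=frozenset({2, 9}),
                       attenuation=0.2, noise_floor=0.02)
    records, _ = map_perturbations(apo, bound)
    assert abs(records["z_intensity"].mean()) < 1e-9
    assert records["z_intensity"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    assert (records.loc[records["broadened"], "mark"] == "*").all()


def test_broadened_substitution_is_stable_and_strongly_positive():
    # a vanished peak enters with the noise floor: the result is finite,
    # independent of the meaningless sub-noise measurement, and still the
    # dataset's strongest intensity-loss Z
    apo, bound = _pair(seed=4, n_residues=30, hotspot_residues=frozenset({5}),
                       attenuation=0.05, noise_floor=0.2)
    recs = []
    for measured in (0.0, 0.001, 0.19):
        b = bound.copy()
        b.loc[b["residue"] == 5, "intensity"] = measured
        rec, _ = map_perturbations(apo, b)
        recs.append(rec.loc[rec["residue"] == 5])
    z_values = [r["z_intensity"].item() for r in recs]
    assert z_values[0] == pytest.approx(z_values[1], abs=1e-12)
    assert z_values[0] == pytest.approx(z_values[2], abs=1e-12)
    assert all(r["broadened"].item() for r in recs)
    full, _ = map_perturbations(apo, bound)
    assert full["z_intensity"].idxmax() == \
        full.index[full["residue"] == 5].item()
    assert full.loc[full["residue"] == 5, "z_intensity"].item() > 0


def test_domain_contrast_core_stronger_than_p2():
    apo, bound = _pair(seed=5)
    # plant uniform mild loss in P2, strong loss in the core domains
    p2 = bound["domain"] == "P2"
    core = bound["domain"].str.startswith("core")
    rng = np.random.default_rng(0)
    bound.loc[p2, "intensity"] *= rng.uniform(0.6, 0.9, int(p2.sum()))
    bound.loc[core, "intensity"] *= 0.3
    records, summary = map_perturbations(apo, bound)
    z = summary.set_index("domain")["mean_z_intensity"]
    assert z["core-N"] > z["P2"] and z["core-C"] > z["P2"]


def test_excluded_and_overlapped_peaks_are_dropped():
    apo, bound = _pair(seed=6)
    apo.loc[apo["residue"] == 1, "flags"] = "overlapped"
    bound.loc[bound["residue"] == 2, "flags"] = "excluded"
    records, _ = map_perturbations(apo, bound)
    assert not set(records["residue"]) & {1, 2}


def test_no_common_residues_is_an_error():
    apo, bound = _pair(seed=7)
    bound["residue"] += 1000
    with pytest.raises(ValueError, match="no common residues"):
        map_perturbations(apo, bound)


def test_hotspots_rank_top_by_intensity_z_single_seed():
    hot = frozenset({3, 11, 19, 25, 33, 40})
    apo, bound = _pair(seed=8, n_residues=40, hotspot_residues=hot,
                       attenuation=0.4, noise_floor=0.05)
    records, _ = map_perturbations(apo, bound)
    top6 = set(records.nlargest(6, "z_intensity")["residue"])
    assert len(top6 & hot) >= 5
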
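import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps
from scipy.stats import spearmanr

from stnspot.dataio import STNModel, default_stn_model
from stnspot.synthcohort import (GroundTruth, SourceSpec, SynthConfig,
                                 band_limited_noise, default_sources,
                                 emg_burst_envelope, make_lead_geometry,
                                 raised_cosine_bump, simulate_clinical_scores,
                                 simulate_cohort, simulate_contact_powers,
                                 simulate_recording)


def _small_cfg(**kw):
    base = dict(n_hemispheres=2, n_trials=5, rest_dur_s=8.0, fs_raw=800.0)
    base.update(kw)
    return dataclasses.replace(SynthConfig(), **base)


# -- geometry ---------------------------------------------------------------

def test_lead_geometry_layout():
    geom = make_lead_geometry(seed=0)
    assert len(geom) == 8
    pos = np.array([c.position for c in geom])
    # rings at contact 0 and 7, segment triplets in between share axial levels
    axis = pos[7] - pos[0]
    axis /= np.linalg.norm(axis)
    proj = (pos - pos[0]) @ axis
    np.testing.assert_allclose(sorted(proj), [0, 2, 2, 2, 4, 4, 4, 6], atol=1e-9)
    # segments sit 0.66 mm off the axis
    radial = np.linalg.norm(pos - (pos[0] + proj[:, None] * axis), axis=1)
    np.testing.assert_allclose(radial[[1, 2, 3, 4, 5, 6]], 0.66, atol=1e-9)
    np.testing.assert_allclose(radial[[0, 7]], 0.0, atol=1e-9)


def test_lead_geometry_deterministic():
    a = make_lead_geometry(seed=42)
    b = make_lead_geometry(seed=42)
    np.testing.assert_array_equal(
        np.array([c.position for c in a]), np.array([c.position for c in b])
    )


def test_center_piercing_trajectory_hits_stn():
    geom = make_lead_geometry(default_stn_model(), seed=1,
                              target_jitter_mm=0.0, entry_jitter_mm=0.0)
    assert sum(c.inside_stn for c in geom) >= 2


def test_rejection_sampling_always_yields_two_inside_contacts():
    stn = default_stn_model()
    for seed in range(1000):
        geom = make_lead_geometry(stn, seed=seed, target_jitter_mm=2.0,
                                  entry_jitter_mm=2.0)
        assert sum(c.inside_stn for c in geom) >= 2


def test_impossible_geometry_raises():
    tiny = STNModel(center=(500.0, 500.0, 500.0), semi_axes=(0.01, 0.01, 0.01))
    with pytest.raises(RuntimeError, match="geometry"):
        make_lead_geometry(tiny, seed=0, target_jitter_mm=50.0, max_retries=5)


# -- envelopes & carriers ---------------------------------------------------

@given(p=st.floats(0.05, 0.95))
@settings(deadline=None, max_examples=25, derandomize=True)
def test_bump_peaks_exactly_at_peak_frac(p):
    f = np.linspace(0, 1, 2001)
    bump = raised_cosine_bump(f, p)
    assert abs(f[np.argmax(bump)] - p) < 1e-3
    assert raised_cosine_bump(np.array([p]), p)[0] == pytest.approx(1.0)
    assert bump.min() < 1e-12  # compact support: zero outside the bump


def test_emg_envelope_spans_whole_movement():
    f = np.linspace(0, 1, 1001)
    env = emg_burst_envelope(f, 0.29)
    assert f[np.argmax(env)] == pytest.approx(0.29, abs=1e-3)
    assert env[1] > 0  # prompt rise at onset
    assert env[-2] > 0  # burst lasts until offset


@pytest.mark.parametrize("f_lo,f_hi", [(13, 30), (60, 90), (302, 390)])
def test_carrier_power_concentrated_in_band(f_lo, f_hi, rng):
    fs = 800.0
    x = band_limited_noise(2 ** 15, fs, f_lo, f_hi, rng)
    f, pxx = sps.periodogram(x, fs)
    inband = pxx[(f >= f_lo - 2) & (f <= f_hi + 2)].sum()
    assert inband / pxx.sum() >= 0.95
    assert x.std() == pytest.approx(1.0, rel=1e-6)


# -- recording --------------------------------------------------------------

def test_recording_deterministic():
    cfg = _small_cfg()
    geom = make_lead_geometry(seed=3)
    r1, g1 = simulate_recording(cfg, geom, seed=5)
    r2, g2 = simulate_recording(cfg, geom, seed=5)
    np.testing.assert_array_equal(r1.lfp, r2.lfp)
    np.testing.assert_array_equal(r1.emg, r2.emg)
    assert g1.to_dict() == g2.to_dict()


def test_zero_gain_sources_leave_pure_noise():
    cfg = _small_cfg()
    sources = [dataclasses.replace(s, amp_rest=0.0, amp_premove=0.0,
                                   move_envelope_gain=0.0)
               for s in default_sources()]
    cfg = dataclasses.replace(cfg, sources=sources)
    geom = make_lead_geometry(seed=3)
    rec, _ = simulate_recording(cfg, geom, seed=5)
    # movement-locked band power should not differ from rest: compare variance
    # of a movement segment vs a rest segment
    fs = rec.fs
    on = rec.events.emg_onset_s[0]
    mov = rec.lfp[:, int(on * fs): int((on + 1.0) * fs)]
    rest = rec.lfp[:, int(1.0 * fs): int(2.0 * fs)]
    assert np.var(mov) == pytest.approx(np.var(rest), rel=0.25)


def test_events_are_consistent():
    cfg = _small_cfg(n_trials=8)
    geom = make_lead_geometry(seed=0)
    rec, gt = simulate_recording(cfg, geom, seed=1)
    ev = rec.events
    assert len(ev) == 8
    assert np.all(ev.cue_time_s < ev.emg_onset_s)
    assert np.all(ev.emg_onset_s < ev.emg_offset_s)
    assert len(gt.movement_durations_s) == 8


def test_sampling_rate_below_band_edge_rejected():
    with pytest.raises(ValueError, match="2x top band edge"):
        _small_cfg(fs_raw=700.0)


# -- cohort -----------------------------------------------------------------

def test_cohort_count_and_determinism(tmp_path):
    cfg = _small_cfg(n_hemispheres=3, rng_seed=9)
    recs1, gts1, _ = simulate_cohort(cfg, out_dir=tmp_path / "a")
    recs2, gts2, _ = simulate_cohort(cfg, out_dir=tmp_path / "b")
    assert len(recs1) == 3
    np.testing.assert_array_equal(recs1[0].lfp, recs2[0].lfp)
    assert (tmp_path / "a" / "hemi_002" / "signals.tsv.gz").exists()
    assert (tmp_path / "a" / "ground_truth.json").exists()
    assert gts1[1].to_dict() == gts2[1].to_dict()


def test_movement_durations_match_cohort_statistics():
    cfg = _small_cfg(n_hemispheres=6, n_trials=18, rng_seed=21)
    _, gts, _ = simulate_cohort(cfg)
    durs = np.concatenate([gt.movement_durations_s for gt in gts])
    se = 0.59 / np.sqrt(len(durs))
    assert abs(durs.mean() - 1.54) < 3 * se + 0.05  # clipping margin


def test_ground_truth_round_trips():
    cfg = _small_cfg()
    geom = make_lead_geometry(seed=3)
    _, gt = simulate_recording(cfg, geom, seed=5)
    back = GroundTruth.from_dict(gt.to_dict())
    assert back.to_dict() == gt.to_dict()


# -- clinical ---------------------------------------------------------------

def _fake_gts(props):
    return [GroundTruth(bands={}, emg_peak_frac=0.29,
                        planted_propagation={"FG": p}) for p in props]


def test_zero_coefficients_give_uncorrelated_scores():
    props = np.linspace(0.1, 2.0, 40)
    clin = simulate_clinical_scores(_fake_gts(props), {}, noise_sd=5.0, seed=0)
    rho, p = spearmanr(props, [c.pct_improvement for c in clin])
    assert p > 0.01


def test_noiseless_single_coefficient_is_monotone():
    props = np.linspace(0.1, 2.0, 30)
    clin = simulate_clinical_scores(_fake_gts(props), {"FG": -10.0},
                                    noise_sd=0.0, seed=0)
    rho, _ = spearmanr(props, [c.pct_improvement for c in clin])
    assert rho == pytest.approx(-1.0)
    clin = simulate_clinical_scores(_fake_gts(props), {"FG": +10.0},
                                    noise_sd=0.0, seed=0)
    rho, _ = spearmanr(props, [c.pct_improvement for c in clin])
    assert rho == pytest.approx(1.0)


def test_negative_coefficient_sign_recovered_across_replicates():
    hits = 0
    for rep in range(50):
        rng = np.random.default_rng(rep)
        props = rng.uniform(0.2, 2.0, 63)
        clin = simulate_clinical_scores(_fake_gts(props), {"FG": -12.0},
                                        noise_sd=8.0, seed=rep)
        rho, p = spearmanr(props, [c.pct_improvement for c in clin])
        hits += (rho < 0) and (p < 0.05)
    assert hits >= 45


# -- spatial layer ----------------------------------------------------------

def test_contact_power_gain_profile(rng):
    geom = make_lead_geometry(seed=2)
    center = geom[3].position
    p = simulate_contact_powers(geom, center, sigma_mm=1.5,
                                noise_log_sd=0.0, rng=rng)
    d = np.linalg.norm(np.array([c.position for c in geom]) - center, axis=1)
    assert p[3] == pytest.approx(1.0)
    np.testing.assert_allclose(p, np.exp(-(d / 1.5) ** 2))  # Gaussian falloff


def test_null_contact_powers_are_exchangeable(rng):
    geom = make_lead_geometry(seed=2)
    p = simulate_contact_powers(geom, None, 2.0, 0.5, rng)
    assert p.shape == (8,)
    assert np.all(p > 0)
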
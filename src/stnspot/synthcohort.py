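"""Synthetic cohorts of STN lead recordings with planted spectral-spatial structure.

Each hemisphere gets a Vercise-Cartesia-style 8-contact lead threaded through an
STN model, a multichannel LFP built from band-limited noise carriers whose gain
is a spatial Gaussian around a (possibly moving) source center, a signed forearm
EMG channel with movement-locked bursts, and an event table with the true cue /
movement-onset / movement-offset times. Ground truth (source trajectories,
envelope peak fractions, per-hemisphere planted propagation, clinical
coefficients) is stored next to the data so every downstream stage can be
validated against what was planted.

Sub-band sources follow the canonical movement-related pattern: beta (13-30 Hz)
desynchronizes early in the movement while the high-frequency bands — HG
(60-90), FG (110-140), SHFO (202-298) and FHFO (302-390 Hz) — synchronize,
peaking just before mid-movement, with the HG/FG hotspots drifting superiorly
as the movement unfolds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .dataio import (
    ContactRecord,
    ClinicalRecord,
    EventTable,
    LeadRecording,
    STNModel,
    default_stn_model,
    write_bundle,
    write_clinical,
)

__all__ = [
    "SourceSpec",
    "SynthConfig",
    "GroundTruth",
    "default_sources",
    "make_lead_geometry",
    "simulate_recording",
    "simulate_cohort",
    "simulate_clinical_scores",
    "simulate_contact_powers",
    "raised_cosine_bump",
    "emg_burst_envelope",
    "band_limited_noise",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SourceSpec:
    """One band-limited neural source with a spatial Gaussian gain profile.

    The source center moves along a piecewise trajectory: ``center_rest``
    outside trials, ``center_premove`` during the pre-movement window, and a
    linear interpolation from ``center_move_start`` to ``center_move_end``
    across the movement — planting a known hotspot propagation. ``polarity``
    +1 yields event-related synchronization (power increase), -1 yields
    desynchronization (the beta pattern).
    """

    band_name: str
    f_lo: float
    f_hi: float
    center_rest: tuple
    center_premove: tuple
    center_move_start: tuple
    center_move_end: tuple
    spatial_sigma: float = 2.0        # mm
    amp_rest: float = 1.0
    amp_premove: float = 1.2
    move_envelope_peak_frac: float = 0.44
    move_envelope_gain: float = 2.0
    move_envelope_half_width: float = 0.35   # fraction of movement; caps at peak/edge distance
    polarity: int = 1

    def __post_init__(self) -> None:
        if not self.f_lo < self.f_hi:
            raise ValueError(f"{self.band_name}: need f_lo < f_hi")
        if self.spatial_sigma <= 0:
            raise ValueError(f"{self.band_name}: spatial_sigma must be > 0")
        if not 0.0 <= self.move_envelope_peak_frac <= 1.0:
            raise ValueError(f"{self.band_name}: envelope peak fraction outside [0, 1]")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        for name in ("center_rest", "center_premove", "center_move_start", "center_move_end"):
            v = np.asarray(getattr(self, name), float)
            if v.shape != (3,):
                raise ValueError(f"{self.band_name}: {name} must be a 3-vector")


def default_sources(stn_center=(12.0, -13.0, -7.0)) -> list:
    """The five sub-band sources used as the cohort's study conditions.

    Envelope peak fractions and the superior movement drifts are the planted
    ground truths the pipeline is expected to recover: EMG peak near 29% of
    the movement, ERS peaks at 44/48/44/43% for HG/FG/SHFO/FHFO, beta trough
    at 14%, and a (0, 0, +1.18) mm HG hotspot shift (+0.84 mm for FG, mildly
    inferior for SHFO, none for FHFO).
    """
    c = np.asarray(stn_center, float)
    lo = tuple(c + (0.0, -0.5, -0.8))  # slightly posterior-inferior motor STN

    def src(name, f_lo, f_hi, peak, dz_move, polarity=1, **kw):
        start = np.asarray(lo)
        end = start + (0.0, 0.0, dz_move)
        return SourceSpec(
            band_name=name, f_lo=f_lo, f_hi=f_hi,
            center_rest=lo, center_premove=lo,
            center_move_start=tuple(start), center_move_end=tuple(end),
            move_envelope_peak_frac=peak, polarity=polarity, **kw,
        )

    return [
        src("beta", 13, 30, 0.14, 0.0, polarity=-1,
            amp_rest=2.0, amp_premove=2.0, move_envelope_gain=1.6),
        src("HG", 60, 90, 0.44, +1.18, move_envelope_gain=2.4),
        src("FG", 110, 140, 0.48, +0.84, move_envelope_gain=2.0),
        src("SHFO", 202, 298, 0.44, -0.30, move_envelope_gain=2.0),
        src("FHFO", 302, 390, 0.43, 0.0, move_envelope_gain=2.0),
    ]


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the intraoperative protocol being emulated: 63 hemispheres,
    ~18 usable trials per motion block, 2048 Hz acquisition, 93 s of rest,
    auditory cue followed by movement onset after 0.43 +/- 0.18 s, movement
    duration 1.54 +/- 0.59 s, 8 s intertrial interval.
    """

    n_hemispheres: int = 63
    n_trials: int = 18
    fs_raw: float = 2048.0
    trial_gap_s: float = 8.0
    cue_to_onset_mean_s: float = 0.43
    cue_to_onset_sd_s: float = 0.18
    movement_dur_mean_s: float = 1.54
    movement_dur_sd_s: float = 0.59
    rest_dur_s: float = 93.0
    sources: list = field(default_factory=default_sources)
    pink_noise_scale: float = 1.0
    line_noise_50hz_amp: float = 0.0
    lead_entry_jitter_mm: float = 1.0
    lead_target_jitter_mm: float = 0.8
    emg_peak_frac: float = 0.29
    emg_burst_gain: float = 8.0
    emg_baseline: float = 0.6
    prop_scale_range: tuple = (0.25, 1.75)
    artifact_rate: float = 0.0
    artifact_amp: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("trial_gap_s", "movement_dur_mean_s", "rest_dur_s", "fs_raw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        top = max((s.f_hi for s in self.sources), default=0.0)
        if self.fs_raw < 2.0 * top:
            raise ValueError(
                f"fs_raw={self.fs_raw} below 2x top band edge ({top} Hz)"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sources"] = [asdict(s) for s in self.sources]
        return d


@dataclass
class GroundTruth:
    """What was planted: trajectories, peak fractions, propagation, coefficients."""

    bands: dict                     # band -> centers per state, peak fracs, polarity
    emg_peak_frac: float
    prop_scale: dict = field(default_factory=dict)  # band -> per-hemisphere drift multiplier
    planted_propagation: dict = field(default_factory=dict)   # band -> mm (z drift)
    movement_durations_s: list = field(default_factory=list)
    clinical_coeffs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def raised_cosine_bump(frac: np.ndarray, peak_frac: float,
                       half_width: float | None = None) -> np.ndarray:
    """Symmetric raised-cosine bump: 1 exactly at ``peak_frac``, compact support.

    ``cos^2(pi (f - p) / (2 w))`` on ``|f - p| <= w`` and 0 elsewhere; the
    default half-width ``min(p, 1 - p)`` keeps the support inside [0, 1].
    Symmetry about the peak means any symmetric temporal smoothing downstream
    leaves the peak location unbiased.
    """
    f = np.asarray(frac, float)
    p = float(np.clip(peak_frac, 1e-6, 1 - 1e-6))
    w = half_width if half_width is not None else min(p, 1.0 - p)
    out = np.zeros_like(f)
    m = np.abs(f - p) <= w
    out[m] = np.cos(np.pi * (f[m] - p) / (2.0 * w)) ** 2
    return out


def emg_burst_envelope(frac: np.ndarray, peak_frac: float,
                       plateau: float = 0.3, ramp: float = 0.03) -> np.ndarray:
    """EMG burst: a locally symmetric peak over a sustained plateau.

    The burst must span the entire movement because its rising and descending
    phases define movement onset and offset, so a raised-cosine peak (height
    1 at ``peak_frac``, symmetric, hence unbiased under smoothing) rides on a
    trapezoidal plateau of height ``plateau`` with sharp edge ramps (fraction
    ``ramp`` of the movement) that give threshold detectors prompt on/offsets.
    """
    f = np.asarray(frac, float)
    p = float(np.clip(peak_frac, 1e-6, 1 - 1e-6))
    bump = raised_cosine_bump(f, p, min(p, 1.0 - p))
    with np.errstate(invalid="ignore"):
        base = np.clip(f / ramp, 0.0, 1.0) * np.clip((1.0 - f) / ramp, 0.0, 1.0)
    base = np.where((f >= 0) & (f <= 1), np.clip(base, 0.0, 1.0), 0.0)
    return (1.0 - plateau) * bump + plateau * base


def band_limited_noise(n: int, fs: float, f_lo: float, f_hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Unit-variance white noise band-passed with a zero-phase FIR filter."""
    x = rng.standard_normal(n)
    numtaps = int(min(4097, max(257, round(6 * fs / f_lo)))) | 1
    nyq = fs / 2.0
    hi = min(f_hi, 0.98 * nyq)
    taps = sps.firwin(numtaps, [f_lo, hi], pass_zero=False, fs=fs)
    y = sps.filtfilt(taps, [1.0], x, padlen=min(3 * numtaps, n - 1))
    sd = y.std()
    return y / sd if sd > 0 else y


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    y = np.fft.irfft(spec * scale, n)
    return y / y.std()


# ---------------------------------------------------------------------------
# Lead geometry
# ---------------------------------------------------------------------------

_LEVEL_OFFSETS_MM = (0.0, 2.0, 4.0, 6.0)   # center-to-center along the lead axis
_SEGMENT_RADIUS_MM = 0.66


def make_lead_geometry(stn_model: STNModel | None = None, seed: int = 0,
                       entry_jitter_mm: float = 1.0, target_jitter_mm: float = 0.8,
                       max_retries: int = 200) -> list:
    """Place an 8-contact directional lead on a jittered trajectory through the STN.

    Layout (distal to proximal): ring, 3-segment level, 3-segment level, ring;
    2 mm center-to-center between levels; directional segments sit 0.66 mm off
    the axis at 120 degree spacing, sharing their level's axial coordinate.
    Trajectories are redrawn until at least two contacts land inside the STN,
    mirroring the cohort inclusion rule; a geometry that cannot intersect the
    nucleus after ``max_retries`` draws raises.
    """
    stn = stn_model if stn_model is not None else default_stn_model()
    rng = np.random.default_rng(seed)
    base_dir = np.array([-0.25, 0.35, 1.0])

    for _ in range(max_retries):
        target = stn.center + rng.normal(0.0, target_jitter_mm, 3)
        direction = base_dir + rng.normal(0.0, 0.12, 3) * (entry_jitter_mm / 1.0)
        direction = direction / np.linalg.norm(direction)
        # orthonormal frame for the radial segment offsets
        ref = np.array([1.0, 0.0, 0.0])
        if abs(direction @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(direction, ref)
        u /= np.linalg.norm(u)
        v = np.cross(direction, u)
        phi0 = rng.uniform(0, 2 * np.pi)

        # distal ring 1 mm below target so the two segmented levels straddle it
        tip = target - 1.0 * direction
        positions, ids = [], []
        cid = 0
        for lvl, off in enumerate(_LEVEL_OFFSETS_MM):
            axial = tip + off * direction
            if lvl in (0, 3):  # rings
                positions.append(axial)
                cid += 1
            else:
                for k in range(3):
                    phi = phi0 + 2 * np.pi * k / 3.0
                    positions.append(
                        axial + _SEGMENT_RADIUS_MM * (np.cos(phi) * u + np.sin(phi) * v)
                    )
                    cid += 1
        positions = np.array(positions)
        inside = stn.contains(positions)
        if inside.sum() >= 2:
            sub = stn.subregion_of(positions)
            return [
                ContactRecord(i, positions[i], bool(inside[i]), str(sub[i]))
                for i in range(8)
            ]
    raise RuntimeError(
        "could not place a lead with >=2 contacts inside the STN; "
        "check the geometry configuration"
    )


# ---------------------------------------------------------------------------
# Recording simulation
# ---------------------------------------------------------------------------

def _event_schedule(cfg: SynthConfig, rng: np.random.Generator):
    cues, onsets, offsets = [], [], []
    t = cfg.rest_dur_s + 5.0
    for _ in range(cfg.n_trials):
        delay = float(np.clip(rng.normal(cfg.cue_to_onset_mean_s, cfg.cue_to_onset_sd_s),
                              0.10, 1.20))
        dur = float(np.clip(rng.normal(cfg.movement_dur_mean_s, cfg.movement_dur_sd_s),
                            0.40, 4.00))
        cues.append(t)
        onsets.append(t + delay)
        offsets.append(t + delay + dur)
        t = offsets[-1] + cfg.trial_gap_s
    return np.array(cues), np.array(onsets), np.array(offsets)


def _source_amplitude(src: SourceSpec, t: np.ndarray, cues, onsets, offsets) -> np.ndarray:
    amp = np.full_like(t, src.amp_rest)
    for cue, on, off in zip(cues, onsets, offsets):
        pre = (t >= cue - 1.5) & (t < on)
        amp[pre] = src.amp_premove
        mov = (t >= on) & (t <= off)
        frac = (t[mov] - on) / (off - on)
        p = src.move_envelope_peak_frac
        bump = raised_cosine_bump(
            frac, p, min(src.move_envelope_half_width, p, 1.0 - p))
        amp[mov] = np.maximum(
            0.15, src.amp_rest + src.polarity * src.move_envelope_gain * bump
        )
    return amp


def _source_gain(src: SourceSpec, positions: np.ndarray, t: np.ndarray,
                 onsets, offsets, prop_scale: float) -> np.ndarray:
    """(8, n) spatial gain; the center drifts linearly during each movement."""
    n = t.size

    def gains_at(center):
        d2 = np.sum((positions - center) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * src.spatial_sigma ** 2))

    g = np.repeat(gains_at(np.asarray(src.center_rest, float))[:, None], 1, axis=1)
    out = np.empty((positions.shape[0], n))
    out[:] = g  # broadcast rest gain everywhere
    pre_g = gains_at(np.asarray(src.center_premove, float))[:, None]
    start = np.asarray(src.center_move_start, float)
    end = start + prop_scale * (np.asarray(src.center_move_end, float) - start)
    for on, off in zip(onsets, offsets):
        pre = (t >= on - 2.0) & (t < on)
        out[:, pre] = pre_g
        mov = (t >= on) & (t <= off)
        if mov.any():
            frac = (t[mov] - on) / (off - on)
            centers = start[None, :] + frac[:, None] * (end - start)[None, :]
            d2 = np.sum((positions[:, None, :] - centers[None, :, :]) ** 2, axis=2)
            out[:, mov] = np.exp(-d2 / (2.0 * src.spatial_sigma ** 2))
    return out


def simulate_recording(config: SynthConfig, geometry: list, seed: int,
                       hemisphere_id: str = "hemi_000",
                       prop_scale: dict | float | None = None):
    """Synthesize one hemisphere: (LeadRecording, GroundTruth).

    LFP per contact = sum over sources of
    ``gain(contact, center(t)) * envelope(t) * band-limited carrier`` plus
    pink noise (and optional 50 Hz line). The EMG channel is a signed
    high-frequency burst per trial, peaking at ``emg_peak_frac`` of each
    movement, over a low-amplitude baseline tone.
    """
    rng = np.random.default_rng(seed)
    fs = config.fs_raw
    cues, onsets, offsets = _event_schedule(config, rng)
    total_s = offsets[-1] + 4.0
    n = int(round(total_s * fs))
    t = np.arange(n) / fs
    positions = np.array([c.position for c in geometry])

    if prop_scale is None:
        # independent per-band scales: one band's planted propagation carries
        # no information about another's
        prop_scale = {src.band_name: float(rng.uniform(*config.prop_scale_range))
                      for src in config.sources}
    elif not isinstance(prop_scale, dict):
        prop_scale = {src.band_name: float(prop_scale) for src in config.sources}

    lfp = np.zeros((8, n))
    for src in config.sources:
        carrier = band_limited_noise(n, fs, src.f_lo, src.f_hi, rng)
        amp = _source_amplitude(src, t, cues, onsets, offsets)
        gain = _source_gain(src, positions, t, onsets, offsets,
                            prop_scale[src.band_name])
        lfp += gain * (amp * carrier)[None, :]

    for c in range(8):
        lfp[c] += config.pink_noise_scale * pink_noise(n, rng)
    if config.line_noise_50hz_amp > 0:
        lfp += config.line_noise_50hz_amp * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi)
        )[None, :]

    # EMG: signed burst so the rectification path downstream is exercised
    emg_carrier = band_limited_noise(n, fs, 60.0, min(300.0, 0.45 * fs), rng)
    emg_env = np.full(n, config.emg_baseline)
    for on, off in zip(onsets, offsets):
        mov = (t >= on) & (t <= off)
        frac = (t[mov] - on) / (off - on)
        emg_env[mov] += config.emg_burst_gain * emg_burst_envelope(frac, config.emg_peak_frac)
    emg = emg_env * emg_carrier

    artifact_flags = np.zeros(len(cues), dtype=bool)
    if config.artifact_rate > 0:
        hit = rng.random(len(cues)) < config.artifact_rate
        scale = config.artifact_amp * max(1.0, np.abs(lfp).max())
        for i in np.flatnonzero(hit):
            mov = (t >= onsets[i]) & (t <= offsets[i])
            j = np.flatnonzero(mov)
            if j.size:
                k = j[j.size // 2]
                lfp[:, k: k + int(0.05 * fs)] += scale
        # flags intentionally NOT set: rejection must find these trials itself

    events = EventTable(cues, onsets, offsets, artifact_flags)
    rec = LeadRecording(
        hemisphere_id=hemisphere_id, fs=fs, lfp=lfp, emg=emg,
        events=events, contacts=geometry, side="right",
    )
    bands = {}
    planted = {}
    for src in config.sources:
        start = np.asarray(src.center_move_start, float)
        end = start + prop_scale[src.band_name] * (
            np.asarray(src.center_move_end, float) - start)
        bands[src.band_name] = {
            "center_rest": list(src.center_rest),
            "center_premove": list(src.center_premove),
            "center_move_start": list(start),
            "center_move_end": [float(x) for x in end],
            "envelope_peak_frac": src.move_envelope_peak_frac,
            "polarity": src.polarity,
        }
        planted[src.band_name] = float(np.linalg.norm(end - start))
    gt = GroundTruth(
        bands=bands,
        emg_peak_frac=config.emg_peak_frac,
        prop_scale=prop_scale,
        planted_propagation=planted,
        movement_durations_s=list(offsets - onsets),
    )
    return rec, gt


def simulate_cohort(config: SynthConfig, out_dir=None, stn_model: STNModel | None = None):
    """Simulate ``config.n_hemispheres`` recordings with independent seeds.

    Returns ``(recordings, ground_truths, stn_model)`` and, when ``out_dir``
    is given, writes the dataio bundle layout plus ``ground_truth.json``.
    """
    if config.n_hemispheres < 1:
        raise ValueError("n_hemispheres must be >= 1")
    stn = stn_model if stn_model is not None else default_stn_model()
    master = np.random.default_rng(config.rng_seed)
    hemi_seeds = master.integers(0, 2 ** 31 - 1, size=2 * config.n_hemispheres)
    recs, gts = [], []
    for h in range(config.n_hemispheres):
        hemi_id = f"hemi_{h:03d}"
        geom = make_lead_geometry(
            stn, seed=int(hemi_seeds[2 * h]),
            entry_jitter_mm=config.lead_entry_jitter_mm,
            target_jitter_mm=config.lead_target_jitter_mm,
        )
        rec, gt = simulate_recording(
            config, geom, seed=int(hemi_seeds[2 * h + 1]), hemisphere_id=hemi_id
        )
        recs.append(rec)
        gts.append(gt)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, gt in zip(recs, gts):
            write_bundle(rec, out, ground_truth=gt.to_dict())
        (out / "ground_truth.json").write_text(
            json.dumps({r.hemisphere_id: g.to_dict() for r, g in zip(recs, gts)}, indent=1)
        )
        (out / "manifest.json").write_text(json.dumps({
            "hemispheres": [r.hemisphere_id for r in recs],
            "seed": config.rng_seed,
            "stn_model": stn.to_dict(),
        }, indent=1))
    return recs, gts, stn


def simulate_clinical_scores(ground_truths: list, coeffs: dict, noise_sd: float,
                             seed: int, intercept: float = 65.0,
                             off_intercept: float = 39.4, off_coeffs: dict | None = None,
                             off_noise_sd: float = 11.4):
    """Clinical scores linear in the planted per-hemisphere propagation.

    ``pct_improvement = intercept + sum_b coeffs[b] * propagation_b + noise``
    clipped to [0, 100]; the OFF MDS-UPDRS III score likewise on 0-132. The
    coefficients are recorded into each hemisphere's GroundTruth.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i, gt in enumerate(ground_truths):
        imp = intercept + sum(
            c * gt.planted_propagation.get(b, 0.0) for b, c in coeffs.items()
        ) + rng.normal(0.0, noise_sd)
        imp = float(np.clip(imp, 0.0, 100.0))
        off = off_intercept + sum(
            c * gt.planted_propagation.get(b, 0.0) for b, c in (off_coeffs or {}).items()
        ) + rng.normal(0.0, off_noise_sd)
        off = float(np.clip(off, 5.0, 132.0))
        on = float(np.clip(off * (1.0 - imp / 100.0), 0.0, 132.0))
        gt.clinical_coeffs = {"improvement": dict(coeffs), "off": dict(off_coeffs or {}),
                              "intercept": intercept, "noise_sd": noise_sd}
        records.append(ClinicalRecord(f"patient_{i:03d}", off, on))
    return records


# ---------------------------------------------------------------------------
# Spatial-layer shortcut (contact powers without time series)
# ---------------------------------------------------------------------------

def simulate_contact_powers(geometry: list, center, sigma_mm: float,
                            noise_log_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Per-contact band power for one hemisphere at the spatial stage.

    ``power_c = exp(-||pos_c - center||^2 / sigma^2) * lognormal noise``; with
    ``center=None`` the gain is uniform, making contacts exchangeable — the
    null condition for surrogate-test calibration.
    """
    positions = np.array([c.position for c in geometry])
    if center is None:
        gain = np.ones(len(geometry))
    else:
        d2 = np.sum((positions - np.asarray(center, float)) ** 2, axis=1)
        gain = np.exp(-d2 / (sigma_mm ** 2))  # amplitude gain squared -> power
    return gain * np.exp(rng.normal(0.0, noise_log_sd, size=len(geometry)))
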
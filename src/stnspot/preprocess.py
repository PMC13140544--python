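"""Signal conditioning, EMG onset detection, trial segmentation, artifact rejection.

All filtering is zero-phase (forward-backward), so a symmetric transient stays
symmetric and detected onset times are not biased by filter group delay. LFP:
polyphase anti-aliased decimation to 800 Hz, 0.5 Hz high-pass, notches at the
50 Hz harmonics. EMG: decimation, mean removal, 10 Hz high-pass, full-wave
rectification. Movement trials are aligned to the detected EMG onset and span
3 s before onset to 2 s after offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sps

from .dataio import EventTable, LeadRecording

log = logging.getLogger(__name__)


@dataclass
class PreprocConfig:
    fs_target: float = 800.0
    lfp_highpass_hz: float = 0.5
    emg_highpass_hz: float = 10.0
    notch_base_hz: float = 50.0
    notch_max_hz: float = 400.0
    notch_q: float = 35.0
    trial_pre_s: float = 3.0
    trial_post_offset_s: float = 2.0
    baseline_window_s: tuple = (-3.0, -2.0)     # relative to EMG onset
    premove_window_s: tuple = (-1.5, -0.2)      # relative to cue
    onset_k: float = 3.0
    onset_sustain_ms: float = 50.0
    emg_smooth_ms: float = 20.0
    onset_search_s: float = 2.5
    artifact_z_thresh: float = 5.0

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window_s
        p0, p1 = self.premove_window_s
        if not (b0 < b1 and p0 < p1):
            raise ValueError("windows must be (start, end) with start < end")


@dataclass
class TrialEpoch:
    """One movement trial, time-locked to EMG onset (t = 0)."""

    hemisphere_id: str
    trial_index: int
    fs: float
    lfp: np.ndarray            # (8, n)
    emg_rect: np.ndarray       # (n,)
    time_s: np.ndarray         # relative to EMG onset
    movement_duration_s: float
    cue_time_rel_s: float      # cue relative to onset (negative)

    def __post_init__(self) -> None:
        if self.movement_duration_s <= 0:
            raise ValueError("movement duration must be positive")


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def _decimate(x: np.ndarray, fs: float, fs_target: float) -> np.ndarray:
    if np.isclose(fs, fs_target):
        return np.asarray(x, float)
    frac = Fraction(fs_target / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)

def _highpass(x: np.ndarray, fs: float, fc: float) -> np.ndarray:
    sos = sps.butter(4, fc, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)

def _notch_comb(x: np.ndarray, fs: float, base: float, fmax: float, q: float) -> np.ndarray:
    # a notch exactly at Nyquist is undefined; stop just below it
    freqs = np.arange(base, min(fmax, 0.995 * fs / 2) + 1e-9, base)
    for f0 in freqs:
        b, a = sps.iirnotch(f0, q, fs=fs)
        x = sps.filtfilt(b, a, x, axis=-1)
    return x


def condition_signals(rec: LeadRecording, cfg: PreprocConfig | None = None) -> LeadRecording:
    """Downsample, filter and rectify; returns a new LeadRecording at 800 Hz."""
    cfg = cfg or PreprocConfig()
    if rec.fs < cfg.fs_target:
        raise ValueError(f"recording fs {rec.fs} below target {cfg.fs_target}")
    fs = cfg.fs_target
    lfp = _decimate(rec.lfp, rec.fs, fs)
    lfp = _highpass(lfp, fs, cfg.lfp_highpass_hz)
    lfp = _notch_comb(lfp, fs, cfg.notch_base_hz, cfg.notch_max_hz, cfg.notch_q)
    emg = _decimate(rec.emg, rec.fs, fs)
    emg = emg - emg.mean()
    emg = np.abs(_highpass(emg, fs, cfg.emg_highpass_hz))
    return LeadRecording(
        hemisphere_id=rec.hemisphere_id, fs=fs, lfp=lfp, emg=emg,
        events=rec.events, contacts=rec.contacts, side=rec.side,
    )


# ---------------------------------------------------------------------------
# EMG burst detection
# ---------------------------------------------------------------------------

def detect_emg_bursts(emg_rect: np.ndarray, fs: float, cue_times: np.ndarray,
                      cfg: PreprocConfig | None = None) -> EventTable:
    """Threshold detection of movement bursts in rectified EMG.

    Onset = first post-cue time at which the moving-average EMG exceeds
    baseline mean + k*SD for at least ``onset_sustain_ms``; offset = end of the
    descending phase, i.e. the last suprathreshold sample of that burst (first
    sustained recrossing). Trials without a qualifying burst are flagged as
    artifact with cue-anchored placeholder times.
    """
    cfg = cfg or PreprocConfig()
    cue_times = np.asarray(cue_times, float)
    if cue_times.size == 0:
        raise ValueError("no cue times provided")
    win = max(1, int(round(cfg.emg_smooth_ms / 1000.0 * fs)))
    smooth = np.convolve(emg_rect, np.ones(win) / win, mode="same")
    sustain = max(1, int(round(cfg.onset_sustain_ms / 1000.0 * fs)))

    onsets, offsets, artifact = [], [], []
    for j, cue in enumerate(cue_times):
        b0 = int(round((cue + cfg.premove_window_s[0]) * fs))
        b1 = int(round((cue + cfg.premove_window_s[1]) * fs))
        b0, b1 = max(b0, 0), min(b1, len(smooth))
        base = smooth[b0:b1]
        if base.size < 2:
            onsets.append(cue + 0.1); offsets.append(cue + 0.2); artifact.append(True)
            continue
        thresh = base.mean() + cfg.onset_k * base.std()
        s0 = int(round(cue * fs))
        s1 = min(len(smooth), int(round((cue + cfg.onset_search_s) * fs)))
        above = smooth[s0:s1] > thresh
        onset_idx = _first_sustained(above, sustain)
        if onset_idx is None:
            onsets.append(cue + 0.1); offsets.append(cue + 0.2); artifact.append(True)
            continue
        # backtrack from the threshold crossing to where the envelope left the
        # baseline mean: removes the rise-time lag of the k*SD criterion
        k0 = s0 + onset_idx
        base_mean = base.mean()
        while k0 > s0 and smooth[k0 - 1] > base_mean:
            k0 -= 1
        onset = k0 / fs
        # walk forward to the end of the burst
        e0 = s0 + onset_idx
        e1 = min(len(smooth), e0 + int(round(6.0 * fs)))
        below = smooth[e0:e1] <= thresh
        off_idx = _first_sustained(below, sustain)
        if off_idx is None:
            off_idx = e1 - e0 - 1
        offset = (e0 + off_idx) / fs
        if offset <= onset:
            onsets.append(cue + 0.1); offsets.append(cue + 0.2); artifact.append(True)
            continue
        onsets.append(onset); offsets.append(offset); artifact.append(False)
    return EventTable(cue_times, np.array(onsets), np.array(offsets),
                      np.array(artifact, dtype=bool))


def _first_sustained(mask: np.ndarray, sustain: int):
    """Index of the first run of True of length >= sustain, else None."""
    if mask.size == 0:
        return None
    if sustain <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    conv = np.convolve(mask.astype(int), np.ones(sustain, dtype=int), mode="valid")
    hits = np.flatnonzero(conv == sustain)
    return int(hits[0]) if hits.size else None


# ---------------------------------------------------------------------------
# Segmentation & artifact rejection
# ---------------------------------------------------------------------------

def segment_trials(rec: LeadRecording, events: EventTable | None = None,
                   cfg: PreprocConfig | None = None):
    """Cut one epoch per non-artifact trial; returns (epochs, dropped_log).

    Epochs clipped by the recording edges are dropped and logged, so
    kept + dropped + artifact-flagged always equals the trial count.
    """
    cfg = cfg or PreprocConfig()
    events = events if events is not None else rec.events
    fs = rec.fs
    epochs, dropped = [], []
    for i in range(len(events)):
        if events.artifact[i]:
            continue
        onset = events.emg_onset_s[i]
        offset = events.emg_offset_s[i]
        t0 = onset - cfg.trial_pre_s
        t1 = offset + cfg.trial_post_offset_s
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        if i0 < 0 or i1 > rec.n_samples:
            dropped.append({"trial": i, "reason": "clipped at recording edge"})
            log.info("%s trial %d dropped: clipped at edge", rec.hemisphere_id, i)
            continue
        time_s = np.arange(i0, i1) / fs - onset
        epochs.append(TrialEpoch(
            hemisphere_id=rec.hemisphere_id, trial_index=i, fs=fs,
            lfp=rec.lfp[:, i0:i1], emg_rect=rec.emg[i0:i1], time_s=time_s,
            movement_duration_s=offset - onset,
            cue_time_rel_s=events.cue_time_s[i] - onset,
        ))
    return epochs, dropped


def reject_artifact_trials(epochs: list, cfg: PreprocConfig | None = None):
    """Robust-z rejection on per-channel peak amplitude; returns (kept, log).

    A trial is rejected if any LFP channel's peak absolute amplitude, robustly
    z-scored against that channel's across-trial median/MAD, exceeds
    ``artifact_z_thresh``. Raises if every trial would be rejected.
    """
    cfg = cfg or PreprocConfig()
    if not epochs:
        raise ValueError("no epochs to screen")
    peaks = np.array([np.abs(ep.lfp).max(axis=1) for ep in epochs])  # (trial, ch)
    med = np.median(peaks, axis=0)
    mad = np.median(np.abs(peaks - med), axis=0)
    scale = np.where(mad > 0, 1.4826 * mad, 1e-12)
    z = (peaks - med) / scale
    kept, rejections = [], []
    for i, ep in enumerate(epochs):
        bad = np.flatnonzero(z[i] > cfg.artifact_z_thresh)
        if bad.size:
            rejections.append({
                "hemisphere_id": ep.hemisphere_id,
                "trial": ep.trial_index,
                "channels": ",".join(map(str, bad)),
                "max_z": float(z[i].max()),
                "reason": "peak-amplitude robust z exceeds threshold",
            })
        else:
            kept.append(ep)
    if not kept:
        raise RuntimeError(
            f"all trials rejected for hemisphere {epochs[0].hemisphere_id}"
        )
    return kept, pd.DataFrame(
        rejections, columns=["hemisphere_id", "trial", "channels", "max_z", "reason"]
    )


def preprocess_recording(rec: LeadRecording, cfg: PreprocConfig | None = None,
                         redetect_events: bool = True):
    """Full conditioning path: filter, (re)detect EMG bursts, segment, reject.

    Returns ``(kept_epochs, conditioned_recording, rejection_log)``.
    """
    cfg = cfg or PreprocConfig()
    cond = condition_signals(rec, cfg)
    if redetect_events:
        events = detect_emg_bursts(cond.emg, cond.fs, rec.events.cue_time_s, cfg)
    else:
        events = rec.events
    cond = LeadRecording(
        hemisphere_id=cond.hemisphere_id, fs=cond.fs, lfp=cond.lfp, emg=cond.emg,
        events=events, contacts=cond.contacts, side=cond.side,
    )
    epochs, _ = segment_trials(cond, events, cfg)
    kept, rej = reject_artifact_trials(epochs, cfg)
    return kept, cond, rej
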
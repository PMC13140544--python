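"""Multitaper spectral estimation and event-related synchronization (ERS).

Spectrograms use DPSS (Slepian) tapers in two configurations: a low range
(10-50 Hz; 400 ms windows stepped by 10 ms, +/-2 Hz smoothing, 2.5 Hz grid)
and a high range (50-395 Hz; 200 ms windows, +/-10 Hz smoothing, 5 Hz grid).
Band power is z-scored against a pooled pre-movement baseline (-3 to -2 s
before EMG onset), expressed per sub-band (beta 13-30, HG 60-90, FG 110-140,
SHFO 202-298, FHFO 302-390 Hz), and the movement period is resampled onto a
21-point 0-100% grid (5% bins) so trials of different durations average
cleanly.

Note on the low range: a 400 ms window with +/-2 Hz half-bandwidth has
time-half-bandwidth product 0.8, for which the usual 2TW-1 rule yields no
admissible taper; the taper count is floored at one (a single Slepian), which
realizes the stated smoothing at the cost of periodogram-level variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import dpss

from .preprocess import PreprocConfig, TrialEpoch

MOVE_GRID = np.arange(0.0, 100.0 + 1e-9, 5.0)   # 21 inclusive percent points


@dataclass
class RangeConfig:
    f_lo: float
    f_hi: float
    window_s: float
    step_s: float
    half_bandwidth_hz: float

    @property
    def freq_spacing_hz(self) -> float:
        return 1.0 / self.window_s


@dataclass
class SpectralConfig:
    low: RangeConfig = field(default_factory=lambda: RangeConfig(10.0, 50.0, 0.400, 0.010, 2.0))
    high: RangeConfig = field(default_factory=lambda: RangeConfig(50.0, 395.0, 0.200, 0.010, 10.0))
    bands: dict = field(default_factory=lambda: {
        "beta": (13.0, 30.0, "low"),
        "HG": (60.0, 90.0, "high"),
        "FG": (110.0, 140.0, "high"),
        "SHFO": (202.0, 298.0, "high"),
        "FHFO": (302.0, 390.0, "high"),
    })
    state_epoch_s: float = 0.100        # rest / pre-movement epoch length
    baseline_window_s: tuple = (-3.0, -2.0)
    premove_window_s: tuple = (-1.5, -0.2)

    @property
    def high_bands(self) -> list:
        return [b for b, (_, _, r) in self.bands.items() if r == "high"]


# ---------------------------------------------------------------------------
# Multitaper spectrogram
# ---------------------------------------------------------------------------

def multitaper_spectrogram(x: np.ndarray, fs: float, range_cfg: RangeConfig):
    """Sliding-window DPSS multitaper power.

    Parameters
    ----------
    x : (n,) or (n_channels, n) array
    fs : sampling rate, Hz
    range_cfg : window/step/half-bandwidth and the frequency range to keep

    Returns
    -------
    times : (n_frames,) window-center times, seconds from the start of ``x``
    freqs : (n_freq,) Hz, spaced ``1 / window_s``
    power : (n_channels, n_freq, n_frames) one-sided PSD (x^2 units per Hz);
        leading axis squeezed for 1-D input
    """
    x = np.asarray(x, float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    n_win = int(round(range_cfg.window_s * fs))
    if n_win > n:
        raise ValueError(f"window ({n_win} samples) longer than signal ({n})")
    step = max(1, int(round(range_cfg.step_s * fs)))
    tw = range_cfg.window_s * range_cfg.half_bandwidth_hz
    k = max(1, int(np.floor(2 * tw)) - 1)
    tapers = dpss(n_win, tw, Kmax=k)            # (k, n_win), unit energy
    if tapers.ndim == 1:
        tapers = tapers[None, :]

    starts = np.arange(0, n - n_win + 1, step)
    idx = starts[:, None] + np.arange(n_win)[None, :]
    frames = x[:, idx]                           # (ch, n_frames, n_win)
    tapered = frames[:, :, None, :] * tapers[None, None, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    psd = (spec.real ** 2 + spec.imag ** 2) / fs  # unit-energy tapers
    psd = psd.mean(axis=2)                       # average over tapers
    freqs = np.fft.rfftfreq(n_win, 1.0 / fs)
    # one-sided doubling (DC and Nyquist excluded)
    dbl = np.ones_like(freqs) * 2.0
    dbl[0] = 1.0
    if n_win % 2 == 0:
        dbl[-1] = 1.0
    psd = psd * dbl[None, None, :]
    keep = (freqs >= range_cfg.f_lo - 1e-9) & (freqs <= range_cfg.f_hi + 1e-9)
    times = (starts + n_win / 2.0) / fs
    out = np.swapaxes(psd[:, :, keep], 1, 2)     # (ch, n_freq, n_frames)
    if squeeze:
        out = out[0]
    return times, freqs[keep], out


# ---------------------------------------------------------------------------
# ERS tensor
# ---------------------------------------------------------------------------

@dataclass
class ERSTensor:
    """Baseline-z-scored band power for one hemisphere, all behavioural states.

    ``move_grid_z[band]`` is (n_trials, 8, 21) on the 0-100% movement grid;
    ``rest_z`` / ``premove_z`` hold 100 ms-epoch views; ``trial_z`` keeps the
    full 10 ms-frame series per trial for timing analyses. Units everywhere:
    baseline standard deviations.
    """

    hemisphere_id: str
    bands: list
    trial_z: dict              # band -> list of (8, n_frames)
    frame_times: dict          # band -> list of (n_frames,) rel. EMG onset
    move_grid_z: dict          # band -> (n_trials, 8, 21)
    rest_z: dict               # band -> (8, n_rest_epochs)
    premove_z: dict            # band -> (n_trials, 8, n_pre_epochs)
    emg_grid: np.ndarray       # (n_trials, 21) normalized rectified EMG
    movement_durations_s: np.ndarray
    flagged_channels: list = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return len(self.movement_durations_s)

    def state_mean(self, band: str, state: str) -> np.ndarray:
        """(8,) mean z per contact for 'rest', 'premove' or 'move'."""
        if state == "rest":
            return self.rest_z[band].mean(axis=1)
        if state == "premove":
            return self.premove_z[band].mean(axis=(0, 2))
        if state == "move":
            return self.move_grid_z[band].mean(axis=(0, 2))
        raise ValueError(f"unknown state {state!r}")


def normalize_movement_time(values: np.ndarray, frame_times: np.ndarray,
                            movement_duration_s: float) -> np.ndarray:
    """Interpolate frame series onto the 21-point percent-of-movement grid.

    ``values`` has frames on the last axis; frame_times are seconds relative
    to EMG onset (movement spans [0, duration]).
    """
    if movement_duration_s <= 0:
        raise ValueError("movement duration must be positive")
    grid_t = MOVE_GRID / 100.0 * movement_duration_s
    vals = np.atleast_2d(values)
    in_range = (frame_times >= grid_t[0] - 0.2) & (frame_times <= grid_t[-1] + 0.2)
    if in_range.sum() < 2:
        raise ValueError("movement shorter than two spectrogram frames")
    out = np.stack([np.interp(grid_t, frame_times, row) for row in vals])
    return out if values.ndim > 1 else out[0]


def compute_ers(epochs: list, cfg: SpectralConfig | None = None,
                rest_lfp: np.ndarray | None = None, fs: float | None = None) -> ERSTensor:
    """Spectrograms -> pooled-baseline z-scores -> band/state views.

    The baseline mean and SD are pooled over the (-3, -2) s pre-onset frames of
    all kept trials, per contact and frequency bin; z-scored power is then
    averaged over each band's frequency bins. ``rest_lfp`` (8, n) at ``fs``
    adds the resting-state view, z-scored against the same baseline.
    """
    cfg = cfg or SpectralConfig()
    if not epochs:
        raise ValueError("no epochs")
    fs = fs or epochs[0].fs
    ranges = {"low": cfg.low, "high": cfg.high}

    # pass 1: spectrograms per trial per range
    spect = {r: [] for r in ranges}
    times = {r: [] for r in ranges}
    freqs = {}
    for ep in epochs:
        for rname, rcfg in ranges.items():
            tt, ff, pp = multitaper_spectrogram(ep.lfp, fs, rcfg)
            spect[rname].append(pp)
            times[rname].append(tt + ep.time_s[0])   # rel. EMG onset
            freqs[rname] = ff

    # pooled baseline stats per range: (8, n_freq)
    base_mu, base_sd = {}, {}
    b0, b1 = cfg.baseline_window_s
    for rname in ranges:
        frames = [pp[:, :, (tt >= b0) & (tt <= b1)]
                  for pp, tt in zip(spect[rname], times[rname])]
        allb = np.concatenate(frames, axis=2)
        base_mu[rname] = allb.mean(axis=2)
        base_sd[rname] = allb.std(axis=2)

    flagged = sorted({int(c) for rname in ranges
                      for c in np.flatnonzero((base_sd[rname] == 0).any(axis=1))})
    for rname in ranges:
        base_sd[rname] = np.where(base_sd[rname] > 0, base_sd[rname], 1.0)

    bands = list(cfg.bands)
    trial_z = {b: [] for b in bands}
    frame_times = {b: [] for b in bands}
    move_grid = {b: [] for b in bands}
    premove = {b: [] for b in bands}
    p0, p1 = cfg.premove_window_s
    n_pre = int(round((p1 - p0) / cfg.state_epoch_s))
    emg_grid = []
    durations = []

    for j, ep in enumerate(epochs):
        durations.append(ep.movement_duration_s)
        for b in bands:
            lo, hi, rname = cfg.bands[b]
            ff = freqs[rname]
            sel = (ff >= lo - 1e-9) & (ff <= hi + 1e-9)
            z = (spect[rname][j] - base_mu[rname][:, :, None]) / base_sd[rname][:, :, None]
            bz = z[:, sel, :].mean(axis=1)          # (8, n_frames)
            tt = times[rname][j]
            trial_z[b].append(bz)
            frame_times[b].append(tt)
            move_grid[b].append(
                normalize_movement_time(bz, tt, ep.movement_duration_s)
            )
            # pre-movement 100 ms epochs, windows relative to the cue
            cue = ep.cue_time_rel_s
            pz = np.full((8, n_pre), np.nan)
            for k in range(n_pre):
                w0, w1 = cue + p0 + k * cfg.state_epoch_s, cue + p0 + (k + 1) * cfg.state_epoch_s
                m = (tt >= w0) & (tt < w1)
                if m.any():
                    pz[:, k] = bz[:, m].mean(axis=1)
            premove[b].append(pz)
        # EMG onto the percent grid (smoothed to frame scale)
        win = max(1, int(round(0.02 * fs)))
        em = np.convolve(ep.emg_rect, np.ones(win) / win, mode="same")
        emg_grid.append(np.interp(MOVE_GRID / 100.0 * ep.movement_duration_s,
                                  ep.time_s, em))

    tensor = ERSTensor(
        hemisphere_id=epochs[0].hemisphere_id,
        bands=bands,
        trial_z=trial_z,
        frame_times=frame_times,
        move_grid_z={b: np.array(move_grid[b]) for b in bands},
        rest_z={},
        premove_z={b: np.nan_to_num(np.array(premove[b])) for b in bands},
        emg_grid=np.array(emg_grid),
        movement_durations_s=np.array(durations),
        flagged_channels=flagged,
    )

    if rest_lfp is not None and rest_lfp.shape[-1] > int(cfg.low.window_s * fs):
        for b in bands:
            lo, hi, rname = cfg.bands[b]
            tt, ff, pp = multitaper_spectrogram(rest_lfp, fs, ranges[rname])
            sel = (ff >= lo - 1e-9) & (ff <= hi + 1e-9)
            z = (pp - base_mu[rname][:, :, None]) / base_sd[rname][:, :, None]
            bz = z[:, sel, :].mean(axis=1)
            # collapse into consecutive 100 ms epochs
            per = max(1, int(round(cfg.state_epoch_s / cfg.high.step_s)))
            n_ep = bz.shape[1] // per
            tensor.rest_z[b] = bz[:, : n_ep * per].reshape(8, n_ep, per).mean(axis=2)
    else:
        for b in bands:
            tensor.rest_z[b] = np.zeros((8, 1))
    return tensor


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _focus_contact(tensor: ERSTensor, band: str) -> int:
    """Contact evidencing the strongest movement response for this band.

    Max mean movement z for synchronizing bands; min for beta (ERD).
    """
    mean_by_contact = tensor.move_grid_z[band].mean(axis=(0, 2))
    if band == "beta":
        return int(np.argmin(mean_by_contact))
    return int(np.argmax(mean_by_contact))


def summarize_ers(tensor: ERSTensor, cfg: SpectralConfig | None = None) -> pd.DataFrame:
    """Per-band movement summaries for one hemisphere.

    AUC is the plain sum of the trial-mean z over the 21 grid points; peak
    timing is the grid argmax (argmin for the beta trough), in percent of the
    movement; EMG peak timing comes from the trial-mean normalized rectified
    EMG; ``delta_ers_emg = peak_frac - emg_peak_frac`` and
    ``delta_ers_erd = beta_trough_frac - peak_frac`` (signed percent).
    """
    cfg = cfg or SpectralConfig()
    emg_mean = tensor.emg_grid.mean(axis=0)
    emg_peak_frac = float(MOVE_GRID[np.argmax(emg_mean)])
    beta_trough = np.nan
    if "beta" in tensor.bands:
        c = _focus_contact(tensor, "beta")
        beta_curve = tensor.move_grid_z["beta"][:, c, :].mean(axis=0)
        beta_trough = float(MOVE_GRID[np.argmin(beta_curve)])
    rows = []
    for b in tensor.bands:
        c = _focus_contact(tensor, b)
        curve = tensor.move_grid_z[b][:, c, :].mean(axis=0)
        if b == "beta":
            peak = float(MOVE_GRID[np.argmin(curve)])
        else:
            peak = float(MOVE_GRID[np.argmax(curve)])
        rows.append({
            "hemisphere_id": tensor.hemisphere_id,
            "band": b,
            "contact": c,
            "auc_total": float(curve.sum()),
            "peak_frac": peak,
            "erd_trough_frac": beta_trough,
            "emg_peak_frac": emg_peak_frac,
            "delta_ers_emg": peak - emg_peak_frac,
            "delta_ers_erd": beta_trough - peak,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Standardized cross-correlation
# ---------------------------------------------------------------------------

@dataclass
class XCorrResult:
    pair: str
    lags: np.ndarray
    trace: np.ndarray          # mean normalized cross-correlation per lag
    score: float               # mean r at lags -3..+3
    z: float                   # (score - mu_null) / sd_null
    mu_null: float
    sd_null: float
    p: float


def _xcorr_rows(a: np.ndarray, b: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Per-row Pearson correlation of overlapping segments at each lag.

    Positive lag means the first series leads the second. Returns the mean
    trace across rows; constant overlap segments contribute r = 0.
    """
    n_rows, L = a.shape
    out = np.zeros(len(lags))
    for i, lag in enumerate(lags):
        # positive lag: the first series leads (second is a delayed copy)
        if lag >= 0:
            x, y = a[:, : L - lag], b[:, lag:]
        else:
            x, y = a[:, -lag:], b[:, : L + lag]
        xm = x - x.mean(axis=1, keepdims=True)
        ym = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xm ** 2).sum(axis=1) * (ym ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xm * ym).sum(axis=1) / denom, 0.0)
        out[i] = r.mean()
    return out


def crosscorr_standardized(series_a: np.ndarray, series_b: np.ndarray,
                           n_shuffles: int = 1000, seed: int = 0,
                           pair: str = "", score_halfwidth: int = 3) -> XCorrResult:
    """Trial-paired cross-correlation with a shuffle-standardized lag-0 score.

    ``series_a``/``series_b`` are (n_units, L) matrices of per-trial (or
    per-hemisphere) series on the percent grid; the trace averages per-unit
    normalized cross-correlations over lags -(L-1)..(L-1) (in 5% bins; positive
    lag = ``series_a`` leads). The score (mean r within +/-3 bins of lag 0) is
    standardized against a null that shuffles which unit of ``series_b`` is
    paired with each unit of ``series_a``; p is the two-tailed empirical rank.
    """
    a = np.atleast_2d(np.asarray(series_a, float))
    b = np.atleast_2d(np.asarray(series_b, float))
    if a.shape != b.shape:
        raise ValueError("series must have equal shape")
    n_rows, L = a.shape
    if np.allclose(a, a[:, :1]) or np.allclose(b, b[:, :1]):
        raise ValueError("constant series: correlation undefined")
    lags = np.arange(-(L - 1), L)
    trace = _xcorr_rows(a, b, lags)
    score_lags = np.arange(-score_halfwidth, score_halfwidth + 1)

    # pairwise correlation matrices at the score lags: observed score is the
    # diagonal mean, shuffle-null scores are permuted-index means
    pair_r = np.empty((len(score_lags), n_rows, n_rows))
    for i, lag in enumerate(score_lags):
        if lag >= 0:
            x, y = a[:, : L - lag], b[:, lag:]
        else:
            x, y = a[:, -lag:], b[:, : L + lag]
        xz = x - x.mean(axis=1, keepdims=True)
        yz = y - y.mean(axis=1, keepdims=True)
        nx = np.sqrt((xz ** 2).sum(axis=1))
        ny = np.sqrt((yz ** 2).sum(axis=1))
        denom = np.outer(nx, ny)
        with np.errstate(invalid="ignore", divide="ignore"):
            pair_r[i] = np.where(denom > 0, (xz @ yz.T) / denom, 0.0)
    diag = np.arange(n_rows)
    score = float(pair_r[:, diag, diag].mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(n_rows)
        null[s] = pair_r[:, diag, perm].mean()
    mu, sd = float(null.mean()), float(null.std())
    z = (score - mu) / sd if sd > 0 else 0.0
    p = (1.0 + np.sum(np.abs(null - mu) >= abs(score - mu))) / (n_shuffles + 1.0)
    return XCorrResult(pair=pair, lags=lags, trace=trace, score=score,
                       z=z, mu_null=mu, sd_null=sd, p=float(p))
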
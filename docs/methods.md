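# Methods

## Setting

One "hemisphere" is an intraoperative recording from an 8-contact directional
DBS lead in the STN (two ring contacts flanking two levels of three 120°
segments; 2 mm between levels, segments 0.66 mm off-axis), with a forearm EMG
channel and auditory-cue annotations. Analyses run in a right-hemisphere
MNI-like coordinate frame (x lateral+, y anterior+, z superior+, mm);
left-sided leads are mirrored by negating x (`flip_to_right`; a user-supplied
affine can replace the rigid mirror — nonlinear warps are out of scope because
the imaging pipeline is not part of this package). Coordinates are assumed
already normalized. Hemispheres enter spatial analyses only when at least two
contacts lie inside the STN model.

## Preprocessing

Signals are polyphase-decimated to 800 Hz, LFPs high-passed at 0.5 Hz and
notch-filtered at 50 Hz harmonics, EMG high-passed at 10 Hz, mean-removed and
full-wave rectified. All filters are applied forward–backward (zero phase), so
event timing is not biased by group delay; a unit test asserts that a
symmetric pulse stays symmetric. The harmonic comb stops at 350 Hz: after
decimation to 800 Hz the 400 Hz harmonic sits exactly at Nyquist, where an IIR
notch is undefined.

EMG onsets are detected automatically (the original procedure this emulates
was manual): the 20 ms moving-average rectified EMG must exceed the
per-trial baseline mean + 3 SD for ≥ 50 ms; the onset is then backtracked to
the last crossing of the baseline mean, which removes the rise-time lag of the
k·SD criterion (mean |error| ≈ 10 ms on synthetic bursts at SNR ≥ 5). The
offset is the end of the descending phase, i.e. the first sustained
recrossing of the threshold. Trials without a qualifying burst are flagged.
Epochs span −3 s before onset to +2 s after offset; epochs clipped by the
recording edges are dropped and logged, so kept + dropped + flagged always
equals the attempted trial count. Artifact rejection is a conservative
automated proxy for visual inspection: a trial is excluded when any channel's
peak absolute amplitude exceeds a robust z of 5 against that channel's
across-trial median/MAD.

The pre-movement analysis window is taken literally as (−1.5, −0.2) s before
the cue (the nominal "1 s" label for this 1.3 s interval is not self-
consistent; the interval is configurable). The baseline (−3, −2) s precedes it
without overlap given the ~0.43 s cue-to-onset delay.

## Spectral estimation and ERS

Two multitaper configurations: 10–50 Hz with 400 ms windows, 10 ms steps and
±2 Hz half-bandwidth (2.5 Hz grid), and 50–395 Hz with 200 ms windows and
±10 Hz half-bandwidth (5 Hz grid). Taper count is K = ⌊2·TW⌋ − 1 floored at
one: the low range has TW = 0.8, for which no second standard Slepian exists,
so a single taper realizes the stated smoothing at periodogram-level variance
— a deliberate deviation documented here. PSD scaling is checked against a
Parseval identity on white noise (±5%).

Per contact and frequency bin, power is z-scored against baseline statistics
pooled over all kept trials of the hemisphere (pooling is the default; a
per-trial variant would be noisier at ~18 trials). Band z is the mean over
the band's bins: beta 13–30 (low range), HG 60–90, FG 110–140, SHFO 202–298,
FHFO 302–390 Hz (high range). Movement frames are linearly interpolated onto
the 21-point 0–100% grid; the grid is exactly duration-invariant for
shape-preserving time rescalings. AUC is the plain sum over the 21 grid
points (so constant z = 1 gives AUC = 21), not a trapezoid.

Summary timings use the trial-mean curve of the band's focus contact (argmax
of movement-mean z; argmin for beta, whose response is a trough). EMG peak
timing likewise comes from the trial-mean normalized rectified EMG — trial
means are less noisy than per-trial argmaxes at this trial count.
Cross-correlations are computed per trial (or per hemisphere) and averaged;
positive lag means the first series leads, one lag = one 5% bin. The lag-0
score (mean r within ±3 bins) is standardized against a null that shuffles
the pairing of the second series' units; the shuffle null is this package's
construction, chosen because a "standardized difference" needs an explicit
reference distribution.

## Hotspots, propagation, surrogates

Per band and state (or 100 ms rest/pre-movement epoch, or 5% movement bin),
each eligible hemisphere contributes its maximal-power inside contact (ties
break to the lowest contact id, logged); weights are the state-normalized
powers (cohort weights scaled to sum 1, so overall ERS scale cannot move the
hotspot). "Per axis" is read as three 1-D weighted Gaussian KDEs — matching
the per-axis density panels this mirrors — with an optional joint
product-kernel mode. Bandwidth is the weighted Silverman rule per axis,
floored at 0.3 mm (below the floor the 2 mm contact spacing dominates and the
rule collapses); the peak is located on a 0.05 mm grid spanning the data
range ± 3 bandwidths and always lies within the contributing coordinate
range. Degenerate cases: a single unique coordinate is returned directly; a
state whose selected powers are all ≤ 0 (possible for z-scored nulls) falls
back to uniform weights rather than failing.

Propagation is the per-axis difference and Euclidean distance between a bin's
hotspot and a reference hotspot (pre-movement by default, rest selectable).
Significance: 1000 surrogates re-select a uniformly random inside contact per
hemisphere, keeping the observed movement-state power as its weight (weights
fixed, positions randomized — the redraw-with-weights variant is left as an
open choice), recompute the KDE hotspot and its difference from the actual
pre-movement reference; a bin is significant when the observed value falls
outside the surrogate 2.5–97.5 percentile band, with Benjamini–Hochberg FDR
across movement bins per band and axis. Under an exchangeable-contact null
this test is calibrated: the observed selection is one more draw from the
surrogate law, so the two-tailed level is ~5% (≈5.4% at 200 draws due to
percentile interpolation; the acceptance script measures it empirically).

Volatility is the percentage of bin-to-bin transitions in which the
maximal-power inside contact changes identity — a pure argmax statistic,
invariant under strictly increasing power transforms; iid powers over 8
contacts give 100·(1 − 1/8) = 87.5% in expectation. Per-hemisphere
propagation (the clinical feature) is the displacement of the power-weighted
inside-contact centroid between states — centroids rather than single-contact
jumps, because an argmax jump is 0-or-2 mm quantized at the individual level.
The magnitude–propagation ratio divides grand-mean-normalized AUC by
grand-mean-normalized propagation per hemisphere × band and is compared
against 1 by signed-rank.

## Clinical stage

Features: 4 high-frequency bands × {ERS power, propagation} × 3 transitions
(rest→pre-movement, rest→movement, pre-movement→movement) = 24 columns per
hemisphere; targets are the OFF MDS-UPDRS III score and % levodopa
improvement. Spearman correlations carry percentile-bootstrap 95% CIs (5000
paired resamples) and per-target FDR. LSBoost is stagewise least-squares
gradient boosting of depth-2 regression trees (scikit-learn's
GradientBoostingRegressor behind the module surface); hyperparameters are
searched over learn rate {0.3, 0.45, 0.6} × cycles {30, 75, 120, 200} —
spanning the printed (0.3, 0.6) and (30, 200) ranges at desk cost — by inner
3-fold CV *within each LOOCV training fold*, so the held-out row never
informs its own prediction (verified by a poisoning test). Importance is the
tree-ensemble split-gain (squared-error reduction) measure, normalized to sum
1; p-values come from 1000 refits on shuffled targets; top-rank probabilities
are the fraction of 100 bootstrap/seed refits in which a feature (or its
band / feature-type / transition group) ranks first, and sum to 1 over any
group partition. The repeated-measures ANOVA is the within-subject two-way
decomposition with subject blocking (no sphericity correction; cross-checked
against pingouin in the tests) with Tukey HSD on the RM error term.

## Synthetic cohort

Each contact's LFP is a sum over band sources of
`gain(contact, center(t)) · envelope(t) · carrier(t)` plus 1/f noise and
optional 50 Hz line. Carriers are white noise band-passed with a zero-phase
FIR (≥95% of power in-band) — high-frequency STN activity is broadband, not
sinusoidal. Spatial gain is `exp(−‖pos − center‖²/(2σ²))` with σ = 2 mm,
comparable to the 6 mm contact span. Envelopes are symmetric raised-cosine
bumps peaking at a configurable fraction of each movement; symmetry makes the
planted peak recoverable without bias under the symmetric multitaper window.
The beta source has polarity −1 (an amplitude dip troughing at 14% of the
movement); HG/FG/SHFO/FHFO peak at 44/48/44/43% with movement drifts of
(0, 0, +1.18)/(0, 0, +0.84)/(0, 0, −0.30)/(0, 0, 0) mm, linearly interpolated
across the movement and scaled per hemisphere and band by independent
uniform(0.25, 1.75) factors so per-hemisphere propagation varies. Source
bumps use a 0.35 half-width (of the movement): a planted peak fraction is
only recoverable to one 5% bin if the envelope has curvature at that scale,
and the default half-width min(p, 1 − p) leaves the near-50% peaks too flat
to localize. The EMG burst peaks at 29% of the movement but spans all of it
— a locally symmetric raised-cosine peak over a 0.3-height trapezoidal
plateau with sharp edge ramps — because its rising/descending phases
*define* onset and offset; it is generated signed so the rectification path
is exercised. Protocol parameters:
2048 Hz acquisition, 93 s rest, 18 trials (20 attempted when emulating a 10%
artifact rate, giving ≈18 kept — matching the reference 17.93 ± 4.7), cue→
onset delay 0.43 ± 0.18 s, movement duration 1.54 ± 0.59 s, 8 s intertrial
interval (the alternative 9.0 ± 2.67 s reading is configurable). Clinical
scores are linear in the planted per-hemisphere propagation plus Gaussian
noise, clipped to their scales — linear by design so boosting-stage recovery
is interpretable.

What the generator does not emulate: volume conduction and common-reference
correlations between contacts, nonstationary tremor/artifact regimes, phase–
amplitude coupling, microlesion drift over the session, or realistic UPDRS
item structure. Passing tests therefore demonstrate correctness of the
estimators under the planted model, not clinical validity on patient data.

## Validation experiments and problem sizes

`stnspot.validate` runs the statistical experiments at the spatial stage
(lead geometry + per-contact powers), which is the stage those statistics
consume; the full signal path is validated end-to-end separately on an
8-hemisphere, 18-trial cohort. Sizes used by the test suite and acceptance
script, chosen to keep replicate counts high where Monte-Carlo error matters:

- surrogate calibration: 400 null cohorts × 30 hemispheres × 200 surrogates
  (expected two-tailed level ≈ 5%);
- hotspot recovery: 20 cohorts × 63 hemispheres (center within 0.5 mm/axis;
  a planted (0, 0, +1.18) mm shift recovered within 0.4 mm — residual
  shrinkage reflects the 2 mm contact quantization);
- clinical recovery: 50 cohorts × 63 hemispheres with per-band planted drifts
  and coefficient −14 %/mm, noise SD 3 — yielding a measured marginal
  Spearman ρ ≈ −0.43 per band, the planted effect scale;
- type-I calibration of the cross-correlation score, signed-rank and
  RM-ANOVA at 1000 null runs each.

## Known limitations

Single-taper estimation below 50 Hz (see above); the surrogate's
keep-weights choice and the power-before-KDE state hotspot are flagged open
alternatives; per-hemisphere propagation has no reference definition at the
individual level, so the centroid construction here is this package's own;
Greenhouse–Geisser correction is not applied; EDF export is not provided
(the bundle uses compressed TSV signals).
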
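# stnspot

Spatiotemporal analysis of movement-related subthalamic nucleus (STN) local
field potentials, built for intraoperative DBS-lead recordings in Parkinson's
disease and for methodologists who want a tested, fully synthetic benchmark of
the whole analysis chain.

During voluntary movement the STN shows broadband high-frequency
synchronization — high-gamma (HG, 60–90 Hz), fast-gamma (FG, 110–140 Hz) and
high-frequency oscillations (SHFO 202–298 Hz, FHFO 302–390 Hz) — alongside the
classic beta (13–30 Hz) desynchronization. `stnspot` quantifies both *when*
and *where* this activity evolves:

- **ERS/ERD**: multitaper spectrograms (DPSS tapers; 400 ms windows / ±2 Hz
  smoothing below 50 Hz, 200 ms / ±10 Hz above) are z-scored against a
  pre-movement baseline (−3 to −2 s before EMG onset),
  `z = (P − μ_base)/σ_base`, and movement trials are resampled onto a 0–100%
  grid in 5% bins so trials of different durations average cleanly.
- **Hotspots**: per hemisphere the inside-STN contact with the highest band
  power is selected; across the cohort a power-weighted Gaussian kernel
  density over the selected contacts' MNI-like coordinates is peaked per axis.
- **Propagation**: the hotspot displacement (mm) between behavioural states or
  5% movement bins, tested against a surrogate null built from 1000
  random-contact hotspots (two-tailed 5% critical values, FDR over bins), plus
  per-hemisphere weighted-centroid propagation, hotspot volatility and a
  magnitude–propagation ratio.
- **Clinical inference**: band × {ERS power, propagation} × state-transition
  features are related to MDS-UPDRS III scores by Spearman correlation
  (5000-resample bootstrap CIs) and ranked with least-squares boosting
  (LSBoost, leave-one-out cross-validation, 1000-shuffle importance nulls).

Because the underlying patient recordings are not publicly available, the
package ships a first-class synthetic-cohort generator (`stnspot.synthcohort`)
that plants known source centers, envelope timings, hotspot drifts and
clinical coefficients — every downstream stage is validated against this
ground truth.

## Worked example

```bash
stnspot simulate --seed 1 --out cohort/
stnspot all --seed 1 --bundle cohort/ --out results/
```

or, scripted on a small cohort:

```python
import dataclasses
from stnspot import SynthConfig, simulate_cohort, simulate_clinical_scores
from stnspot.pipeline import RunConfig, analyze_cohort

cfg = RunConfig(seed=1)
cfg.synth = dataclasses.replace(cfg.synth, n_hemispheres=8, n_trials=18,
                                rest_dur_s=20.0, fs_raw=800.0, rng_seed=11)
cfg.n_surrogates = 200
recs, gts, stn = simulate_cohort(cfg.synth)
clinical = simulate_clinical_scores(gts, {"FG": -14.0}, 3.0, seed=2)
tables = analyze_cohort(recs, cfg, clinical)
print(tables["ers_summary"].groupby("band")[["peak_frac", "emg_peak_frac",
                                             "delta_ers_emg"]].mean())
```

prints (seed 1, 8 hemispheres):

```
      peak_frac  emg_peak_frac  delta_ers_emg
band
FG       52.500         30.625         21.875
FHFO     41.875         30.625         11.250
HG       46.875         30.625         16.250
SHFO     44.375         30.625         13.750
beta     19.375         30.625        -11.250
```

Reading: the rectified EMG peaks at ~30% of the movement and the
high-frequency ERS peaks follow at 42–53% (the generator plants 29% and
44/48/44/43%; at 8 hemispheres the per-hemisphere argmax means carry a bin
or two of noise); for beta the `peak_frac` column holds its
desynchronization trough, planted at 14%. `tables["propagation"]` holds the
per-bin hotspot displacement with surrogate significance flags — under the
default conditions the HG hotspot drifts superiorly (planted +1.18 mm scaled
per hemisphere) from pre-movement to movement.

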
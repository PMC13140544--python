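"""End-to-end orchestration: simulate -> preprocess -> ERS -> hotspots -> clinical.

Every stage is deterministic under the master seed; per-stage seeds are
derived by fixed offsets so stages can be rerun independently. All outputs
are TSV tables with a JSON metadata sidecar (config hash, seed, version).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinstats, hotspot as hs, preprocess as pp, spectral as sp
from .dataio import (STNModel, default_stn_model, read_bundle, read_clinical,
                     write_clinical, write_results)
from .synthcohort import (SynthConfig, SourceSpec, default_sources,
                          simulate_clinical_scores, simulate_cohort)

log = logging.getLogger("stnspot")

# seed offsets per stage (counter-based, so stages rerun independently)
_SEED_SYNTH, _SEED_CLIN, _SEED_SURR, _SEED_STATS, _SEED_BOOST = 0, 1, 2, 3, 4


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    synth: SynthConfig = dataclasses.field(default_factory=SynthConfig)
    preproc: pp.PreprocConfig = dataclasses.field(default_factory=pp.PreprocConfig)
    spectral: sp.SpectralConfig = dataclasses.field(default_factory=sp.SpectralConfig)
    kde_bw_floor_mm: float = 0.3
    kde_grid_step_mm: float = 0.05
    n_surrogates: int = 1000
    stats: clinstats.StatsConfig = dataclasses.field(default_factory=clinstats.StatsConfig)
    boost: clinstats.BoostConfig = dataclasses.field(default_factory=clinstats.BoostConfig)
    run_boost: bool = True
    clinical_coeffs: dict = dataclasses.field(
        default_factory=lambda: {"FG": -18.0, "SHFO": -12.0, "FHFO": -12.0})
    clinical_noise_sd: float = 12.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synth"] = self.synth.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if "synth" in raw:
            s = dict(raw["synth"])
            if "sources" in s:
                s["sources"] = [SourceSpec(**src) for src in s["sources"]]
            cfg.synth = SynthConfig(**s)
        if "preproc" in raw:
            cfg.preproc = pp.PreprocConfig(**raw["preproc"])
        for key in ("kde_bw_floor_mm", "kde_grid_step_mm", "n_surrogates",
                    "run_boost", "clinical_noise_sd"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "clinical_coeffs" in raw:
            cfg.clinical_coeffs = dict(raw["clinical_coeffs"])
        if "stats" in raw:
            cfg.stats = clinstats.StatsConfig(**raw["stats"])
        if "boost" in raw:
            b = raw["boost"]
            for k in ("learn_rates", "n_cycles_grid"):
                if k in b:
                    b[k] = tuple(b[k])
            cfg.boost = clinstats.BoostConfig(**b)
        return cfg


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: RunConfig, out_dir) -> Path:
    """Simulate the cohort and clinical scores; write the bundle layout."""
    synth = dataclasses.replace(cfg.synth, rng_seed=cfg.seed + _SEED_SYNTH)
    recs, gts, stn = simulate_cohort(synth, out_dir=out_dir)
    clin = simulate_clinical_scores(
        gts, cfg.clinical_coeffs, cfg.clinical_noise_sd, seed=cfg.seed + _SEED_CLIN
    )
    write_clinical(clin, out_dir)
    log.info("simulated %d hemispheres into %s", len(recs), out_dir)
    return Path(out_dir)


def load_cohort(bundle_dir) -> list:
    """Read every hemisphere bundle under ``bundle_dir`` (sorted by id)."""
    root = Path(bundle_dir)
    hemis = sorted(p for p in root.iterdir() if (p / "recording.json").exists())
    if not hemis:
        raise FileNotFoundError(f"no hemisphere bundles under {root}")
    return [read_bundle(p) for p in hemis]


def process_hemisphere(rec, cfg: RunConfig):
    """Preprocess + ERS for one hemisphere; returns (tensor, spatial_view, n_kept)."""
    kept, cond, rej = pp.preprocess_recording(rec, cfg.preproc)
    first_cue = cond.events.cue_time_s[0]
    r1 = max(int((first_cue - 5.0) * cond.fs), int(2.0 * cond.fs))
    rest_lfp = cond.lfp[:, int(1.0 * cond.fs): r1]
    tensor = sp.compute_ers(kept, cfg.spectral, rest_lfp=rest_lfp, fs=cond.fs)
    view = hs.spatial_view(tensor, rec.contacts)
    return tensor, view, len(kept), rej


def analyze_cohort(recs: list, cfg: RunConfig, clinical: list | None = None) -> dict:
    """Run the full analysis on in-memory recordings; returns result tables."""
    tensors, views, summaries, rejections = [], [], [], []
    for rec in recs:
        tensor, view, n_kept, rej = process_hemisphere(rec, cfg)
        tensors.append(tensor)
        views.append(view)
        summaries.append(sp.summarize_ers(tensor, cfg.spectral))
        if len(rej):
            rejections.append(rej)
        log.info("%s: %d kept trials", rec.hemisphere_id, n_kept)
    summary = pd.concat(summaries, ignore_index=True)
    eligible = [v for v in views if v.inside.sum() >= 2]

    hot_rows, prop_frames, vol_rows, prop_hemi_rows = [], [], [], []
    bands = [b for b in tensors[0].bands if b != "beta"]
    for band in bands:
        tc = hs.hotspot_timecourse(eligible, band,
                                   bw_floor_mm=cfg.kde_bw_floor_mm,
                                   grid_step_mm=cfg.kde_grid_step_mm)
        for state, h in tc["state"].items():
            hot_rows.append({"band": band, "state": state,
                             "x": h.coords[0], "y": h.coords[1], "z": h.coords[2],
                             "n_hemispheres": h.n_hemispheres})
        ref = tc["state"]["premove"]
        move_bins = tc["bins"]["move"]
        prop = hs.propagation(move_bins, ref)
        obs = prop[["dx", "dy", "dz"]].to_numpy()
        pts = [v.positions for v in eligible]
        ins = [v.inside for v in eligible]
        _, wts = hs._select_points_weights(eligible, band, "move")
        null = hs.surrogate_propagation_null(
            pts, ins, wts, ref.coords, n_draws=cfg.n_surrogates,
            seed=cfg.seed + _SEED_SURR, band=band,
            bw_floor_mm=cfg.kde_bw_floor_mm, grid_step_mm=cfg.kde_grid_step_mm)
        sig = hs.surrogate_test(obs, null)
        sig["band"] = band
        prop["band"] = band
        prop_frames.append((prop, sig))
        for v in eligible:
            for state in ("rest", "premove", "move"):
                try:
                    vol = hs.volatility(v.bin_power[state][band], v.inside)
                except ValueError:
                    continue
                vol_rows.append({"hemisphere_id": v.hemisphere_id, "band": band,
                                 "state": state, "volatility_pct": vol})
            for a, b2 in clinstats.TRANSITIONS:
                d = hs.per_hemisphere_propagation(
                    v.positions, v.inside,
                    v.state_power[a][band], v.state_power[b2][band])
                prop_hemi_rows.append({"hemisphere_id": v.hemisphere_id,
                                       "band": band, "transition": f"{a}-{b2}",
                                       **d})
    hotspots = pd.DataFrame(hot_rows)
    prop_table = pd.concat([p for p, _ in prop_frames], ignore_index=True)
    sig_table = pd.concat([s for _, s in prop_frames], ignore_index=True)
    vol_table = pd.DataFrame(vol_rows)
    prop_hemi = pd.DataFrame(prop_hemi_rows)

    pm = prop_hemi[prop_hemi["transition"] == "premove-move"][
        ["hemisphere_id", "band", "euclid"]]
    ratio = hs.magnitude_propagation_ratio(
        summary[summary["band"] != "beta"][["hemisphere_id", "band", "auc_total"]], pm)
    try:
        battery = clinstats.comparison_battery(summary, ratio, cfg.stats)
    except ValueError as e:
        log.warning("comparison battery skipped: %s", e)
        battery = pd.DataFrame()

    tables = {
        "ers_summary": summary,
        "hotspots": hotspots,
        "propagation": prop_table,
        "propagation_significance": sig_table,
        "volatility": vol_table,
        "per_hemisphere_propagation": prop_hemi,
        "magnitude_propagation_ratio": ratio,
        "comparison_battery": battery,
    }
    if rejections:
        tables["rejection_log"] = pd.concat(rejections, ignore_index=True)

    if clinical is not None:
        elig_clin = [c for v, c in zip(views, clinical) if v.inside.sum() >= 2]
        features = clinstats.build_feature_matrix(eligible, elig_clin)
        tables["feature_matrix"] = features
        if len(features) >= 5:
            tables["correlations"] = clinstats.correlation_grid(
                features, cfg=cfg.stats, seed=cfg.seed + _SEED_STATS)
        if cfg.run_boost and len(features) >= 10:
            cols = clinstats.feature_columns(features)
            X = features[cols].to_numpy(float)
            boost_rows = []
            for tgt in ("updrs3_off", "pct_improvement"):
                rep = clinstats.loocv_evaluate(
                    X, features[tgt].to_numpy(float),
                    dataclasses.replace(cfg.boost, seed=cfg.seed + _SEED_BOOST),
                    feature_names=cols)
                for f, imp in zip(rep.feature_names, rep.importance):
                    boost_rows.append({"target": tgt, "feature": f,
                                       "importance": imp,
                                       "pearson_r": rep.pearson_r,
                                       "rmse": rep.rmse})
            tables["boost_report"] = pd.DataFrame(boost_rows)
    return tables


def run_all(cfg: RunConfig, bundle_dir, out_dir) -> Path:
    """Load a bundle directory, run the full analysis, write result tables."""
    recs = load_cohort(bundle_dir)
    try:
        clinical = read_clinical(bundle_dir)
    except FileNotFoundError:
        clinical = None
    except Exception:
        clinical = None
    tables = analyze_cohort(recs, cfg, clinical)
    write_results(tables, out_dir, config=cfg.to_dict(), seed=cfg.seed)
    log.info("wrote %d tables to %s", len(tables), out_dir)
    return Path(out_dir)
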
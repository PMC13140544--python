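"""Clinico-electrophysiological inference.

Hemisphere-level features — sub-band ERS magnitude and spatial propagation
across the three motor-state transitions (rest->pre-movement, rest->movement,
pre-movement->movement) — are related to MDS-UPDRS III motor scores with
Spearman correlations (95% CI by 5000-resample bootstrap, FDR-corrected) and
ranked by importance in least-squares boosting (LSBoost) models evaluated
with leave-one-out cross-validation; feature importance is tested against a
1000-refit shuffled-target null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .hotspot import per_hemisphere_propagation

HF_BANDS = ("HG", "FG", "SHFO", "FHFO")
TRANSITIONS = (("rest", "premove"), ("rest", "move"), ("premove", "move"))
FEATURE_TYPES = ("ers_power", "propagation")


@dataclass
class StatsConfig:
    n_bootstrap: int = 5000
    ci_level: float = 0.95
    alpha: float = 0.05
    fdr_method: str = "fdr_bh"


@dataclass
class BoostConfig:
    learn_rates: tuple = (0.3, 0.45, 0.6)          # spans the (0.3, 0.6) range
    n_cycles_grid: tuple = (30, 75, 120, 200)      # spans the (30, 200) range
    max_depth: int = 2
    inner_cv_folds: int = 3
    n_permutations: int = 1000
    n_rank_replicates: int = 100
    seed: int = 0


@dataclass
class BoostReport:
    predictions: np.ndarray
    actual: np.ndarray
    pearson_r: float
    rmse: float
    importance: np.ndarray            # mean over folds, sums to ~1
    feature_names: list
    fold_params: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------

def feature_name(band: str, ftype: str, transition: tuple) -> str:
    return f"{band}_{ftype}_{transition[0]}-{transition[1]}"


def build_feature_matrix(cohort: list, clinical: list) -> pd.DataFrame:
    """24 features per hemisphere: 4 bands x {ers_power, propagation} x 3 transitions.

    ``cohort`` is a list of HemisphereSpatial (hotspot.spatial_view output),
    ``clinical`` a list of ClinicalRecord aligned one-to-one with it. The
    ers_power feature is the transition difference of the inside-contact mean
    band z; the propagation feature is the Euclidean displacement of the
    power-weighted inside-contact centroid between the two states.
    """
    if len(cohort) != len(clinical):
        raise ValueError(
            f"{len(cohort)} hemispheres but {len(clinical)} clinical records"
        )
    rows = []
    for h, cl in zip(cohort, clinical):
        inside = np.asarray(h.inside, bool)
        row = {"hemisphere_id": h.hemisphere_id, "patient_id": cl.patient_id}
        for band in HF_BANDS:
            for a, b in TRANSITIONS:
                pa, pb = h.state_power[a][band], h.state_power[b][band]
                row[feature_name(band, "ers_power", (a, b))] = float(
                    pb[inside].mean() - pa[inside].mean()
                )
                prop = per_hemisphere_propagation(h.positions, inside, pa, pb)
                row[feature_name(band, "propagation", (a, b))] = prop["euclid"]
        row["updrs3_off"] = cl.updrs3_off
        row["pct_improvement"] = cl.pct_improvement
        rows.append(row)
    return pd.DataFrame(rows)


def feature_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns
            if any(c.startswith(f"{b}_") for b in HF_BANDS)]


# ---------------------------------------------------------------------------
# Spearman with bootstrap CI
# ---------------------------------------------------------------------------

def _spearman_rows(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho via Pearson on ranks (tie-safe, vectorized)."""
    rx = stats.rankdata(xs, axis=1)
    ry = stats.rankdata(ys, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (rx * ry).sum(axis=1) / denom, np.nan)


def spearman_bootstrap(x, y, cfg: StatsConfig | None = None, seed: int = 0):
    """Spearman rho with p-value and percentile-bootstrap CI over paired resamples.

    Returns ``(rho, p, (ci_lo, ci_hi))``.
    """
    cfg = cfg or StatsConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("ties-only input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(cfg.n_bootstrap, x.size))
    boots = _spearman_rows(x[idx], y[idx])
    boots = boots[np.isfinite(boots)]
    a = (1 - cfg.ci_level) / 2
    ci = (float(np.percentile(boots, 100 * a)),
          float(np.percentile(boots, 100 * (1 - a))))
    return float(rho), float(p), ci


def correlation_grid(features: pd.DataFrame, targets=("updrs3_off", "pct_improvement"),
                     cfg: StatsConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Spearman/bootstrap over every feature x clinical-target pair, FDR per target."""
    cfg = cfg or StatsConfig()
    cols = feature_columns(features)
    rows = []
    for k, tgt in enumerate(targets):
        for j, c in enumerate(cols):
            rho, p, ci = spearman_bootstrap(
                features[c], features[tgt], cfg, seed=seed + 1000 * k + j
            )
            rows.append({"target": tgt, "feature": c, "rho": rho, "p": p,
                         "ci_lo": ci[0], "ci_hi": ci[1]})
    df = pd.DataFrame(rows)
    df["p_fdr"] = np.nan
    for tgt in df["target"].unique():
        m = df["target"] == tgt
        _, adj, _, _ = multipletests(df.loc[m, "p"], alpha=cfg.alpha, method=cfg.fdr_method)
        df.loc[m, "p_fdr"] = adj
    return df


# ---------------------------------------------------------------------------
# LSBoost
# ---------------------------------------------------------------------------

def lsboost_fit(X, y, learn_rate: float = 0.45, n_cycles: int = 120,
                depth: int = 2, seed: int = 0) -> GradientBoostingRegressor:
    """Stagewise least-squares gradient boosting of depth-limited trees.

    F0 = mean(y); each cycle fits a regression tree to the residuals and adds
    its prediction shrunk by ``learn_rate``, so training MSE is non-increasing
    in the number of cycles.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    model = GradientBoostingRegressor(
        loss="squared_error", learning_rate=learn_rate, n_estimators=n_cycles,
        max_depth=depth, random_state=seed,
    )
    model.fit(X, y)
    return model


def _inner_select(X, y, cfg: BoostConfig, seed: int):
    """Grid search (learn_rate x n_cycles) by inner K-fold MSE on the training fold."""
    n = len(y)
    folds = min(cfg.inner_cv_folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best, best_mse = None, np.inf
    splits = list(kf.split(X))
    for lr in cfg.learn_rates:
        for nc in cfg.n_cycles_grid:
            errs = []
            for tr, te in splits:
                m = lsboost_fit(X[tr], y[tr], lr, nc, cfg.max_depth, seed)
                errs.append(np.mean((m.predict(X[te]) - y[te]) ** 2))
            mse = float(np.mean(errs))
            if mse < best_mse:
                best_mse, best = mse, (lr, nc)
    return best


def loocv_evaluate(X, y, cfg: BoostConfig | None = None,
                   feature_names: list | None = None) -> BoostReport:
    """Leave-one-out evaluation with per-fold hyperparameter selection.

    Hyperparameters are re-optimized on each training fold (inner K-fold grid
    search over the configured ranges), so the held-out row never informs its
    own prediction. Reports Pearson r and RMSE over the held-out predictions
    and the fold-mean feature importance.
    """
    cfg = cfg or BoostConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    if n < 10:
        raise ValueError("need >= 10 rows for LOOCV")
    preds = np.empty(n)
    importances = np.zeros((n, X.shape[1]))
    fold_params = []
    for i in range(n):
        tr = np.r_[0:i, i + 1:n]
        lr, nc = _inner_select(X[tr], y[tr], cfg, seed=cfg.seed + i)
        model = lsboost_fit(X[tr], y[tr], lr, nc, cfg.max_depth, cfg.seed + i)
        preds[i] = model.predict(X[i][None, :])[0]
        importances[i] = model.feature_importances_
        fold_params.append((lr, nc))
    r = float(np.corrcoef(preds, y)[0, 1]) if np.std(preds) > 0 else 0.0
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    return BoostReport(
        predictions=preds, actual=y.copy(), pearson_r=r, rmse=rmse,
        importance=importances.mean(axis=0),
        feature_names=list(feature_names) if feature_names is not None
        else [f"f{j}" for j in range(X.shape[1])],
        fold_params=fold_params,
    )


def importance_permutation_test(X, y, cfg: BoostConfig | None = None,
                                feature_names: list | None = None):
    """Observed feature importance vs a shuffled-target null, plus top-rank probabilities.

    The null refits the model ``n_permutations`` times on permuted y; per
    feature, p = fraction of null importances >= observed (FDR-corrected
    across features). Top-rank probabilities are estimated over
    ``n_rank_replicates`` bootstrap/seed refits: the fraction of replicates in
    which each feature (and each band / feature-type / transition group, via
    its member features) holds the highest importance; over any group
    partition the probabilities sum to 1.
    """
    cfg = cfg or BoostConfig()
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    names = (list(feature_names) if feature_names is not None
             else [f"f{j}" for j in range(X.shape[1])])
    lr = cfg.learn_rates[len(cfg.learn_rates) // 2]
    nc = cfg.n_cycles_grid[len(cfg.n_cycles_grid) // 2]
    obs = lsboost_fit(X, y, lr, nc, cfg.max_depth, cfg.seed).feature_importances_

    rng = np.random.default_rng(cfg.seed)
    null = np.empty((cfg.n_permutations, X.shape[1]))
    for s in range(cfg.n_permutations):
        null[s] = lsboost_fit(X, rng.permutation(y), lr, nc, cfg.max_depth,
                              cfg.seed + 1 + s).feature_importances_
    p = (1.0 + (null >= obs[None, :]).sum(axis=0)) / (cfg.n_permutations + 1.0)
    _, p_fdr, _, _ = multipletests(p, method="fdr_bh")

    top_counts = np.zeros(X.shape[1])
    n = len(y)
    for rsd in range(cfg.n_rank_replicates):
        idx = rng.integers(0, n, n)
        imp = lsboost_fit(X[idx], y[idx], lr, nc, cfg.max_depth,
                          cfg.seed + 10_000 + rsd).feature_importances_
        top_counts[np.argmax(imp)] += 1
    top_prob = top_counts / cfg.n_rank_replicates

    per_feature = pd.DataFrame({
        "feature": names, "importance": obs, "p": p, "p_fdr": p_fdr,
        "top_rank_prob": top_prob,
    })
    groups = {}
    for gname, keyfun in (
        ("band", lambda f: f.split("_")[0]),
        ("feature_type", lambda f: f.split("_")[1] if "_" in f else f),
        ("transition", lambda f: f.split("_")[-1]),
    ):
        agg = {}
        for f, tp in zip(names, top_prob):
            agg[keyfun(f)] = agg.get(keyfun(f), 0.0) + tp
        groups[gname] = agg
    return per_feature, groups


# ---------------------------------------------------------------------------
# Comparison battery
# ---------------------------------------------------------------------------

def rm_anova(data: np.ndarray):
    """One-way repeated-measures ANOVA (subjects x conditions).

    Within-subject decomposition with subject blocking; returns
    ``(F, df_cond, df_error, p)``. No sphericity correction is applied.
    """
    d = np.asarray(data, float)
    n, k = d.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    grand = d.mean()
    ss_cond = n * np.sum((d.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((d.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((d - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    ms_c, ms_e = ss_cond / df_c, ss_err / df_e
    F = ms_c / ms_e if ms_e > 0 else np.inf
    return float(F), df_c, df_e, float(stats.f.sf(F, df_c, df_e))


def tukey_posthoc(data: np.ndarray, labels: list) -> pd.DataFrame:
    """Tukey HSD on condition means using the RM-ANOVA error term."""
    d = np.asarray(data, float)
    n, k = d.shape
    _, _, df_e, _ = rm_anova(d)
    grand = d.mean()
    ss_cond = n * np.sum((d.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((d.mean(axis=1) - grand) ** 2)
    ms_e = (np.sum((d - grand) ** 2) - ss_cond - ss_subj) / df_e
    se = np.sqrt(ms_e / n)
    means = d.mean(axis=0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / se if se > 0 else np.inf
            rows.append({
                "a": labels[i], "b": labels[j],
                "mean_diff": means[i] - means[j],
                "q": q, "p": float(studentized_range.sf(q, k, df_e)),
            })
    return pd.DataFrame(rows)


def comparison_battery(summaries: pd.DataFrame, ratio: pd.DataFrame | None = None,
                       cfg: StatsConfig | None = None) -> pd.DataFrame:
    """The omnibus/paired test battery over per-hemisphere band summaries.

    - repeated-measures ANOVA across sub-bands on ERS AUC, with Tukey post hoc
    - paired Wilcoxon signed-rank per band on the ERS-vs-EMG peak delta and
      the ERS-vs-beta-trough delta (against 0)
    - signed-rank per band on the magnitude-propagation ratio (against 1)

    All p-values are FDR-corrected together; effect directions are reported.
    ``summaries`` is the concatenated summarize_ers output (high bands only
    are used for the ANOVA).
    """
    cfg = cfg or StatsConfig()
    rows = []
    hf = summaries[summaries["band"] != "beta"]
    wide = hf.pivot(index="hemisphere_id", columns="band", values="auc_total")
    wide = wide.dropna()
    if len(wide) < 3:
        raise ValueError("need >= 3 hemispheres")
    labels = list(wide.columns)
    F, df_c, df_e, p = rm_anova(wide.to_numpy())
    rows.append({"test": "rm_anova_auc", "contrast": "bands", "stat": F, "p": p,
                 "direction": ""})
    for _, r in tukey_posthoc(wide.to_numpy(), labels).iterrows():
        rows.append({"test": "tukey_auc", "contrast": f"{r['a']}-{r['b']}",
                     "stat": r["q"], "p": r["p"],
                     "direction": ">" if r["mean_diff"] > 0 else "<"})
    for col, ref, name in (("delta_ers_emg", 0.0, "signed_rank_ers_vs_emg"),
                           ("delta_ers_erd", 0.0, "signed_rank_ers_vs_erd")):
        for band in labels:
            vals = hf.loc[hf["band"] == band, col].to_numpy(float) - ref
            vals = vals[np.isfinite(vals)]
            if np.allclose(vals, 0) or vals.size < 5:
                continue
            stat, p = stats.wilcoxon(vals)
            rows.append({"test": name, "contrast": band, "stat": float(stat),
                         "p": float(p),
                         "direction": ">" if np.median(vals) > 0 else "<"})
    if ratio is not None:
        for band in ratio["band"].unique():
            vals = ratio.loc[ratio["band"] == band, "ratio"].to_numpy(float) - 1.0
            vals = vals[np.isfinite(vals)]
            if vals.size >= 5 and not np.allclose(vals, 0):
                stat, p = stats.wilcoxon(vals)
                rows.append({"test": "signed_rank_ratio_vs_1", "contrast": band,
                             "stat": float(stat), "p": float(p),
                             "direction": ">" if np.median(vals) > 0 else "<"})
    df = pd.DataFrame(rows)
    rej, p_adj, _, _ = multipletests(df["p"], alpha=cfg.alpha, method=cfg.fdr_method)
    df["p_fdr"] = p_adj
    df["significant"] = rej
    return df
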
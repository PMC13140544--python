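import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from stnspot.dataio import ContactRecord, default_stn_model
from stnspot.hotspot import (Hotspot, classify_contacts, eligible,
                             magnitude_propagation_ratio,
                             per_hemisphere_propagation, propagation,
                             select_max_contact, surrogate_propagation_null,
                             surrogate_test, volatility, weighted_kde_hotspot)
from stnspot.synthcohort import make_lead_geometry, simulate_contact_powers
from stnspot.validate import _observed_propagation, _spatial_cohort


# -- containment ------------------------------------------------------------

def test_centroid_inside_far_point_outside():
    stn = default_stn_model()
    contacts = [ContactRecord(0, stn.center), ContactRecord(1, stn.center + 50.0)]
    out = classify_contacts(contacts, stn)
    assert out[0].inside_stn and out[0].subregion != "outside"
    assert not out[1].inside_stn and out[1].subregion == "outside"
    assert not eligible(out)


def test_mesh_containment_matches_analytic_ellipsoid(rng):
    trimesh = pytest.importorskip("trimesh")
    pytest.importorskip("rtree")  # trimesh containment backend
    stn = default_stn_model()
    mesh = trimesh.creation.icosphere(subdivisions=4)
    mesh.apply_scale(stn.semi_axes)
    mesh.apply_translation(stn.center)
    pts = stn.center + rng.uniform(-5, 5, size=(2000, 3))
    analytic = stn.contains(pts)
    q = np.abs(np.linalg.norm((pts - stn.center) / stn.semi_axes, axis=1) - 1.0)
    keep = q > 0.02  # skip points within mesh-facet tolerance of the surface
    np.testing.assert_array_equal(mesh.contains(pts[keep]), analytic[keep])


# -- selection --------------------------------------------------------------

def test_select_max_contact_respects_inside_and_ties():
    powers = np.array([9.0, 1.0, 5.0, 5.0, 2.0, 0.0, 0.0, 0.0])
    inside = np.array([0, 1, 1, 1, 1, 0, 0, 0], bool)
    assert select_max_contact(powers, inside) == 2      # 9.0 is outside; tie -> lowest id
    assert select_max_contact(np.ones(8), inside) == 1  # uniform -> first inside
    mono = np.log1p(powers)  # strictly increasing transform
    assert select_max_contact(mono, inside) == 2
    with pytest.raises(ValueError, match="no contacts inside"):
        select_max_contact(powers, np.zeros(8, bool))


# -- weighted KDE -----------------------------------------------------------

def test_all_weight_on_one_point_returns_it():
    pts = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    h = weighted_kde_hotspot(pts, np.array([1.0, 0.0]))
    np.testing.assert_allclose(h.coords, pts[0], atol=0.06)


def _brute_force_peak(x, w, bw, step=1e-3):
    grid = np.arange(x.min() - 3 * bw, x.max() + 3 * bw, step)
    dens = (np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2) * w).sum(axis=1)
    return grid[np.argmax(dens)]


def test_kde_peak_matches_brute_force_mixture():
    from stnspot.hotspot import _kde_peak_1d, _silverman_bw
    cases = [
        (np.array([0.0, 4.0]), np.array([2.0, 1.0])),
        (np.array([0.0, 1.0, 2.5]), np.array([1.0, 1.0, 3.0])),
        (np.array([-2.0, 0.0, 0.4, 3.0, 3.2]), np.array([0.5, 1.0, 1.0, 2.0, 0.1])),
    ]
    for x, w in cases:
        bw = _silverman_bw(x, w, 0.3)
        peak, _, _ = _kde_peak_1d(x, w, 0.3, 0.05)
        assert abs(peak - _brute_force_peak(x, w, bw)) <= 0.05 / 2 + 1e-2


@given(st.integers(0, 10_000))
@settings(deadline=None, max_examples=30, derandomize=True)
def test_kde_peak_contained_in_data_range(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 12)
    pts = rng.uniform(-10, 10, size=(n, 3))
    w = rng.uniform(0.0, 1.0, n)
    w[rng.integers(n)] = 1.0  # ensure not all zero
    h = weighted_kde_hotspot(pts, w)
    for ax in range(3):
        assert pts[:, ax].min() - 1e-9 <= h.coords[ax] <= pts[:, ax].max() + 1e-9


def test_kde_weight_validation():
    pts = np.zeros((3, 3))
    with pytest.raises(ValueError, match="zero"):
        weighted_kde_hotspot(np.arange(9.0).reshape(3, 3), np.zeros(3))
    with pytest.raises(ValueError, match="non-negative"):
        weighted_kde_hotspot(np.arange(9.0).reshape(3, 3), np.array([1, -1, 1.0]))
    # identical coordinates short-circuit to the point itself
    h = weighted_kde_hotspot(pts, np.ones(3))
    np.testing.assert_allclose(h.coords, 0.0)


def test_joint_mode_close_to_marginal_on_symmetric_input(rng):
    pts = rng.normal(0, 1.0, size=(40, 3))
    w = rng.uniform(0.5, 1.5, 40)
    h1 = weighted_kde_hotspot(pts, w)
    h2 = weighted_kde_hotspot(pts, w, joint=True)
    assert np.all(np.abs(h1.coords - h2.coords) < 1.0)


# -- propagation ------------------------------------------------------------

def test_propagation_arithmetic():
    ref = Hotspot("HG", "premove", np.array([12.0, -13.0, -7.00]))
    bins = [Hotspot("HG", "move:0", np.array([12.0, -13.0, -7.00])),
            Hotspot("HG", "move:1", np.array([12.0, -13.0, -5.82])),
            Hotspot("HG", "move:2", np.array([12.3, -12.6, -7.00]))]
    df = propagation(bins, ref)
    assert df.loc[0, ["dx", "dy", "dz", "euclid"]].tolist() == [0, 0, 0, 0]
    assert df.loc[1, "dz"] == pytest.approx(1.18)      # superior shift
    assert df.loc[2, "euclid"] == pytest.approx(0.5)   # 3-4-5 triangle
    assert np.all(df["euclid"] >= df[["dx", "dy", "dz"]].abs().max(axis=1) - 1e-12)


# -- surrogate test ---------------------------------------------------------

def _toy_cohort(n_h=12, seed=0):
    rng = np.random.default_rng(seed)
    return _spatial_cohort(n_h, default_stn_model(), rng, None, None, 2.0, 0.5)


def test_surrogate_null_deterministic():
    cohort = _toy_cohort()
    pts = [c[0] for c in cohort]
    ins = [c[1] for c in cohort]
    w = np.ones(len(cohort))
    ref = np.array([12.0, -13.0, -7.0])
    n1 = surrogate_propagation_null(pts, ins, w, ref, n_draws=150, seed=5)
    n2 = surrogate_propagation_null(pts, ins, w, ref, n_draws=150, seed=5)
    np.testing.assert_array_equal(n1.props, n2.props)
    assert np.all(n1.critical_low <= n1.critical_high)


def test_extreme_observation_is_significant_with_rank_bound():
    cohort = _toy_cohort()
    pts = [c[0] for c in cohort]
    ins = [c[1] for c in cohort]
    null = surrogate_propagation_null(pts, ins, np.ones(len(cohort)),
                                      np.zeros(3), n_draws=200, seed=1)
    huge = null.props.max(axis=0) + 10.0
    df = surrogate_test(huge[None, :], null)
    assert df["outside_band"].all() and df["significant"].all()
    assert np.all(df["p"] <= 2.0 / 201 + 1e-12)


def test_surrogate_pvalues_uniform_under_null():
    rng = np.random.default_rng(7)
    stn = default_stn_model()
    pvals = []
    for _ in range(150):
        cohort = _spatial_cohort(15, stn, rng, None, None, 2.0, 0.5)
        ref_c, _, obs, w = _observed_propagation(cohort, axis=2)
        ref_coords = np.array([0.0, 0.0, ref_c])
        null = surrogate_propagation_null(
            [c[0] for c in cohort], [c[1] for c in cohort], w,
            ref_coords, n_draws=99, seed=int(rng.integers(2 ** 31 - 1)),
            axes=(2,))
        draws = null.props[:, 0]
        # one-sided rank p; reference offset cancels between obs and draws
        pvals.append((1 + np.sum(draws >= obs)) / 100.0)
    ks = kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


# -- volatility -------------------------------------------------------------

def test_volatility_constant_and_alternating():
    bp = np.zeros((8, 10))
    bp[3] = 1.0
    assert volatility(bp, np.ones(8, bool)) == 0.0
    alt = np.zeros((8, 10))
    alt[0, ::2] = 1.0
    alt[1, 1::2] = 1.0
    assert volatility(alt, np.ones(8, bool)) == 100.0
    with pytest.raises(ValueError):
        volatility(bp[:, :1], np.ones(8, bool))


def test_volatility_invariant_under_monotone_transform(rng):
    bp = rng.random((8, 50))
    inside = np.array([1, 1, 0, 1, 1, 1, 0, 1], bool)
    v1 = volatility(bp, inside)
    v2 = volatility(np.exp(3.0 * bp), inside)
    assert v1 == v2


def test_volatility_iid_expectation_87_5(rng):
    # with iid continuous powers over 8 contacts, consecutive argmaxes differ
    # with probability 1 - 1/8
    bp = rng.random((8, 10_000))
    v = volatility(bp, np.ones(8, bool))
    assert abs(v - 87.5) < 2.0


# -- per-hemisphere propagation & ratio --------------------------------------

def test_per_hemisphere_propagation_trivials():
    geom = make_lead_geometry(seed=0)
    pos = np.array([c.position for c in geom])
    inside = np.array([c.inside_stn for c in geom], bool)
    same = np.ones(8)
    assert per_hemisphere_propagation(pos, inside, same, same)["euclid"] == 0.0
    ii = np.flatnonzero(inside)
    a = np.zeros(8); a[ii[0]] = 5.0
    b = np.zeros(8); b[ii[1]] = 3.0
    d = per_hemisphere_propagation(pos, inside, a, b)
    assert d["euclid"] == pytest.approx(np.linalg.norm(pos[ii[1]] - pos[ii[0]]))


def test_per_hemisphere_propagation_monotone_in_planted_drift(rng):
    geom = make_lead_geometry(seed=4)
    pos = np.array([c.position for c in geom])
    inside = np.array([c.inside_stn for c in geom], bool)
    center = pos[inside].mean(axis=0)
    rec = []
    for drift in (0.0, 1.0, 2.0):
        pa = simulate_contact_powers(geom, center, 2.0, 0.0, rng)
        pb = simulate_contact_powers(geom, center + (0, 0, drift), 2.0, 0.0, rng)
        rec.append(per_hemisphere_propagation(pos, inside, pa, pb)["euclid"])
    assert rec[0] < rec[1] < rec[2]


def test_magnitude_propagation_ratio_trivials():
    auc = pd.DataFrame({"hemisphere_id": ["h0", "h0"], "band": ["HG", "FG"],
                        "auc_total": [10.0, 20.0]})
    prop = pd.DataFrame({"hemisphere_id": ["h0", "h0"], "band": ["HG", "FG"],
                         "euclid": [1.0, 1.0]})
    df = magnitude_propagation_ratio(auc, prop)
    # grand-mean AUC = 15, grand-mean prop = 1
    assert df.loc[df["band"] == "HG", "ratio"].iloc[0] == pytest.approx(10 / 15)
    assert df.loc[df["band"] == "FG", "ratio"].iloc[0] == pytest.approx(20 / 15)
    both_mean = magnitude_propagation_ratio(
        auc.assign(auc_total=[15.0, 15.0]), prop)
    np.testing.assert_allclose(both_mean["ratio"], 1.0)
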
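"""Isotope processing, niche metrics and the discriminant machinery,
checked against independent brute-force / library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import shearwater as sw
from shearwater import isotopes
from shearwater.pipeline import fixture_ellipse_points, fixture_ward_points


# ---------------------------------------------------------------------------
# lipid normalization and discrimination


@given(st.floats(-25, -12), st.floats(0.5, 3.15))
def test_lipid_identity_at_or_below_threshold(d13c, cn):
    assert sw.lipid_normalize(d13c, cn) == d13c


def test_lipid_correction_matches_hand_evaluation():
    # post2007: d13C - 3.32 + 0.99 * C:N
    assert sw.lipid_normalize(-19.0, 4.5) == pytest.approx(-19.0 - 3.32 + 0.99 * 4.5)
    # kiljunen2006 at C:N = 4.5: L = 93 / (1 + 1/(0.246*4.5 - 0.775))
    lipid = 93.0 / (1.0 + 1.0 / (0.246 * 4.5 - 0.775))
    expect = -19.0 + 7.018 * (0.048 + 3.90 / (1 + 287.0 / lipid))
    assert sw.lipid_normalize(-19.0, 4.5, "kiljunen2006") == pytest.approx(expect)
    with pytest.raises(KeyError, match="unknown lipid"):
        sw.lipid_normalize(-19.0, 4.5, "nope")
    with pytest.raises(ValueError, match="cn_ratio"):
        sw.lipid_normalize(-19.0, np.nan)


def test_discrimination_offsets_and_inverse():
    n, c = sw.apply_discrimination(8.0, -19.0)
    assert (float(n), float(c)) == (11.7, -17.1)
    zero = sw.DiscriminationFactors(0.0, 0.0)
    n, c = sw.apply_discrimination(8.0, -19.0, zero)
    assert (float(n), float(c)) == (8.0, -19.0)
    n, c = sw.apply_discrimination(11.7, -17.1, inverse=True)
    assert float(n) == pytest.approx(8.0) and float(c) == pytest.approx(-19.0)


# ---------------------------------------------------------------------------
# Ward clustering


def _ward_bruteforce(xy):
    """Greedy Ward agglomeration via cluster sizes and centroids;
    merge height = sqrt(2 |A||B| / (|A|+|B|)) * ||muA - muB||."""
    clusters = {i: (1, xy[i].astype(float)) for i in range(len(xy))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                na, ca = clusters[a]
                nb, cb = clusters[b]
                d = np.sqrt(2 * na * nb / (na + nb)) * np.linalg.norm(ca - cb)
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        na, ca = clusters.pop(a)
        nb, cb = clusters.pop(b)
        clusters[min(a, b)] = (na + nb, (na * ca + nb * cb) / (na + nb))
    return heights


def test_ward_separated_clusters_recovered():
    rng = np.random.default_rng(0)
    a = rng.normal([0, 0], 0.5, size=(20, 2))
    b = rng.normal([10, 10], 0.5, size=(15, 2))
    labels, _ = sw.ward_cluster(np.vstack([a, b]), k=2)
    assert len(set(labels[:20])) == 1
    assert len(set(labels[20:])) == 1
    assert labels[0] != labels[-1]


def test_ward_k_equals_n_singletons():
    xy = fixture_ward_points()[["d15N", "d13C"]].to_numpy()
    labels, _ = sw.ward_cluster(xy, k=len(xy))
    assert len(set(labels)) == len(xy)
    with pytest.raises(ValueError, match="at least"):
        sw.ward_cluster(xy[:1], k=2)


def test_ward_merge_heights_match_bruteforce_oracle():
    xy = fixture_ward_points()[["d15N", "d13C"]].to_numpy()
    _, z = sw.ward_cluster(xy, k=2)
    np.testing.assert_allclose(sorted(z[:, 2]), sorted(_ward_bruteforce(xy)),
                               rtol=1e-8)


# ---------------------------------------------------------------------------
# standard ellipses


def test_sea_limits_and_correction():
    rng = np.random.default_rng(1)
    big = rng.normal(size=(100000, 2))
    assert sw.standard_ellipse(big).sea == pytest.approx(np.pi, rel=0.02)
    tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    e3 = sw.standard_ellipse(tri)
    assert e3.seac == pytest.approx(2.0 * e3.sea)
    with pytest.raises(ValueError, match="n >= 3"):
        sw.standard_ellipse(tri[:2])
    line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
    with pytest.raises(ValueError, match="degenerate"):
        sw.standard_ellipse(line)


def test_sea_matches_hand_eigen_computation():
    df = fixture_ellipse_points()
    xy = df[["d15N", "d13C"]].to_numpy()
    e = sw.standard_ellipse(df)
    # independent: SEA = pi sqrt(det(cov)) via explicit sums
    d = xy - xy.mean(axis=0)
    n = len(xy)
    a = (d[:, 0] ** 2).sum() / (n - 1)
    b = (d[:, 0] * d[:, 1]).sum() / (n - 1)
    c = (d[:, 1] ** 2).sum() / (n - 1)
    assert e.sea == pytest.approx(np.pi * np.sqrt(a * c - b * b), rel=1e-10)
    assert e.seac == pytest.approx(e.sea * (n - 1) / (n - 2))
    from shapely.geometry import MultiPoint

    assert e.hull_area == pytest.approx(MultiPoint(xy.tolist()).convex_hull.area)


# ---------------------------------------------------------------------------
# discriminant analysis


def _training_frame(seed=0, n=50, sep=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for reg, (mn, mc) in (("Atlantic", (14.5, -16.1)), ("Mediterranean", (11.1, -17.4))):
        mu = np.array([mn, mc]) * sep + np.array([13.0, -16.7]) * (1 - sep)
        d = rng.normal(mu, [1.2, 0.6], size=(n, 2))
        rows += [{"bird_id": f"{reg[:3]}{i}", "d15N": a, "d13C": b, "region": reg}
                 for i, (a, b) in enumerate(d)]
    return pd.DataFrame(rows)


def test_equal_means_no_discrimination():
    df = _training_frame(seed=2, sep=0.0)
    m = sw.fit_lda(df)
    assert m.wilks_lambda > 0.95


def test_fisher_equals_nearest_mahalanobis_mean():
    df = _training_frame(seed=3)
    m = sw.fit_lda(df)
    rng = np.random.default_rng(4)
    pts = pd.DataFrame({"d15N": rng.uniform(8, 18, 100),
                        "d13C": rng.uniform(-20, -14, 100)})
    got = sw.classify(m, pts)["region"].to_numpy()
    si = np.linalg.inv(m.pooled_cov)
    x = pts[["d15N", "d13C"]].to_numpy()
    d2 = {g: np.einsum("ij,jk,ik->i", x - m.means[g], si, x - m.means[g])
          for g in m.groups}
    expect = np.where(d2[m.groups[0]] < d2[m.groups[1]], m.groups[0], m.groups[1])
    assert (got == expect).all()


def test_canonical_sign_rule_agrees_with_fisher_argmax():
    df = _training_frame(seed=5)
    m = sw.fit_lda(df)
    rng = np.random.default_rng(6)
    pts = pd.DataFrame({"d15N": rng.uniform(8, 18, 200),
                        "d13C": rng.uniform(-20, -14, 200)})
    out = sw.classify(m, pts)
    by_sign = np.where(out["D"] > 0, m.groups[0], m.groups[1])
    assert (by_sign == out["region"].to_numpy()).all()


def test_lda_against_sklearn_and_manova():
    df = _training_frame(seed=7, n=20)
    m = sw.fit_lda(df)
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(
        df[["d15N", "d13C"]], df["region"]
    )
    pts = _training_frame(seed=8, n=30)
    ours = sw.classify(m, pts)["region"].to_numpy()
    theirs = sk.predict(pts[["d15N", "d13C"]])
    assert (ours == theirs).all()
    from statsmodels.multivariate.manova import MANOVA

    mv = MANOVA.from_formula("d15N + d13C ~ region", data=df)
    wilks = mv.mv_test().results["region"]["stat"].loc["Wilks' lambda", "Value"]
    assert m.wilks_lambda == pytest.approx(float(wilks), rel=1e-6)


def test_decisions_invariant_to_affine_rescaling():
    df = _training_frame(seed=9)
    pts = _training_frame(seed=10, n=40)
    base = sw.classify(sw.fit_lda(df), pts)["region"].to_numpy()
    scaled = df.copy()
    scaled["d15N"] = 3.0 * scaled["d15N"] + 5.0
    scaled["d13C"] = 0.5 * scaled["d13C"] - 2.0
    pts2 = pts.copy()
    pts2["d15N"] = 3.0 * pts2["d15N"] + 5.0
    pts2["d13C"] = 0.5 * pts2["d13C"] - 2.0
    again = sw.classify(sw.fit_lda(scaled), pts2)["region"].to_numpy()
    assert (base == again).all()


def test_boundary_converges_to_analytic_optimum():
    """With Gaussian groups and shared covariance the fitted canonical
    direction converges to Sigma^-1 (mu1 - mu2)."""
    df = _training_frame(seed=11, n=5000)
    m = sw.fit_lda(df)
    sigma = np.diag([1.2**2, 0.6**2])
    w = np.linalg.inv(sigma) @ np.array([14.5 - 11.1, -16.1 + 17.4])
    got = np.array(m.canonical[:2])
    cos = got @ w / np.linalg.norm(got) / np.linalg.norm(w)
    assert cos > 0.999


def test_printed_p6_preset_classifies_published_group_means():
    samp = pd.DataFrame({"d15N": [11.8, 14.5], "d13C": [-17.4, -16.1]})
    out = sw.classify("paper_p6", samp)
    assert out["region"].tolist() == ["Mediterranean", "Atlantic"]
    assert out["margin"].iloc[0] == pytest.approx(7.4, abs=0.1)


def test_printed_p1_canonical_signs():
    p1 = sw.get_preset("published_p1")
    d = p1.canonical_score([13.7, 11.8], [-16.9, -17.2])
    assert d[0] == pytest.approx(0.86, abs=0.01)
    assert d[1] == pytest.approx(-0.57, abs=0.01)
    assert d[0] * d[1] < 0
    with pytest.raises(KeyError, match="unknown preset"):
        sw.get_preset("paper_p9")


def test_exact_tie_left_unassigned():
    m = isotopes.DiscriminantModel(
        groups=("Atlantic", "Mediterranean"),
        canonical=(1.0, 0.0, 0.0),
        fisher={"Atlantic": (1.0, 0.0, 0.0), "Mediterranean": (1.0, 0.0, 0.0)},
    )
    out = sw.classify(m, pd.DataFrame({"d15N": [12.0], "d13C": [-17.0]}))
    assert out["unassigned"].iloc[0]
    assert out["region"].iloc[0] == ""


# ---------------------------------------------------------------------------
# cross-validation and cohort assignment


def test_loocv_perfectly_separated():
    df = _training_frame(seed=12, n=10)
    df.loc[df["region"] == "Atlantic", "d15N"] += 20.0
    acc, preds = sw.loocv(df)
    assert acc == 1.0
    assert (preds["region_pred"] == preds["region_true"]).all()


def test_loocv_chance_level_when_identical():
    df = _training_frame(seed=13, n=100, sep=0.0)
    acc, _ = sw.loocv(df)
    assert 0.35 <= acc <= 0.65


def test_loocv_matches_bruteforce_refits():
    df = _training_frame(seed=14, n=4)
    _, preds = sw.loocv(df)
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    for i in range(len(df)):
        rest = df.drop(index=i)
        sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(
            rest[["d15N", "d13C"]], rest["region"]
        )
        assert preds["region_pred"].iloc[i] == sk.predict(
            df.iloc[[i]][["d15N", "d13C"]]
        )[0]


def test_assign_untracked_edge_cases():
    m = sw.fit_lda(_training_frame(seed=15))
    empty = sw.assign_untracked(m, pd.DataFrame(columns=["d15N", "d13C"]))
    assert empty["counts"] == {} and len(empty["assignments"]) == 0
    at_mean = pd.DataFrame({"d15N": [11.1] * 5, "d13C": [-17.4] * 5})
    res = sw.assign_untracked(m, at_mean)
    assert res["proportions"]["Mediterranean"] == 1.0


def test_cluster_dfa_agreement_on_separated_data():
    rng = np.random.default_rng(16)
    m = sw.fit_lda(_training_frame(seed=17))
    a = rng.normal([14.5, -16.1], 0.2, size=(25, 2))
    b = rng.normal([11.1, -17.4], 0.2, size=(25, 2))
    samp = pd.DataFrame(np.vstack([a, b]), columns=["d15N", "d13C"])
    res = sw.assign_untracked(m, samp)
    assert res["ward_agreement"] == 1.0
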
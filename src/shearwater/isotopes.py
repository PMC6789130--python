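"""Feather and prey stable-isotope processing and region assignment.

delta15N and delta13C of primary feathers grown at sea record trophic level
and regional baseline biochemistry, which differ strongly between NE
Atlantic and western Mediterranean food webs.  This module covers the
standard processing chain (lipid normalization of prey muscle at C:N >
3.15, trophic discrimination correction, Ward clustering of the bivariate
isotope space, standard ellipse areas) and the two-group linear
discriminant machinery used to assign birds to a non-breeding region:
fitting with pooled within-group covariance, Fisher classification
functions, Wilks' Lambda with its F and chi-square approximations,
leave-one-out cross-validation, and evaluation of previously published
fixed-coefficient classifiers for *Puffinus* shearwaters (shipped as
presets ``published_p1`` / ``published_p6``; ``paper_p1`` / ``paper_p6``
are accepted aliases).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull

__all__ = [
    "DiscriminationFactors",
    "DiscriminantModel",
    "EllipseSummary",
    "LIPID_EQUATIONS",
    "lipid_normalize",
    "apply_discrimination",
    "ward_cluster",
    "standard_ellipse",
    "fit_lda",
    "classify",
    "get_preset",
    "loocv",
    "assign_untracked",
]

REGIONS = ("Atlantic", "Mediterranean")


@dataclass(frozen=True)
class DiscriminationFactors:
    """Diet-to-feather trophic discrimination offsets (permil)."""

    d15N_offset: float = 3.7
    d13C_offset: float = 1.9

    def __post_init__(self):
        if self.d15N_offset < 0 or self.d13C_offset < 0:
            raise ValueError("discrimination factors must be non-negative")


# ---------------------------------------------------------------------------
# lipid normalization


def _post2007(d13c, cn):
    # aquatic-tissue linear normalization: d13C' = d13C - 3.32 + 0.99 C:N
    return d13c - 3.32 + 0.99 * cn


def _kiljunen2006(d13c, cn):
    # revised fish-muscle normalization (D = 7.018, I = 0.048)
    lipid = 93.0 / (1.0 + (0.246 * cn - 0.775) ** -1)
    return d13c + 7.018 * (0.048 + 3.90 / (1.0 + 287.0 / lipid))


LIPID_EQUATIONS = {"post2007": _post2007, "kiljunen2006": _kiljunen2006}
CN_THRESHOLD = 3.15


def lipid_normalize(d13C, cn_ratio, equation: str = "post2007"):
    """Lipid-correct prey-muscle d13C when C:N strictly exceeds 3.15.

    Values at or below the threshold pass through unchanged.  The equation
    id should be recorded alongside outputs (see the registry
    :data:`LIPID_EQUATIONS`).
    """
    if equation not in LIPID_EQUATIONS:
        raise KeyError(f"unknown lipid equation {equation!r}; "
                       f"known: {sorted(LIPID_EQUATIONS)}")
    d13C = np.asarray(d13C, float)
    cn = np.asarray(cn_ratio, float)
    if np.any(~np.isfinite(cn)) or np.any(cn <= 0):
        raise ValueError("cn_ratio must be positive and finite")
    corrected = LIPID_EQUATIONS[equation](d13C, cn)
    out = np.where(cn > CN_THRESHOLD, corrected, d13C)
    return float(out) if out.ndim == 0 else out


def apply_discrimination(d15N, d13C, factors: DiscriminationFactors = DiscriminationFactors(),
                         *, inverse: bool = False):
    """Shift prey isotope values into bird-feather space (or back)."""
    s = -1.0 if inverse else 1.0
    return (
        np.asarray(d15N, float) + s * factors.d15N_offset,
        np.asarray(d13C, float) + s * factors.d13C_offset,
    )


# ---------------------------------------------------------------------------
# clustering and ellipses


def _xy(samples) -> np.ndarray:
    if isinstance(samples, pd.DataFrame):
        return samples[["d15N", "d13C"]].to_numpy(float)
    return np.asarray(samples, float)


def ward_cluster(samples, k: int = 2):
    """Ward minimum-variance hierarchical clustering in (d15N, d13C) space.

    Returns (labels 1..k, scipy linkage matrix).
    """
    xy = _xy(samples)
    n = len(xy)
    if n < k:
        raise ValueError(f"need at least k={k} samples, got {n}")
    z = linkage(xy, method="ward")
    labels = fcluster(z, t=k, criterion="maxclust")
    return labels, z


@dataclass(frozen=True)
class EllipseSummary:
    """Bivariate isotopic niche metrics of one group (permil^2)."""

    group: str
    sea: float
    seac: float
    hull_area: float
    n: int


def standard_ellipse(samples, group: str = "") -> EllipseSummary:
    """Standard ellipse area SEA = pi sqrt(l1 l2) of the sample covariance,
    its small-sample correction SEAc = SEA (n-1)/(n-2), and the convex
    hull area."""
    xy = _xy(samples)
    n = len(xy)
    if n < 3:
        raise ValueError("standard ellipse needs n >= 3")
    cov = np.cov(xy.T)
    ev = np.linalg.eigvalsh(cov)
    if ev[0] <= 1e-12:
        raise ValueError("degenerate covariance: samples are collinear")
    sea = float(np.pi * np.sqrt(ev[0] * ev[1]))
    seac = sea * (n - 1) / (n - 2)
    hull = float(ConvexHull(xy).volume)  # 2-D: volume is the area
    return EllipseSummary(group, sea, seac, hull, n)


# ---------------------------------------------------------------------------
# discriminant analysis


@dataclass
class DiscriminantModel:
    """Two-group linear discriminant in (d15N, d13C) space.

    ``canonical`` is (coef_d15N, coef_d13C, constant); scores are scaled to
    unit pooled within-group variance and centred on the midpoint of the
    group means, so (with the default equal priors) the sign rule on the
    canonical score D agrees with the Fisher-function argmax: D > 0 means
    the first group of ``groups``.  ``fisher`` maps each group to its
    classification function (coef_d15N, coef_d13C, constant).
    """

    groups: tuple
    canonical: tuple
    fisher: dict
    means: dict = field(default_factory=dict)
    pooled_cov: np.ndarray | None = None
    priors: dict = field(default_factory=dict)
    n_train: dict = field(default_factory=dict)
    wilks_lambda: float | None = None
    rao_f: float | None = None
    rao_f_df: tuple | None = None
    bartlett_chi2: float | None = None
    bartlett_chi2_df: int | None = None
    name: str = "fitted"

    def canonical_score(self, d15N, d13C):
        a, b, c = self.canonical
        return a * np.asarray(d15N, float) + b * np.asarray(d13C, float) + c

    def fisher_scores(self, d15N, d13C) -> dict:
        out = {}
        for g, (a, b, c) in self.fisher.items():
            out[g] = a * np.asarray(d15N, float) + b * np.asarray(d13C, float) + c
        return out


def fit_lda(training: pd.DataFrame, *, priors: dict | None = None) -> DiscriminantModel:
    """Fit the two-group linear discriminant on tracked birds.

    ``training`` needs columns ``d15N, d13C, region`` with exactly two
    regions, >= 3 birds each.  Priors default to equal (the training
    groups are typically unbalanced; proportional priors can be passed
    explicitly).  Emits Wilks' Lambda with Rao's F and Bartlett's
    chi-square approximations.
    """
    df = training
    groups = tuple(sorted(df["region"].unique()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two regions, got {groups}")
    xs = {g: df.loc[df["region"] == g, ["d15N", "d13C"]].to_numpy(float) for g in groups}
    ns = {g: len(xs[g]) for g in groups}
    if min(ns.values()) < 3:
        raise ValueError("need >= 3 training birds per region")
    n = sum(ns.values())
    means = {g: xs[g].mean(axis=0) for g in groups}
    w = sum(
        (xs[g] - means[g]).T @ (xs[g] - means[g]) for g in groups
    )
    sw = w / (n - 2)
    if np.linalg.cond(sw) > 1e12:
        raise ValueError("singular pooled within-group covariance")
    sw_inv = np.linalg.inv(sw)
    if priors is None:
        priors = {g: 0.5 for g in groups}

    fisher = {}
    for g in groups:
        coef = sw_inv @ means[g]
        const = -0.5 * means[g] @ sw_inv @ means[g] + np.log(priors[g])
        fisher[g] = (float(coef[0]), float(coef[1]), float(const))

    diff = means[groups[0]] - means[groups[1]]
    wvec = sw_inv @ diff
    scale = 1.0 / np.sqrt(wvec @ sw @ wvec)
    a = wvec * scale
    mid = 0.5 * (means[groups[0]] + means[groups[1]])
    canonical = (float(a[0]), float(a[1]), float(-a @ mid))

    grand = sum(ns[g] * means[g] for g in groups) / n
    b = sum(ns[g] * np.outer(means[g] - grand, means[g] - grand) for g in groups)
    lam1 = float(np.max(np.linalg.eigvals(np.linalg.solve(w, b)).real))
    wilks = 1.0 / (1.0 + lam1)
    p = 2
    rao_f = (1 - wilks) / wilks * (n - p - 1) / p
    chi2 = -(n - 1 - (p + 2) / 2) * np.log(wilks)

    return DiscriminantModel(
        groups=groups,
        canonical=canonical,
        fisher=fisher,
        means={g: means[g].copy() for g in groups},
        pooled_cov=sw,
        priors=dict(priors),
        n_train=ns,
        wilks_lambda=wilks,
        rao_f=float(rao_f),
        rao_f_df=(p, n - p - 1),
        bartlett_chi2=float(chi2),
        bartlett_chi2_df=p,
    )


# previously published fixed-coefficient classifiers (P1: early
# non-breeding season feather, three populations; P6: mid non-breeding,
# Balearic populations).  Positive canonical score = Atlantic.
_PRESETS = {
    "published_p1": DiscriminantModel(
        groups=("Atlantic", "Mediterranean"),
        canonical=(0.666, 0.538, 0.828),
        fisher={
            "Mediterranean": (14.743, -36.551, -412.491),
            "Atlantic": (16.331, -35.270, -410.518),
        },
        name="published_p1",
    ),
    "published_p6": DiscriminantModel(
        groups=("Atlantic", "Mediterranean"),
        canonical=(1.235, -0.033, -17.995),
        fisher={
            "Mediterranean": (35.138, -55.545, -684.788),
            "Atlantic": (39.971, -55.674, -751.429),
        },
        name="published_p6",
    ),
}
_PRESET_ALIASES = {"paper_p1": "published_p1", "paper_p6": "published_p6"}


def get_preset(name: str) -> DiscriminantModel:
    """Fetch a published fixed-coefficient classifier by name."""
    key = _PRESET_ALIASES.get(name, name)
    if key not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}")
    return _PRESETS[key]


def classify(model, samples: pd.DataFrame) -> pd.DataFrame:
    """Assign each sample to the region with the larger Fisher score.

    ``model`` is a :class:`DiscriminantModel` or a preset name.  Returns a
    DataFrame with per-group scores, the canonical score ``D``, the Fisher
    score margin, and ``region`` ('' on an exact tie, flagged
    ``unassigned``).
    """
    if isinstance(model, str):
        model = get_preset(model)
    d15n = samples["d15N"].to_numpy(float)
    d13c = samples["d13C"].to_numpy(float)
    scores = model.fisher_scores(d15n, d13c)
    g1, g2 = model.groups
    s1, s2 = np.asarray(scores[g1], float), np.asarray(scores[g2], float)
    region = np.where(s1 > s2, g1, g2)
    tie = s1 == s2
    region = np.where(tie, "", region)
    out = pd.DataFrame(
        {
            f"score_{g1}": s1,
            f"score_{g2}": s2,
            "D": model.canonical_score(d15n, d13c),
            "margin": np.abs(s1 - s2),
            "region": region,
            "unassigned": tie,
        },
        index=samples.index,
    )
    if "bird_id" in samples.columns:
        out.insert(0, "bird_id", samples["bird_id"].to_numpy())
    return out


def loocv(training: pd.DataFrame, *, priors: dict | None = None):
    """Jackknife leave-one-out cross-validation of :func:`fit_lda`.

    Returns (accuracy, predictions DataFrame with columns ``region_true,
    region_pred``).  Birds whose removal would empty a group are skipped
    with a warning.
    """
    df = training.reset_index(drop=True)
    preds = []
    for i in range(len(df)):
        rest = df.drop(index=i)
        if rest["region"].nunique() < 2 or rest["region"].value_counts().min() < 3:
            warnings.warn(f"skipping LOOCV fold {i}: group too small", stacklevel=2)
            preds.append(None)
            continue
        m = fit_lda(rest, priors=priors)
        preds.append(classify(m, df.iloc[[i]])["region"].iloc[0])
    out = pd.DataFrame(
        {
            "region_true": df["region"],
            "region_pred": preds,
        }
    )
    ok = out["region_pred"].notna()
    accuracy = float((out.loc[ok, "region_pred"] == out.loc[ok, "region_true"]).mean())
    return accuracy, out


def assign_untracked(model, untracked: pd.DataFrame) -> dict:
    """Classify untracked birds and summarise the cohort.

    Returns a dict with ``assignments`` (per-bird frame), ``counts`` and
    ``proportions`` per region, and ``ward_agreement``: the fraction of
    birds whose discriminant assignment matches the 2-group Ward cluster
    (clusters mapped to regions by majority assignment).  Empty input
    yields an empty summary.
    """
    if isinstance(model, str):
        model = get_preset(model)
    if len(untracked) == 0:
        return {"assignments": pd.DataFrame(), "counts": {}, "proportions": {},
                "ward_agreement": np.nan}
    assigned = classify(model, untracked)
    counts = assigned["region"].value_counts().to_dict()
    total = int(len(assigned))
    proportions = {g: counts.get(g, 0) / total for g in model.groups}
    ward_agreement = np.nan
    if total >= 2:
        labels, _ = ward_cluster(untracked, k=2)
        mapping = {}
        for lbl in np.unique(labels):
            sub = assigned["region"].to_numpy()[labels == lbl]
            sub = sub[sub != ""]
            if len(sub):
                vals, cnts = np.unique(sub, return_counts=True)
                mapping[lbl] = vals[np.argmax(cnts)]
        mapped = np.array([mapping.get(l, "") for l in labels])
        ward_agreement = float((mapped == assigned["region"].to_numpy()).mean())
    return {
        "assignments": assigned,
        "counts": counts,
        "proportions": proportions,
        "ward_agreement": ward_agreement,
    }
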
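"""Phenotype statistics: z-scoring, PCA with correlation loadings,
group-separation summaries, and the age/morphology/marker regressions.

PCA is run on z-scored features (the 53 descriptors mix px, px^2 and
dimensionless units).  Loadings are defined as the Pearson correlation
between each original variable and each principal-component score, and
contributors are ranked by absolute loading.  "Independent contribution"
of a predictor is operationalised as its last-added increment in R^2
(partial R^2).  All inference is at the sample (animal/donor) level:
nuclei are averaged per sample first, so n is the number of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import silhouette_score


@dataclass
class PCAOutput:
    """Scores, correlation loadings and contributor ranking of one PCA."""

    scores: pd.DataFrame
    loadings: pd.DataFrame  # features x components, Pearson correlations
    explained_variance_ratio: np.ndarray
    top_contributors: dict[str, list[str]]
    feature_names: list[str] = field(default_factory=list)


@dataclass
class RegressionOutput:
    """OLS summary: per-term coefficient, CI, p, plus R^2 decomposition."""

    params: dict[str, float]
    bse: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    r_squared: float
    partial_r_squared: dict[str, float]
    nobs: int


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-score (x - mean) / SD with the n-1 denominator.

    Zero-variance columns are dropped with a warning; fewer than two rows
    is an error.
    """
    if len(matrix) < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    numeric = matrix.select_dtypes(include=[np.number])
    sd = numeric.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"zero-variance columns dropped: {constant}", stacklevel=2)
        numeric = numeric.drop(columns=constant)
        sd = sd.drop(index=constant)
    return (numeric - numeric.mean()) / sd


def run_pca(matrix: pd.DataFrame, k_top: int = 10) -> PCAOutput:
    """PCA via SVD of the (z-scored, centered) feature matrix.

    Loadings are recomputed as Pearson correlations between the input
    columns and the component scores.  Each component's sign is fixed so
    that its largest-|loading| variable loads positively, making the
    output deterministic.  ``top_contributors`` ranks features by
    |loading| on PC1 and PC2 (k_top each).
    """
    if len(matrix) < 3:
        raise ValueError("PCA needs at least 3 rows")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_comp = int((S > S[0] * 1e-12).sum()) if S[0] > 0 else 0
    if n_comp == 0:
        raise ValueError("input matrix has no variance")
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]
    scores = U * S

    # loadings as correlations of original columns with scores
    col_sd = X.std(axis=0, ddof=1)
    score_sd = scores.std(axis=0, ddof=1)
    cov = X.T @ scores / (len(X) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        load = cov / np.outer(col_sd, score_sd)
    load = np.nan_to_num(load, nan=0.0)

    # orient each PC so its strongest variable loads positively
    for k in range(n_comp):
        j = np.argmax(np.abs(load[:, k]))
        if load[j, k] < 0:
            load[:, k] *= -1
            scores[:, k] *= -1

    ev = S**2
    evr = ev / ev.sum()
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    features = list(matrix.columns)
    loadings = pd.DataFrame(load, index=features, columns=comp_names)
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=comp_names)

    top = {}
    for pc in comp_names[: min(2, n_comp)]:
        order = loadings[pc].abs().sort_values(ascending=False)
        top[pc] = order.index[:k_top].tolist()

    return PCAOutput(
        scores=scores_df,
        loadings=loadings,
        explained_variance_ratio=evr,
        top_contributors=top,
        feature_names=features,
    )


def _confidence_ellipse(points: np.ndarray, level: float = 0.95) -> dict:
    """95% confidence ellipse of a 2-D point cloud (chi-square quantile
    of the sample covariance)."""
    center = points.mean(axis=0)
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    scale = sps.chi2.ppf(level, df=2)
    angle = float(np.degrees(np.arctan2(evecs[1, -1], evecs[0, -1])))
    return {
        "center": center.tolist(),
        "semi_axes": np.sqrt(np.maximum(evals[::-1], 0) * scale).tolist(),
        "angle_deg": angle,
    }


def group_separation(scores: pd.DataFrame, labels) -> dict:
    """Group-separation report on the PC1-PC2 plane.

    Per-group centroid and 95% confidence ellipse, plus the silhouette
    coefficient over PC1-PC2 as the scalar separation summary.  Groups
    with fewer than 3 observations are excluded with a warning; with a
    single usable group the silhouette is undefined (None).
    """
    labels = np.asarray(labels)
    pcs = scores[["PC1", "PC2"]].to_numpy() if isinstance(scores, pd.DataFrame) else np.asarray(scores)[:, :2]
    report: dict = {"groups": {}, "silhouette": None}
    usable = []
    for g in pd.unique(labels):
        pts = pcs[labels == g]
        if len(pts) < 3:
            warnings.warn(f"group {g!r} has < 3 observations: excluded", stacklevel=2)
            continue
        usable.append(g)
        report["groups"][str(g)] = {
            "n": int(len(pts)),
            "centroid": pts.mean(axis=0).tolist(),
            "ellipse": _confidence_ellipse(pts),
        }
    if len(usable) >= 2:
        keep = np.isin(labels, usable)
        report["silhouette"] = float(
            silhouette_score(pcs[keep], labels[keep].astype(str))
        )
    else:
        warnings.warn("separation undefined with fewer than 2 groups", stacklevel=2)
    return report


def _ols_output(y: np.ndarray, X: pd.DataFrame) -> tuple[RegressionOutput, sm.OLS]:
    design = sm.add_constant(X)
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int()
    out = RegressionOutput(
        params=dict(fit.params),
        bse=dict(fit.bse),
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in ci.index},
        pvalues=dict(fit.pvalues),
        r_squared=float(fit.rsquared),
        partial_r_squared={},
        nobs=int(fit.nobs),
    )
    return out, fit


def regress_trend(outcome, group_codes) -> RegressionOutput:
    """OLS of a per-sample outcome on the ordinal age-group code
    (young=0, middle=1, aged=2): slope, CI and p for the age trend."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(group_codes, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need >= 3 samples with matching outcome and codes")
    if np.ptp(x) == 0:
        raise ValueError("rank-deficient design: single group code")
    X = pd.DataFrame({"group_code": x})
    out, _ = _ols_output(y, X)
    out.partial_r_squared = {"group_code": out.r_squared}
    return out


def regress_marker_on_morphology(marker, eccentricity, age) -> RegressionOutput:
    """Additive OLS: marker ~ age + eccentricity, at the sample level.

    Reports each coefficient with CI and p, the overall R^2, and each
    predictor's partial R^2 (the increment in R^2 when it is added
    last), the operational measure of a contribution independent of the
    other predictor.  Near-collinear predictors
    (|corr(age, eccentricity)| > 0.99) are refused.
    """
    y = np.asarray(marker, dtype=float)
    age = np.asarray(age, dtype=float)
    ecc = np.asarray(eccentricity, dtype=float)
    if not (len(y) == len(age) == len(ecc)):
        raise ValueError("marker, eccentricity and age must share a length")
    if len(y) < 5:
        raise ValueError("need >= 5 samples")
    if np.ptp(age) == 0 or np.ptp(ecc) == 0:
        raise ValueError("rank-deficient design: constant predictor")
    r = float(np.corrcoef(age, ecc)[0, 1])
    if abs(r) > 0.99:
        raise ValueError(
            f"age and eccentricity are collinear (|r| = {abs(r):.4f} > 0.99)"
        )
    X = pd.DataFrame({"age": age, "eccentricity": ecc})
    out, _ = _ols_output(y, X)

    r2_age_only, _ = _ols_output(y, X[["age"]])
    r2_ecc_only, _ = _ols_output(y, X[["eccentricity"]])
    out.partial_r_squared = {
        "eccentricity": out.r_squared - r2_age_only.r_squared,
        "age": out.r_squared - r2_ecc_only.r_squared,
    }
    return out
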
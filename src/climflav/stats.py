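"""Verification statistics: Pearson banding, correlation PCA, HCA.

These are the cross-checks run alongside the neural-network sensitivity
analysis: a Pearson correlation matrix between responses and climate
factors with qualitative strength bands, principal component analysis
on the correlation matrix with a fixed sign convention, and
agglomerative hierarchical clustering with a heatmap-ready z-scored
matrix export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.cluster import hierarchy as _hier
from scipy.spatial import distance as _dist

__all__ = [
    "CorrelationReport",
    "PcaResult",
    "HcaResult",
    "DEFAULT_BAND_THRESHOLDS",
    "pearson_matrix",
    "band_correlation",
    "pca_scores",
    "hca",
]

#: |r| cut points between negligible/low/medium/high bands.
DEFAULT_BAND_THRESHOLDS: tuple[float, float, float] = (0.1, 0.4, 0.7)


def band_correlation(
    r: float, thresholds: tuple[float, float, float] = DEFAULT_BAND_THRESHOLDS
) -> str:
    """Qualitative strength band of a Pearson coefficient, sign included.

    |r| < t0 is "negligible" (no sign); [t0, t1) low, [t1, t2) medium,
    >= t2 high, each prefixed-less and suffixed with "positive" or
    "negative".  NaN maps to "undefined".
    """
    if np.isnan(r):
        return "undefined"
    if abs(r) > 1.0 + 1e-12:
        raise ValueError("correlation coefficient must lie in [-1, 1]")
    t0, t1, t2 = thresholds
    a = abs(r)
    if a < t0:
        return "negligible"
    label = "low" if a < t1 else "medium" if a < t2 else "high"
    return f"{label} {'positive' if r > 0 else 'negative'}"


@dataclass
class CorrelationReport:
    """Pairwise Pearson r, two-sided p-values and band labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    bands: pd.DataFrame
    thresholds: tuple[float, float, float] = DEFAULT_BAND_THRESHOLDS

    def to_long(self) -> pd.DataFrame:
        rows = []
        for a in self.r.index:
            for b in self.r.columns:
                rows.append(
                    {
                        "row": a,
                        "column": b,
                        "r": self.r.loc[a, b],
                        "p": self.p.loc[a, b],
                        "band": self.bands.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def pearson_matrix(
    X: pd.DataFrame,
    Y: pd.DataFrame | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_BAND_THRESHOLDS,
) -> CorrelationReport:
    """Pearson correlation of every column of X against every column of Y.

    With ``Y=None`` the square self-correlation of X is computed.
    p-values are the standard two-sided t-transform with n - 2 degrees
    of freedom.  A constant column yields NaN r/p and an "undefined"
    band for its pairs rather than failing the whole report.  No
    multiple-testing correction is applied; p-values are raw.
    """
    square = Y is None
    Yt = X if square else Y
    if len(X) != len(Yt):
        raise ValueError("X and Y must have the same number of rows")
    if len(X) < 3:
        raise ValueError("need at least 3 rows for correlation")

    r = pd.DataFrame(np.nan, index=X.columns, columns=Yt.columns, dtype=float)
    p = r.copy()
    for a in X.columns:
        xa = X[a].to_numpy(float)
        for b in Yt.columns:
            yb = Yt[b].to_numpy(float)
            if np.ptp(xa) == 0 or np.ptp(yb) == 0:
                continue  # undefined-correlation flag stays NaN
            res = _sps.pearsonr(xa, yb)
            r.loc[a, b] = res.statistic
            p.loc[a, b] = res.pvalue
    bands = r.map(lambda v: band_correlation(v, thresholds))
    return CorrelationReport(r=r, p=p, bands=bands, thresholds=thresholds)


@dataclass
class PcaResult:
    """Correlation-matrix PCA: scores, loadings, explained variance."""

    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # variables x components (orthonormal columns)
    explained_variance_ratio: np.ndarray
    zscored: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def pca_scores(X: pd.DataFrame) -> PcaResult:
    """PCA on the correlation matrix of ``X`` (variables z-scored, ddof=1).

    Components are ordered by decreasing eigenvalue and each loading
    vector is oriented so its largest-magnitude entry is positive,
    making signs reproducible across platforms.  Scores are the
    z-scored data projected on the loadings; with all components
    retained, ``scores @ loadings.T`` reconstructs the z-scored data.
    """
    if len(X) < 3:
        raise ValueError("PCA needs at least 3 samples")
    sd = X.std(ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant column(s) {bad} cannot be z-scored")
    Z = (X - X.mean()) / sd
    corr = np.corrcoef(Z.to_numpy(float), rowvar=False)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention: largest-|loading| entry positive per component
    for k in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]
    comp = [f"PC{k + 1}" for k in range(evecs.shape[1])]
    loadings = pd.DataFrame(evecs, index=X.columns, columns=comp)
    scores = pd.DataFrame(Z.to_numpy(float) @ evecs, index=X.index, columns=comp)
    total = evals.sum()
    ratio = evals / total if total > 0 else np.full_like(evals, 1.0 / len(evals))
    return PcaResult(scores=scores, loadings=loadings,
                     explained_variance_ratio=ratio, zscored=Z)


_LINKAGES = {"average", "single", "complete", "ward"}


@dataclass
class HcaResult:
    """Agglomerative clustering trace plus heatmap-ready matrix."""

    merges: np.ndarray  # (n-1, 2) merged cluster indices (scipy convention)
    heights: np.ndarray  # (n-1,) merge distances
    leaf_order: list[int]
    linkage_method: str
    metric: str
    items: list
    zscored: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]


def hca(
    X: pd.DataFrame,
    linkage: str = "average",
    metric: str = "euclidean",
    standardize: bool = True,
) -> HcaResult:
    """Hierarchical clustering of the rows of ``X``.

    Features are z-scored by default (constant features dropped from
    the distance, they carry no signal); distances use ``metric`` and
    merging uses ``linkage`` (average by default, Ward available).
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(_LINKAGES)}")
    if metric not in ("euclidean", "cityblock", "cosine", "correlation"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(X) < 2:
        raise ValueError("clustering needs at least 2 items")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")

    M = X.astype(float)
    if standardize:
        sd = M.std(ddof=1)
        keep = sd > 0
        M = (M.loc[:, keep] - M.loc[:, keep].mean()) / sd[keep]
    D = _dist.pdist(M.to_numpy(float), metric=metric)
    Zl = _hier.linkage(D, method=linkage)
    order = _hier.leaves_list(Zl)
    return HcaResult(
        merges=Zl[:, :2].astype(int),
        heights=Zl[:, 2].copy(),
        leaf_order=[int(i) for i in order],
        linkage_method=linkage,
        metric=metric,
        items=list(X.index),
        zscored=M,
    )
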
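"""Multivariate genotype screening: heatmap matrix, Ward clustering,
PCA biplot and maximum-genetic-distance contrast-pair selection.

The screening operates on the genotype x trait matrix of means.  Columns
are z-scored (traits have incommensurate units), genotype-genotype
Euclidean distances feed Ward agglomerative dendrograms (Ward.D2 by
default, the modern convention; classical Ward.D on squared
dissimilarities is available), and PCA is the eigendecomposition of the
trait correlation matrix with a deterministic sign convention.  The
heatmap is reduced to its analysis content — an integer colour-bin matrix
plus dendrogram leaf orders — so results are testable without rendering.

``select_contrast_pair`` implements the screening procedure for picking
the tolerant/susceptible genotype pair for expression profiling:

1. the candidate pair maximizes inter-cluster Euclidean distance, with
   the other members of each endpoint's cluster as alternates;
2. candidates are ranked by the proximity of their biplot scores to the
   loading direction of the target traits (e.g. SOD and yield);
3. remaining ties break on extremal target-trait means, then
   lexicographically on the genotype label.

When both irrigation conditions are screened, the stress-condition result
takes precedence over the normal one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PcaResult",
    "ScreeningBundle",
    "ContrastPair",
    "zscore",
    "euclidean_distances",
    "ward_linkage",
    "cut_clusters",
    "pca_biplot",
    "heatmap_bins",
    "build_screening_bundle",
    "select_contrast_pair",
    "select_contrast_pair_by_priority",
]


def zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-wise (x - mean) / sd with sample sd; drops constant columns."""
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = matrix.std(ddof=1)
    constant = list(sd.index[(sd == 0) | ~np.isfinite(sd)])
    if constant:
        warnings.warn(f"dropping zero-variance columns: {constant}", stacklevel=2)
        matrix = matrix.drop(columns=constant)
        sd = sd.drop(constant)
    if matrix.shape[1] == 0:
        raise ValueError("no non-degenerate columns left to standardize")
    return (matrix - matrix.mean()) / sd


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise L2 distances between rows, as a labelled square frame."""
    dist = squareform(pdist(matrix.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(dist, index=matrix.index, columns=matrix.index)


def ward_linkage(matrix: pd.DataFrame, variant: str = "D2") -> np.ndarray:
    """Ward agglomeration of the rows of a standardized matrix.

    ``"D2"`` (default) applies the Ward criterion to Euclidean distances
    (squared inside the criterion); ``"D"`` is the classical variant run
    on squared dissimilarities.
    """
    condensed = pdist(matrix.to_numpy(dtype=float), metric="euclidean")
    if variant == "D2":
        return hierarchy.linkage(condensed, method="ward")
    if variant == "D":
        return hierarchy.linkage(condensed**2, method="ward")
    raise ValueError(f"unknown Ward variant {variant!r}")


def cut_clusters(linkage: np.ndarray, k: int, labels) -> pd.Series:
    """Cluster labels (1..k) at a k-group cut of the dendrogram."""
    n = linkage.shape[0] + 1
    if k > n:
        raise ValueError(f"cannot cut {n} leaves into {k} clusters")
    assignments = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return pd.Series(assignments, index=labels, name="cluster")


@dataclass
class PcaResult:
    """Correlation-matrix PCA: scores, biplot loadings, percent variance."""

    scores: pd.DataFrame        # genotypes x components
    loadings: pd.DataFrame      # traits x components, scaled by sqrt(eigenvalue)
    eigenvectors: pd.DataFrame  # traits x components, unit length
    eigenvalues: np.ndarray
    pct_variance: np.ndarray


def pca_biplot(standardized: pd.DataFrame) -> PcaResult:
    """Eigendecomposition of the column correlation matrix.

    Components are ordered by decreasing eigenvalue; each component's sign
    is fixed so its largest-magnitude loading is positive.  Scores are the
    standardized data projected on the unit eigenvectors (distance
    scaling); ``loadings`` carry the sqrt-eigenvalue scaling used for the
    biplot arrows.
    """
    z = standardized.to_numpy(dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    corr = np.corrcoef(z, rowvar=False)
    corr = np.atleast_2d(corr)
    vals, vecs = np.linalg.eigh(corr)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
    if vals.sum() <= 0:
        raise ValueError("degenerate (rank-0) input: no variance to decompose")
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    comps = [f"PC{i+1}" for i in range(len(vals))]
    scores = pd.DataFrame(z @ vecs, index=standardized.index, columns=comps)
    eigenvectors = pd.DataFrame(vecs, index=standardized.columns, columns=comps)
    loadings = eigenvectors * np.sqrt(vals)
    pct = 100.0 * vals / vals.sum()
    return PcaResult(
        scores=scores,
        loadings=loadings,
        eigenvectors=eigenvectors,
        eigenvalues=vals,
        pct_variance=pct,
    )


def heatmap_bins(
    standardized: pd.DataFrame,
    row_linkage: np.ndarray,
    col_linkage: np.ndarray,
    n_bins: int = 9,
) -> pd.DataFrame:
    """Integer colour bins with rows/columns in dendrogram leaf order.

    Values are binned into ``n_bins`` equal-width bins over the global
    matrix range; bin 0 is the minimum, ``n_bins - 1`` the maximum.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    row_order = hierarchy.leaves_list(row_linkage)
    col_order = hierarchy.leaves_list(col_linkage)
    ordered = standardized.iloc[row_order, col_order]
    vals = ordered.to_numpy(dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        bins = np.zeros_like(vals, dtype=int)
    else:
        bins = np.clip(((vals - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    return pd.DataFrame(bins, index=ordered.index, columns=ordered.columns)


@dataclass
class ScreeningBundle:
    """Everything the genotype-screening stage derives from one condition."""

    z: pd.DataFrame
    distances: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    clusters: pd.Series
    pca: PcaResult
    bins: pd.DataFrame
    k: int
    ward_variant: str


def build_screening_bundle(
    means: pd.DataFrame,
    k: int = 3,
    ward_variant: str = "D2",
    n_bins: int = 9,
) -> ScreeningBundle:
    """Standardize genotype means and derive the full screening bundle."""
    z = zscore(means)
    dist = euclidean_distances(z)
    row_link = ward_linkage(z, variant=ward_variant)
    col_link = ward_linkage(z.T, variant=ward_variant)
    clusters = cut_clusters(row_link, k, z.index)
    pca = pca_biplot(z)
    bins = heatmap_bins(z, row_link, col_link, n_bins=n_bins)
    return ScreeningBundle(
        z=z,
        distances=dist,
        row_linkage=row_link,
        col_linkage=col_link,
        clusters=clusters,
        pca=pca,
        bins=bins,
        k=k,
        ward_variant=ward_variant,
    )


@dataclass
class ContrastPair:
    """The tolerant/susceptible genotype pair plus its selection trace."""

    high: str
    low: str
    alternates_high: tuple[str, ...]
    alternates_low: tuple[str, ...]
    trace: dict = field(default_factory=dict)


def _target_direction(pca: PcaResult, target_traits) -> np.ndarray:
    present = [t for t in target_traits if t in pca.loadings.index]
    if not present:
        raise ValueError(f"none of the target traits {list(target_traits)} in loadings")
    direction = pca.loadings.loc[present, ["PC1", "PC2"]].mean(axis=0).to_numpy()
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("target traits have a zero loading direction")
    return direction / norm


def select_contrast_pair(
    bundle: ScreeningBundle,
    target_traits=("SOD", "Yld"),
) -> ContrastPair:
    """Pick the maximum-distance contrast pair, oriented and tie-broken by
    target-trait biplot proximity and means (see module docstring)."""
    clusters = bundle.clusters
    if clusters.nunique() < 2:
        raise ValueError("all genotypes fall in one cluster: no contrast possible")
    labels = list(bundle.distances.index)
    dist = bundle.distances.to_numpy()
    same = (
        clusters.loc[labels].to_numpy()[:, None]
        == clusters.loc[labels].to_numpy()[None, :]
    )
    masked = np.where(same, -np.inf, dist)
    flat = int(np.argmax(masked))  # first occurrence = lexicographic tie-break
    i, j = divmod(flat, len(labels))
    a, b = labels[i], labels[j]

    direction = _target_direction(bundle.pca, target_traits)
    proj = pd.Series(
        bundle.pca.scores[["PC1", "PC2"]].to_numpy() @ direction,
        index=bundle.pca.scores.index,
    )
    present = [t for t in target_traits if t in bundle.z.columns]
    target_mean = bundle.z[present].mean(axis=1)

    if proj[a] >= proj[b]:
        hi_seed, lo_seed = a, b
    else:
        hi_seed, lo_seed = b, a

    def side(seed: str, sign: float) -> list[str]:
        members = clusters.index[clusters == clusters[seed]]
        return sorted(
            members,
            key=lambda g: (-sign * proj[g], -sign * target_mean[g], g),
        )

    hi_rank = side(hi_seed, +1.0)
    lo_rank = side(lo_seed, -1.0)
    high, low = hi_rank[0], lo_rank[0]
    return ContrastPair(
        high=high,
        low=low,
        alternates_high=tuple(g for g in hi_rank if g != high),
        alternates_low=tuple(g for g in lo_rank if g != low),
        trace={
            "max_distance": float(dist[i, j]),
            "distance_pair": (a, b),
            "projection": proj.to_dict(),
            "target_trait_mean_z": target_mean.to_dict(),
        },
    )


def select_contrast_pair_by_priority(
    bundles: Mapping[str, ScreeningBundle],
    target_traits=("SOD", "Yld"),
    priority=("stress", "normal"),
) -> ContrastPair:
    """Contrast pair across conditions; the first condition in ``priority``
    that was screened decides, the others are recorded in the trace."""
    picks = {
        cond: select_contrast_pair(bundles[cond], target_traits)
        for cond in priority
        if cond in bundles
    }
    if not picks:
        raise ValueError(f"no screened condition among priority {list(priority)}")
    deciding = next(iter(picks))
    final = picks[deciding]
    final.trace["deciding_condition"] = deciding
    final.trace["per_condition"] = {
        cond: (p.high, p.low) for cond, p in picks.items()
    }
    return final
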
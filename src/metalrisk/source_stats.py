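"""Source-apportionment statistics on site × element matrices.

Three standard multivariate views of a concentration survey:

* Pearson correlation between elements, with two-tailed p-values from the
  t transform on n−2 degrees of freedom and 0.05/0.01 significance flags —
  strongly co-varying elements suggest a shared (often anthropogenic) source;
* PCA on the correlation matrix of the elements (variables standardised to
  zero mean / unit variance), eigenvalues reported as fractions of total
  variance, component signs fixed so the largest-magnitude loading is
  positive;
* agglomerative Ward clustering of the site profiles (squared-Euclidean
  criterion, scipy linkage), grouping outfalls with similar element release.

Clustering operates on raw site profiles by default, matching the common
statistical-package default for these surveys; pass ``standardize=True`` to
z-score each element first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core_data import ConcentrationTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationResult",
    "PCAResult",
    "LinkageTree",
    "pearson_matrix",
    "pca_correlation",
    "ward_cluster",
    "cut",
    "to_newick",
]


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    flags: pd.DataFrame  # "", "p<0.05" or "p<0.01"


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    loadings: pd.DataFrame  # element × component
    n_components_retained: int


@dataclass
class LinkageTree:
    merges: np.ndarray  # scipy linkage matrix (n-1) × 4
    labels: list[str]


def pearson_matrix(table: ConcentrationTable) -> CorrelationResult:
    """Element × element Pearson correlation with two-tailed p-values."""
    df = table.values
    n = len(df)
    if n < 3:
        raise ValueError("Pearson inference needs at least 3 observations")
    constant = df.columns[df.std(ddof=1) == 0].tolist()
    if constant:
        logger.warning("constant column(s) %s: correlations reported as NaN", constant)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
        r = np.clip(r, -1.0, 1.0)
        np.fill_diagonal(r, 1.0)
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p = np.where(np.isnan(r), np.nan, p)
    r_df = pd.DataFrame(r, index=df.columns, columns=df.columns)
    p_df = pd.DataFrame(p, index=df.columns, columns=df.columns)
    flags = p_df.map(
        lambda v: "" if pd.isna(v) else
        "p<0.01" if v < 0.01 else "p<0.05" if v < 0.05 else "ns"
    )
    return CorrelationResult(r=r_df, p=p_df, n=n, flags=flags)


def pca_correlation(
    table: ConcentrationTable, n_components: int | None = None
) -> PCAResult:
    """Eigendecomposition of the element correlation matrix.

    Constant columns are dropped with a logged notice.  Eigenvalues are
    returned descending; loadings columns are the orthonormal eigenvectors
    with signs fixed so each component's largest-|loading| entry is positive.
    """
    df = table.values
    constant = df.columns[df.std(ddof=1) == 0].tolist()
    if constant:
        logger.warning("dropping constant column(s) from PCA: %s", constant)
        df = df.drop(columns=constant)
    if df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 non-constant variables")
    corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        if eigvec[np.argmax(np.abs(eigvec[:, j])), j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    k = n_components if n_components is not None else eigvec.shape[1]
    loadings = pd.DataFrame(
        eigvec,
        index=df.columns,
        columns=[f"PC{i + 1}" for i in range(eigvec.shape[1])],
    )
    return PCAResult(
        eigenvalues=eigval,
        variance_fraction=eigval / eigval.sum(),
        loadings=loadings,
        n_components_retained=int(k),
    )


def ward_cluster(table: ConcentrationTable, standardize: bool = False) -> LinkageTree:
    """Ward minimum-variance linkage over the site profiles."""
    df = table.values
    if len(df) < 2:
        raise ValueError("clustering needs at least 2 sites")
    x = df.to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    merges = hierarchy.linkage(x, method="ward")
    return LinkageTree(merges=merges, labels=[str(s) for s in df.index])


def cut(tree: LinkageTree, k: int) -> pd.Series:
    """Flat k-group assignment (site → cluster id) from a linkage tree."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    labels = hierarchy.fcluster(tree.merges, t=k, criterion="maxclust")
    return pd.Series(labels, index=tree.labels, name="cluster")


def to_newick(tree: LinkageTree) -> str:
    """Newick text export of the dendrogram with merge heights as branch lengths."""
    root = hierarchy.to_tree(tree.merges)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:g}"
        return f"({walk(node.left, node.dist)},{walk(node.right, node.dist)}):{length:g}"

    return f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"
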
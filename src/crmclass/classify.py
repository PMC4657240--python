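"""PCA of the binding matrix, significant-component selection, and Ward
clustering of the component scores into classes.

Columns are centred and scaled to unit variance, so the PCA works on the
correlation structure of the datasets.  The published parameterization keeps
a fixed number of components (four); a broken-stick rule is available as the
data-driven alternative.  Classes come from cutting a Ward (D2 convention)
dendrogram of the retained scores, numbered by dendrogram leaf order
(leftmost leaf block = class 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from .features import BindingMatrix

logger = logging.getLogger("crmclass")


@dataclass
class ClassModel:
    """Fitted PCA + clustering state for a set of observations."""

    observation_ids: list[str]
    variable_ids: list[str]
    col_means: np.ndarray
    col_scales: np.ndarray
    scores: np.ndarray          # observations × components
    loadings: np.ndarray        # components × variables
    explained_variance: np.ndarray
    n_significant: int | None = None
    linkage_tree: np.ndarray | None = None
    labels: np.ndarray | None = None
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def explained_fraction(self) -> np.ndarray:
        return self.explained_variance / self.explained_variance.sum()


def fit_pca(matrix: BindingMatrix | pd.DataFrame) -> ClassModel:
    """Unit-variance PCA via SVD of the standardized matrix.

    Zero-variance columns are dropped with a warning (all-zero-variance is
    an error).  Component signs are fixed so the largest-magnitude loading
    of each component is positive, making the fit deterministic.
    """
    df = matrix.df if isinstance(matrix, BindingMatrix) else matrix
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("PCA needs at least 2 observations and 2 variables")
    X = df.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    # tolerance absorbs float round-off in constant columns
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    dropped = list(df.columns[~keep])
    if not keep.any():
        raise ValueError("all columns have zero variance")
    if dropped:
        logger.warning("dropping %d zero-variance column(s): %s", len(dropped), dropped)
    X = X[:, keep]
    mu = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    Z = (X - mu) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    for i in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    n = Z.shape[0]
    return ClassModel(
        observation_ids=list(df.index),
        variable_ids=list(df.columns[keep]),
        col_means=mu,
        col_scales=scale,
        scores=U * s,
        loadings=Vt,
        explained_variance=s ** 2 / (n - 1),
        dropped_columns=dropped,
    )


def broken_stick_fractions(p: int) -> np.ndarray:
    """Expected variance fractions of p ordered segments of a broken stick."""
    return np.array([np.sum(1.0 / np.arange(k, p + 1)) / p for k in range(1, p + 1)])


def select_components(model: ClassModel, method: str = "fixed", k: int = 4) -> int:
    """Number of components to retain.

    ``fixed``: return k.  ``broken_stick``: leading components whose
    explained-variance fraction exceeds the broken-stick expectation
    (counted from the first, stopping at the first failure; at least 1).
    ``kaiser``: count of eigenvalues > 1.
    """
    p = len(model.explained_variance)
    if method == "fixed":
        if not (1 <= k <= p):
            raise ValueError(f"fixed k={k} outside [1, {p}]")
        n_sig = k
    elif method == "broken_stick":
        frac = model.explained_fraction
        expect = broken_stick_fractions(p)
        n_sig = 0
        for f, e in zip(frac, expect):
            if f > e:
                n_sig += 1
            else:
                break
        n_sig = max(n_sig, 1)
    elif method == "kaiser":
        n_sig = max(int(np.sum(model.explained_variance > 1.0)), 1)
    else:
        raise ValueError(f"unknown selection method {method!r}")
    model.n_significant = n_sig
    return n_sig


def cluster_classes(model: ClassModel, n_classes: int = 9,
                    n_components: int | None = None) -> np.ndarray:
    """Ward clustering of the retained component scores, cut to
    ``n_classes``; labels 1..n_classes assigned by dendrogram leaf order."""
    if n_classes < 1:
        raise ValueError("n_classes must be at least 1")
    n_obs = model.scores.shape[0]
    if n_classes > n_obs:
        raise ValueError("more classes than observations")
    k = n_components or model.n_significant or model.scores.shape[1]
    S = model.scores[:, :k]
    Z = linkage(S, method="ward")
    raw = fcluster(Z, t=n_classes, criterion="maxclust")
    labels = _relabel_by_leaf_order(Z, raw)
    model.linkage_tree = Z
    model.labels = labels
    return labels


def _relabel_by_leaf_order(Z: np.ndarray, raw: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    nxt = 1
    for leaf in leaves_list(Z):
        c = int(raw[leaf])
        if c not in mapping:
            mapping[c] = nxt
            nxt += 1
    return np.array([mapping[int(c)] for c in raw])


def classify(matrix: BindingMatrix | pd.DataFrame, n_classes: int = 9,
             selection: str = "fixed", k: int = 4) -> ClassModel:
    """fit_pca → select_components → cluster_classes in one call."""
    model = fit_pca(matrix)
    n_sig = select_components(model, selection,
                              k=min(k, len(model.explained_variance)))
    cluster_classes(model, n_classes=n_classes, n_components=n_sig)
    return model
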
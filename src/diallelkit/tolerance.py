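"""Drought-tolerance indices and cluster-based tolerance grouping.

From each genotype's mean grain yield under non-stress (Y_p) and stress
(Y_s), four indices are computed:

    GMP = sqrt(Y_s * Y_p)          geometric mean productivity
    MP  = (Y_s + Y_p) / 2          mean productivity
    YI  = Y_s / mean(Y_s)          yield index
    STI = Y_s * Y_p / mean(Y_p)^2  stress tolerance index

Genotypes are then grouped by Ward-linkage agglomerative clustering on the
z-scored indices and the k clusters are labelled A (most tolerant) through
E (most sensitive) by descending cluster mean of the standardized indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .errors import ConfigError, DiallelError

INDEX_COLUMNS = ("gmp", "mp", "yi", "sti")


def tolerance_indices(yields_p: pd.Series, yields_s: pd.Series) -> pd.DataFrame:
    """Per-genotype tolerance indices from stress / non-stress yield means.

    Both series must be positive and indexed by the same entries.  Returns a
    DataFrame with columns ``y_p, y_s, gmp, mp, yi, sti``.
    """
    yields_p = pd.Series(yields_p, dtype=float)
    yields_s = pd.Series(yields_s, dtype=float)
    if set(yields_p.index) != set(yields_s.index):
        raise KeyError("yields_p and yields_s must cover the same entries")
    yields_s = yields_s.reindex(yields_p.index)
    if (yields_p <= 0).any() or (yields_s <= 0).any():
        raise DiallelError("yields must be strictly positive (GMP is undefined otherwise)")
    y_p = yields_p.to_numpy()
    y_s = yields_s.to_numpy()
    out = pd.DataFrame(
        {
            "y_p": y_p,
            "y_s": y_s,
            "gmp": np.sqrt(y_s * y_p),
            "mp": (y_s + y_p) / 2.0,
            "yi": y_s / y_s.mean(),
            "sti": (y_s * y_p) / y_p.mean() ** 2,
        },
        index=yields_p.index,
    )
    return out


def _group_letters(k: int) -> list[str]:
    if k <= 26:
        return [chr(ord("A") + i) for i in range(k)]
    raise ConfigError("at most 26 tolerance groups are supported")


class ToleranceClassifier(BaseEstimator):
    """Ward-linkage clustering of genotypes in tolerance-index space.

    Parameters
    ----------
    n_groups : int, default 5
        Number of groups to cut the dendrogram into (the drought study uses
        five, A through E).
    linkage : str, default "ward"
        Any scipy hierarchical linkage method.
    standardize : bool, default True
        z-score each index column before computing Euclidean distances.

    Attributes
    ----------
    labels_ : ndarray of group letters per row of the fitted table.
    groups_ : pd.Series of letters indexed like the input.
    linkage_matrix_ : scipy linkage matrix (for dendrograms / newick export).
    cluster_means_ : pd.Series mean standardized index per group, descending.
    """

    def __init__(self, n_groups: int = 5, linkage: str = "ward", standardize: bool = True):
        self.n_groups = n_groups
        self.linkage = linkage
        self.standardize = standardize

    def fit(self, X: pd.DataFrame, y=None) -> "ToleranceClassifier":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        cols = [c for c in INDEX_COLUMNS if c in X.columns] or list(X.columns)
        table = X[cols].astype(float)
        n = len(table)
        if self.n_groups < 1 or self.n_groups > n:
            raise ConfigError(
                f"n_groups must be between 1 and the number of entries ({n}), got {self.n_groups}"
            )
        values = table.to_numpy()
        if self.standardize:
            sd = values.std(axis=0, ddof=0)
            if np.any(sd == 0):
                bad = [cols[i] for i in np.flatnonzero(sd == 0)]
                raise DiallelError(f"zero-variance index column(s) {bad}: cannot standardize")
            z = (values - values.mean(axis=0)) / sd
        else:
            z = values

        # deterministic tie-break: process rows in lexicographic entry order
        order = np.argsort([str(i) for i in table.index], kind="stable")
        zo = z[order]
        link = hierarchy.linkage(pdist(zo, metric="euclidean"), method=self.linkage)
        flat = hierarchy.fcluster(link, t=self.n_groups, criterion="maxclust")

        # rank clusters by mean standardized index, A = highest
        score = pd.Series(zo.mean(axis=1)).groupby(flat).mean()
        entry_of = [str(table.index[order[i]]) for i in range(n)]
        first_entry = pd.Series(entry_of).groupby(flat).min()
        rank = sorted(score.index, key=lambda c: (-score[c], first_entry[c]))
        letters = _group_letters(self.n_groups)
        letter_of = {c: letters[i] for i, c in enumerate(rank)}

        labels_sorted = np.array([letter_of[c] for c in flat], dtype=object)
        labels = np.empty(n, dtype=object)
        labels[order] = labels_sorted
        self.labels_ = labels
        self.groups_ = pd.Series(labels, index=table.index, name="group")
        self.linkage_matrix_ = link
        # leaf id i of the linkage refers to the i-th row in lexicographic order
        self._leaf_names_ = [str(table.index[o]) for o in order]
        self.leaf_order_ = [table.index[order[i]] for i in hierarchy.leaves_list(link)]
        self.cluster_means_ = pd.Series(
            {letter_of[c]: score[c] for c in score.index}
        ).sort_values(ascending=False)
        self.feature_names_in_ = np.asarray(cols, dtype=object)
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_


def classify_tolerance(
    table: pd.DataFrame,
    k: int = 5,
    linkage: str = "ward",
    standardize: bool = True,
) -> pd.DataFrame:
    """Append a tolerance ``group`` column (A..E) to an index table."""
    model = ToleranceClassifier(n_groups=k, linkage=linkage, standardize=standardize).fit(table)
    out = table.copy()
    out["group"] = model.groups_
    return out


def dendrogram_newick(model: ToleranceClassifier, leaf_names: list[str] | None = None) -> str:
    """Serialize the fitted Ward dendrogram as a newick string with heights."""
    link = model.linkage_matrix_
    names = [str(x) for x in (leaf_names if leaf_names is not None else model._leaf_names_)]
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
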
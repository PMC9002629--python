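"""Stress-response summaries and trait-association analyses.

Covers the three regime-comparison analyses of the trial: per-trait percent
change under water deficit relative to well-watered conditions, the trait
x trait Pearson correlation matrix on entry means, and correlation-matrix
PCA of the entry-mean matrix (traits z-scored) for biplots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

from .datamodel import PhenotypePanel
from .errors import DiallelError, UnknownLabelError

logger = logging.getLogger(__name__)


@dataclass
class CorrelationResult:
    """Pearson trait-trait correlations on entry means, heatmap-ordered."""

    r: pd.DataFrame
    p: pd.DataFrame
    order: list[str]  # hierarchical-clustering leaf order of |r|


@dataclass
class AssociationResult:
    percent_change: pd.Series
    correlations: CorrelationResult
    pca: "TraitPCA"


def percent_change(
    panel: PhenotypePanel,
    control: str | None = None,
    stress: str | None = None,
) -> pd.Series:
    """Per-trait percent change of the grand mean under stress vs control.

    ``100 * (stress_mean - control_mean) / control_mean`` over all entries
    and blocks; negative values are reductions.  Regimes default to the
    panel's first (control) and second (stress) labels.
    """
    regimes = panel.design.regimes
    if control is None or stress is None:
        if len(regimes) < 2:
            raise UnknownLabelError("panel has fewer than two regimes")
        control = control or regimes[0]
        stress = stress or regimes[1]
    out = {}
    for trait in panel.traits:
        c = panel.observations(trait, control)["value"].mean()
        s = panel.observations(trait, stress)["value"].mean()
        if c == 0:
            raise DiallelError(f"trait {trait!r}: control mean is zero, percent change undefined")
        out[trait] = 100.0 * (s - c) / c
    return pd.Series(out, name="percent_change")


def entry_mean_matrix(panel: PhenotypePanel, regime: str) -> pd.DataFrame:
    """Entries x traits matrix of block means for one regime."""
    cols = {t: panel.entry_means(t, regime).means for t in panel.traits}
    mat = pd.DataFrame(cols)
    mat.index = [str(k) for k in panel.design.entries()]
    return mat


class TraitPCA(BaseEstimator):
    """Correlation-matrix PCA of an entries x traits mean matrix.

    Columns are z-scored before the eigendecomposition, so the analysis is
    invariant to affine rescaling of any trait.  Zero-variance columns are
    dropped with a warning.  The sign of each component is fixed by making
    its largest-magnitude loading positive.

    Attributes
    ----------
    loadings_ : DataFrame (trait x component), correlation-scaled
        (eigenvector * sqrt(eigenvalue)), so loadings_ @ loadings_.T
        reproduces the trait correlation matrix when all components are kept.
    scores_ : DataFrame (entry x component) of standardized-data projections.
    explained_variance_ratio_ : ndarray, non-increasing, summing to 1.
    dropped_traits_ : list of zero-variance columns removed before fitting.
    """

    def __init__(self, n_components: int | None = None):
        self.n_components = n_components

    def fit(self, X: pd.DataFrame, y=None) -> "TraitPCA":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if X.shape[0] < 3 or X.shape[1] < 2:
            raise DiallelError("PCA needs at least 3 entries and 2 traits")
        sd = X.std(axis=0, ddof=1)
        dropped = list(sd.index[sd == 0])
        if dropped:
            logger.warning("dropping zero-variance trait(s) before PCA: %s", dropped)
        keep = [c for c in X.columns if c not in dropped]
        if len(keep) < 2:
            raise DiallelError("fewer than two traits with variance; PCA impossible")
        Z = (X[keep] - X[keep].mean(axis=0)) / X[keep].std(axis=0, ddof=1)

        n_comp = self.n_components or min(Z.shape[0] - 1, Z.shape[1])
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(Z.to_numpy())
        components = pca.components_  # (k, n_traits) eigenvectors

        # deterministic sign: largest-|loading| element of each PC positive
        for k in range(components.shape[0]):
            j = int(np.argmax(np.abs(components[k])))
            if components[k, j] < 0:
                components[k] *= -1
                scores[:, k] *= -1

        eigvals = pca.explained_variance_
        names = [f"PC{k + 1}" for k in range(n_comp)]
        self.loadings_ = pd.DataFrame(
            (components * np.sqrt(eigvals)[:, None]).T, index=keep, columns=names
        )
        self.eigenvectors_ = pd.DataFrame(components.T, index=keep, columns=names)
        self.scores_ = pd.DataFrame(scores, index=X.index, columns=names)
        self.explained_variance_ = eigvals
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.dropped_traits_ = dropped
        self.feature_names_in_ = np.asarray(keep, dtype=object)
        self._pca = pca
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        keep = list(self.feature_names_in_)
        if isinstance(X, pd.DataFrame):
            X = X[keep]
        return self._pca.transform(np.asarray(X, dtype=float))

    def biplot_coordinates(self, scale: float | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Scores and scaled loadings for a PC1/PC2 biplot."""
        scores = self.scores_.iloc[:, :2]
        loads = self.loadings_.iloc[:, :2]
        if scale is None:
            scale = float(np.abs(scores.to_numpy()).max() / max(np.abs(loads.to_numpy()).max(), 1e-12))
        return scores, loads * scale


def trait_pca(panel: PhenotypePanel, regime: str, n_components: int | None = None) -> TraitPCA:
    """Fit :class:`TraitPCA` on the entry-mean matrix of one regime."""
    return TraitPCA(n_components=n_components).fit(entry_mean_matrix(panel, regime))


def trait_correlations(panel: PhenotypePanel, regime: str) -> CorrelationResult:
    """Pearson r and two-sided p per trait pair on entry means.

    Exact anticorrelation/correlation yields p reported as 0 (below 1e-15).
    Trait order for heatmap rendering comes from average-linkage clustering
    of 1 - |r|.
    """
    mat = entry_mean_matrix(panel, regime)
    sd = mat.std(axis=0, ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        logger.warning("dropping zero-variance trait(s) before correlation: %s", dropped)
        mat = mat.drop(columns=dropped)
    traits = list(mat.columns)
    k = len(traits)
    if k < 2:
        raise DiallelError("need at least two traits with variance")
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(mat.iloc[:, i], mat.iloc[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    r_df = pd.DataFrame(r, index=traits, columns=traits)
    p_df = pd.DataFrame(p, index=traits, columns=traits)
    dist = squareform(np.clip(1.0 - np.abs(r), 0.0, None), checks=False)
    link = hierarchy.linkage(dist, method="average")
    order = [traits[i] for i in hierarchy.leaves_list(link)]
    return CorrelationResult(r=r_df, p=p_df, order=order)


def associations(
    panel: PhenotypePanel,
    regime: str | None = None,
) -> AssociationResult:
    """Full association bundle: percent change, correlations, PCA.

    ``regime`` defaults to the stress (second) regime, where the trait
    relationships of interest are interpreted.
    """
    regime = regime or panel.design.regimes[-1]
    return AssociationResult(
        percent_change=percent_change(panel),
        correlations=trait_correlations(panel, regime),
        pca=trait_pca(panel, regime),
    )
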
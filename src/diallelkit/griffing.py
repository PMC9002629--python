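"""Griffing method-2 model-1 combining-ability analysis.

Method 2 analyses the ``p(p+1)/2`` entry means of a half diallel (parents
plus one set of F1s, no reciprocals); model 1 treats parents as fixed, so
all F tests use the plot-error mean square of the accompanying RCBD ANOVA,
divided by the number of blocks to put it on the entry-mean scale.

With ``x_ij`` the symmetric matrix of entry means, ``Y_i = sum_j x_ij`` the
array totals and ``Y.. = sum_{i<=j} x_ij``::

    mu  = 2 Y.. / (p(p+1))
    g_i = [ (Y_i + x_ii) - (2/p) Y.. ] / (p+2)
    s_ij = x_ij - (Y_i + x_ii + Y_j + x_jj)/(p+2) + 2 Y.. / ((p+1)(p+2))
    s_ii = x_ii - 2 (Y_i + x_ii)/(p+2)           + 2 Y.. / ((p+1)(p+2))

which satisfy ``sum_i g_i = 0``, per-array ``sum_j s_ij + s_ii = 0`` and the
saturation identity ``x_ij = mu + g_i + g_j + s_ij`` (``x_ii = mu + 2 g_i +
s_ii``).  GCA and SCA sums of squares decompose the total entry-mean SS
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import HIGHER, LOWER, TraitMeanTable
from .errors import ConfigError, DesignError

FAVORABLE = "favorable-significant"
UNFAVORABLE = "unfavorable-significant"
NONSIG = "non-significant"


def decompose_means(x: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, float, float]:
    """Closed-form method-2 decomposition of a symmetric entry-mean matrix.

    Returns ``(mu, g, s, ss_gca, ss_sca)``.  This is the exact projection of
    the means onto the saturated (mu, g, s) parametrization under the
    constraints ``sum g = 0`` and ``sum_j s_ij + s_ii = 0``.
    """
    x = np.asarray(x, dtype=float)
    p = x.shape[0]
    scale = max(1.0, float(np.abs(x).max())) if x.size else 1.0
    if x.ndim != 2 or x.shape != (p, p) or not np.allclose(x, x.T, rtol=0, atol=1e-9 * scale):
        raise ValueError("x must be a symmetric p x p matrix of entry means")
    x = (x + x.T) / 2.0  # remove float-level asymmetry
    iu = np.triu_indices(p)
    y_dot = float(x[iu].sum())
    y_i = x.sum(axis=1)
    diag = np.diag(x)
    t = y_i + diag  # array totals Y_i + x_ii

    mu = 2.0 * y_dot / (p * (p + 1))
    g = (t - 2.0 * y_dot / p) / (p + 2)
    c = 2.0 * y_dot / ((p + 1) * (p + 2))
    s = x - (t[:, None] + t[None, :]) / (p + 2) + c
    np.fill_diagonal(s, diag - 2.0 * t / (p + 2) + c)

    ss_gca = (float((t**2).sum()) - 4.0 * y_dot**2 / p) / (p + 2)
    ss_sca = float((x[iu] ** 2).sum()) - float((t**2).sum()) / (p + 2) + y_dot**2 * 2.0 / (
        (p + 1) * (p + 2)
    )
    return mu, g, s, ss_gca, ss_sca


@dataclass
class CombiningAbilityResult:
    """Combining-ability estimates and tests for one trait under one regime.

    ``gca`` is indexed by parent label; ``sca`` is the symmetric DataFrame of
    s_ij with selfed-parent s_ii on the diagonal.  Standard errors and LSDs
    are for a single effect against zero; ``se_gi_diff`` is the SE of a
    difference g_i - g_j, exposed separately.
    """

    trait: str
    regime: str
    parents: tuple[str, ...]
    mu_hat: float
    gca: pd.Series
    sca: pd.DataFrame
    ss_gca: float
    ss_sca: float
    df_gca: int
    df_sca: int
    ms_gca: float
    ms_sca: float
    ms_error_term: float
    df_error: int
    f_gca: float
    f_sca: float
    p_gca: float
    p_sca: float
    gca_sca_ratio: float
    baker_ratio: float
    se_gi: float
    se_sij: float
    se_sii: float
    se_gi_diff: float
    lsd_gi_05: float
    lsd_gi_01: float
    lsd_sij_05: float
    lsd_sij_01: float
    direction: str = HIGHER

    def lsd_gi(self, alpha: float) -> float:
        if alpha == 0.05:
            return self.lsd_gi_05
        if alpha == 0.01:
            return self.lsd_gi_01
        raise ConfigError(f"alpha must be 0.05 or 0.01, got {alpha}")

    def lsd_sij(self, alpha: float) -> float:
        if alpha == 0.05:
            return self.lsd_sij_05
        if alpha == 0.01:
            return self.lsd_sij_01
        raise ConfigError(f"alpha must be 0.05 or 0.01, got {alpha}")


class GriffingMethod2(BaseEstimator):
    """Griffing method-2 model-1 estimator on half-diallel entry means.

    Parameters
    ----------
    n_blocks : int
        Replications r behind each entry mean; the plot-error MS is divided
        by r to give the error term on the mean scale.

    Attributes (after ``fit``)
    --------------------------
    mu_, gca_, sca_ : grand mean, parent effects (Series), symmetric SCA
        effect matrix (DataFrame, diagonal = s_ii).
    result_ : CombiningAbilityResult with SS/MS/F/p, ratio, SEs and LSDs.
    """

    def __init__(self, n_blocks: int = 3):
        self.n_blocks = n_blocks

    def fit(
        self,
        X: TraitMeanTable,
        y=None,
        *,
        plot_error_ms: float,
        error_df: int,
    ) -> "GriffingMethod2":
        means = X
        design = means.design
        p = design.n_parents
        if p < 3:
            raise DesignError("combining-ability analysis needs at least three parents")
        if plot_error_ms < 0:
            raise ConfigError("plot_error_ms must be non-negative")
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be positive")
        x = means.matrix()
        mu, g, s, ss_gca, ss_sca = decompose_means(x)

        df_gca = p - 1
        df_sca = p * (p - 1) // 2
        ms_gca = ss_gca / df_gca
        ms_sca = ss_sca / df_sca
        err = plot_error_ms / self.n_blocks  # error term on the entry-mean scale

        if err > 0:
            f_gca = ms_gca / err
            f_sca = ms_sca / err
            p_gca = float(stats.f.sf(f_gca, df_gca, error_df))
            p_sca = float(stats.f.sf(f_sca, df_sca, error_df))
        else:
            f_gca = f_sca = float("nan")
            p_gca = p_sca = 1.0
        ratio = ms_gca / ms_sca if ms_sca > 0 else float("nan")

        # Baker (1978) predictability ratio from the fixed-model MS, offered
        # as a named alternative to the plain MS ratio.
        denom = 2.0 * ms_gca + ms_sca
        baker = 2.0 * ms_gca / denom if denom > 0 else float("nan")

        var_gi = err * (p - 1) / (p * (p + 2))
        var_sij = err * (p * p + p + 2) / ((p + 1) * (p + 2))
        var_sii = err * p * (p - 1) / ((p + 1) * (p + 2))
        var_gi_diff = 2.0 * err / (p + 2)
        se_gi, se_sij, se_sii = np.sqrt([var_gi, var_sij, var_sii])
        se_gi_diff = float(np.sqrt(var_gi_diff))
        t05 = float(stats.t.ppf(0.975, error_df))
        t01 = float(stats.t.ppf(0.995, error_df))

        parents = design.parent_ids
        self.mu_ = mu
        self.gca_ = pd.Series(g, index=list(parents), name="gca")
        self.sca_ = pd.DataFrame(s, index=list(parents), columns=list(parents))
        self.result_ = CombiningAbilityResult(
            trait=means.trait,
            regime=means.regime,
            parents=parents,
            mu_hat=mu,
            gca=self.gca_,
            sca=self.sca_,
            ss_gca=ss_gca,
            ss_sca=ss_sca,
            df_gca=df_gca,
            df_sca=df_sca,
            ms_gca=ms_gca,
            ms_sca=ms_sca,
            ms_error_term=err,
            df_error=error_df,
            f_gca=f_gca,
            f_sca=f_sca,
            p_gca=p_gca,
            p_sca=p_sca,
            gca_sca_ratio=ratio,
            baker_ratio=baker,
            se_gi=float(se_gi),
            se_sij=float(se_sij),
            se_sii=float(se_sii),
            se_gi_diff=se_gi_diff,
            lsd_gi_05=t05 * float(se_gi),
            lsd_gi_01=t01 * float(se_gi),
            lsd_sij_05=t05 * float(se_sij),
            lsd_sij_01=t01 * float(se_sij),
        )
        return self


def griffing_method2(
    means: TraitMeanTable,
    plot_error_ms: float,
    error_df: int,
    r: int,
) -> CombiningAbilityResult:
    """Run the method-2 model-1 analysis on one trait x regime mean table."""
    est = GriffingMethod2(n_blocks=r).fit(means, plot_error_ms=plot_error_ms, error_df=error_df)
    return est.result_


def _label(effect: float, lsd: float, direction: str) -> str:
    if abs(effect) <= lsd:  # effect exactly at the LSD is not significant
        return NONSIG
    favorable = effect > 0 if direction == HIGHER else effect < 0
    return FAVORABLE if favorable else UNFAVORABLE


def classify_combiners(
    result: CombiningAbilityResult,
    alpha: float = 0.05,
    direction: str | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Label each GCA and SCA effect by significance and desirability.

    Effects larger in magnitude than the LSD at ``alpha`` are significant;
    the favorable sign is positive for higher-is-better traits and negative
    for lower-is-better traits (plant height).  Returns ``(parent_labels,
    cross_labels)``; cross labels are indexed by (parent_a, parent_b).
    """
    if alpha not in (0.05, 0.01):
        raise ConfigError(f"alpha must be 0.05 or 0.01, got {alpha}")
    direction = direction or result.direction
    if direction not in (HIGHER, LOWER):
        raise ConfigError(f"unknown trait direction {direction!r}")
    lsd_g = result.lsd_gi(alpha)
    lsd_s = result.lsd_sij(alpha)
    parent_labels = result.gca.apply(lambda e: _label(e, lsd_g, direction))
    parent_labels.name = f"gca_class_{alpha}"
    parents = result.parents
    idx, vals = [], []
    for i, a in enumerate(parents):
        for b in parents[i + 1 :]:
            idx.append((a, b))
            vals.append(_label(float(result.sca.loc[a, b]), lsd_s, direction))
    cross_labels = pd.Series(
        vals, index=pd.MultiIndex.from_tuples(idx, names=["parent_a", "parent_b"]),
        name=f"sca_class_{alpha}",
    )
    return parent_labels, cross_labels
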
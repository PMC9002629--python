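"""Per-trait, per-regime RCBD ANOVA with the diallel genotype partition.

The model is the two-way fixed-effects RCBD fit
``y_gk = mu + genotype_g + block_k + e_gk`` on a balanced layout of
``g = p(p+1)/2`` entries in ``r`` blocks.  The genotype sum of squares is
partitioned into parents (df p-1), F1 crosses (df p(p-1)/2 - 1) and the
single-df parents-vs-crosses contrast, whose SS is obtained by subtraction
``SS_G - SS_P - SS_C``.  Every genotype-level source is tested against the
residual mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datamodel import PhenotypePanel
from .errors import DesignError

ANOVA_COLUMNS = ["source", "df", "SS", "MS", "F", "p"]


@dataclass
class AnovaTable:
    """ANOVA rows plus the residual term used by downstream F tests.

    ``rows`` has columns ``source, df, SS, MS, F, p``; sources are Blocks,
    Genotypes, Parents, Crosses, "P vs C" and Error.  Zero-variance data
    yield SS = 0 with F reported as NaN and p = 1.
    """

    trait: str
    regime: str
    rows: pd.DataFrame
    error_ms: float
    error_df: int

    def __post_init__(self) -> None:
        ss = self.rows.set_index("source")["SS"]
        df = self.rows.set_index("source")["df"]
        if not np.isclose(
            ss["Genotypes"],
            ss["Parents"] + ss["Crosses"] + ss["P vs C"],
            rtol=1e-9,
            atol=1e-9 * max(1.0, abs(ss["Genotypes"])),
        ):
            raise AssertionError("genotype SS partition does not add up")
        if df["Genotypes"] != df["Parents"] + df["Crosses"] + 1:
            raise AssertionError("genotype df partition does not add up")

    def ss(self, source: str) -> float:
        return float(self.rows.set_index("source").loc[source, "SS"])

    def ms(self, source: str) -> float:
        return float(self.rows.set_index("source").loc[source, "MS"])

    def dof(self, source: str) -> int:
        return int(self.rows.set_index("source").loc[source, "df"])

    def to_tsv(self, path) -> None:
        out = self.rows.rename(
            columns={"source": "Source", "df": "df", "SS": "SS", "MS": "MS", "F": "F", "p": "p"}
        )
        out.to_csv(path, sep="\t", index=False)


def _ss_from_groups(values: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Within-collection between-group SS: sum n_g (mean_g - grand)^2, df = k-1."""
    df_ = pd.DataFrame({"v": values, "g": labels})
    grand = df_["v"].mean()
    agg = df_.groupby("g")["v"].agg(["mean", "size"])
    ss = float((agg["size"] * (agg["mean"] - grand) ** 2).sum())
    return ss, len(agg) - 1


def _f_and_p(ms: float, error_ms: float, df_num: int, df_den: int) -> tuple[float, float]:
    if error_ms <= 0 or df_den <= 0:
        return float("nan"), 1.0
    f = ms / error_ms
    return f, float(stats.f.sf(f, df_num, df_den))


class RCBDAnova(BaseEstimator):
    """Randomized-complete-block ANOVA for one trait under one regime.

    Parameters
    ----------
    trait, regime : str
        Which panel column / irrigation regime to analyze.

    Attributes
    ----------
    table_ : AnovaTable
        Full ANOVA with the parents / crosses / parents-vs-crosses partition.
    error_ms_, error_df_ : float, int
        Residual mean square and df, the plot-error term downstream
        combining-ability tests are built on.
    """

    def __init__(self, trait: str = "grain_yield", regime: str = "well_watered"):
        self.trait = trait
        self.regime = regime

    def fit(self, X: PhenotypePanel, y=None) -> "RCBDAnova":
        panel = X
        design = panel.design
        if design.n_blocks < 2:
            raise DesignError("RCBD ANOVA needs at least two blocks for an error term")
        obs = panel.observations(self.trait, self.regime)

        y_ = obs["value"].to_numpy(dtype=float)
        entry = (obs["parent_a"] + "\x00" + obs["parent_b"]).to_numpy()
        block = obs["block"].to_numpy()
        n = len(y_)
        g = design.n_entries
        r = design.n_blocks
        grand = y_.mean()
        ss_total = float(((y_ - grand) ** 2).sum())
        ss_geno, df_geno = _ss_from_groups(y_, entry)
        ss_block, df_block = _ss_from_groups(y_, block)
        ss_error = ss_total - ss_geno - ss_block
        df_error = (g - 1) * (r - 1)
        assert n == g * r

        is_parent = obs["parent_a"] == obs["parent_b"]
        # within-group partitions of the genotype SS, computed on each subset
        ss_par, df_par = _ss_from_groups(y_[is_parent], entry[is_parent])
        ss_cross, df_cross = _ss_from_groups(y_[~is_parent], entry[~is_parent])
        ss_pvc = ss_geno - ss_par - ss_cross

        # subtraction can leave tiny negative residue at machine precision
        tol = 1e-9 * max(1.0, ss_total)
        if -tol < ss_pvc < 0:
            ss_pvc = 0.0
        if -tol < ss_error < 0:
            ss_error = 0.0

        error_ms = ss_error / df_error
        rows = []
        for name, ss, df_ in [
            ("Blocks", ss_block, df_block),
            ("Genotypes", ss_geno, df_geno),
            ("Parents", ss_par, df_par),
            ("Crosses", ss_cross, df_cross),
            ("P vs C", ss_pvc, 1),
            ("Error", ss_error, df_error),
        ]:
            ms = ss / df_ if df_ > 0 else float("nan")
            if name == "Error":
                f_val, p_val = float("nan"), float("nan")
            else:
                f_val, p_val = _f_and_p(ms, error_ms, df_, df_error)
            rows.append({"source": name, "df": df_, "SS": ss, "MS": ms, "F": f_val, "p": p_val})
        table = pd.DataFrame(rows, columns=ANOVA_COLUMNS)
        self.table_ = AnovaTable(
            trait=self.trait, regime=self.regime, rows=table,
            error_ms=error_ms, error_df=df_error,
        )
        self.error_ms_ = error_ms
        self.error_df_ = df_error
        return self


def rcbd_anova(panel: PhenotypePanel, trait: str, regime: str) -> AnovaTable:
    """Fit the RCBD ANOVA and return its :class:`AnovaTable`."""
    return RCBDAnova(trait=trait, regime=regime).fit(panel).table_


def significance_stars(p: float, alpha1: float = 0.05, alpha2: float = 0.01) -> str:
    """'**' below 0.01, '*' below 0.05, '' otherwise (NaN -> '')."""
    if not np.isfinite(p):
        return ""
    if p < alpha2:
        return "**"
    if p < alpha1:
        return "*"
    return ""
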
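"""End-to-end analysis pipeline and report bundle writer.

Runs, per trait x regime: RCBD ANOVA -> Griffing method-2 combining-ability
analysis -> effect classification; then tolerance indices + cluster grouping
on grain yield; then percent change, trait correlations and PCA.  Writes a
TSV table set shaped like the study's Tables 1-3 plus tolerance and
association outputs, and a machine-readable JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anova import AnovaTable, rcbd_anova, significance_stars
from .associations import percent_change, trait_correlations, trait_pca
from .datamodel import PhenotypePanel
from .errors import ConfigError
from .griffing import CombiningAbilityResult, classify_combiners, griffing_method2
from .tolerance import ToleranceClassifier, dendrogram_newick, tolerance_indices

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    yield_trait: str = "grain_yield"
    traits: list[str] | None = None  # None = all panel traits
    regimes: list[str] | None = None
    alpha: float = 0.05
    cluster_k: int = 5
    cluster_linkage: str = "ward"
    pca_regime: str | None = None  # None = stress (last) regime
    round_digits: int | None = None
    write_newick: bool = True

    def validate(self, panel: PhenotypePanel) -> None:
        if self.alpha not in (0.05, 0.01):
            raise ConfigError("alpha must be 0.05 or 0.01")
        if self.traits is not None and not self.traits:
            raise ConfigError("trait list is empty")
        for t in self.traits or []:
            if t not in panel.traits:
                raise ConfigError(f"config names unknown trait {t!r}")
        for m in self.regimes or []:
            if m not in panel.design.regimes:
                raise ConfigError(f"config names unknown regime {m!r}")


@dataclass
class ReportBundle:
    """In-memory results of a full run (also serialized to ``out_dir``)."""

    anova: dict[tuple[str, str], AnovaTable]
    combining: dict[tuple[str, str], CombiningAbilityResult]
    tolerance: pd.DataFrame
    percent_change: pd.Series
    correlations: object
    pca: object
    summary: dict = field(default_factory=dict)


SUMMARY_SCHEMA: dict = {
    "type": "object",
    "required": [
        "design",
        "traits",
        "regimes",
        "anova_df",
        "combining_df",
        "tolerance_groups",
        "percent_change",
        "pca_explained_variance_ratio",
    ],
    "properties": {
        "design": {
            "type": "object",
            "required": ["n_parents", "n_blocks", "n_entries", "n_crosses"],
        },
        "traits": {"type": "array"},
        "regimes": {"type": "array"},
        "anova_df": {"type": "object"},
        "combining_df": {"type": "object"},
        "tolerance_groups": {"type": "object"},
        "percent_change": {"type": "object"},
        "pca_explained_variance_ratio": {"type": "array"},
    },
}


def validate_summary(summary: dict, schema: dict = SUMMARY_SCHEMA) -> None:
    """Structural check of the JSON summary against the shipped schema."""
    if not isinstance(summary, dict):
        raise ConfigError("summary must be an object")
    for key in schema["required"]:
        if key not in summary:
            raise ConfigError(f"summary is missing required key {key!r}")
    for key, sub in schema["properties"].items():
        if key not in summary:
            continue
        val = summary[key]
        if sub["type"] == "object" and not isinstance(val, dict):
            raise ConfigError(f"summary[{key!r}] must be an object")
        if sub["type"] == "array" and not isinstance(val, list):
            raise ConfigError(f"summary[{key!r}] must be an array")
        for req in sub.get("required", []):
            if req not in val:
                raise ConfigError(f"summary[{key!r}] is missing {req!r}")


def _fmt(x: float, digits: int | None) -> float:
    return round(float(x), digits) if digits is not None else float(x)


def _effect_cell(effect: float, lsd05: float, lsd01: float, digits: int | None) -> str:
    star = "**" if abs(effect) > lsd01 else ("*" if abs(effect) > lsd05 else "")
    val = _fmt(effect, digits) if digits is not None else effect
    return f"{val:g}{star}" if digits is None else f"{val}{star}"


def run_pipeline(panel: PhenotypePanel, config: RunConfig) -> ReportBundle:
    """Execute every stage on ``panel`` and write the report bundle."""
    config.validate(panel)
    out = Path(config.out_dir)
    traits = config.traits or panel.traits
    regimes = tuple(config.regimes or panel.design.regimes)
    design = panel.design
    r = design.n_blocks
    digits = config.round_digits

    (out / "anova").mkdir(parents=True, exist_ok=True)
    anova_results: dict[tuple[str, str], AnovaTable] = {}
    ca_results: dict[tuple[str, str], CombiningAbilityResult] = {}
    for trait in traits:
        for regime in regimes:
            table = rcbd_anova(panel, trait, regime)
            anova_results[(trait, regime)] = table
            ca = griffing_method2(
                panel.entry_means(trait, regime),
                plot_error_ms=table.error_ms,
                error_df=table.error_df,
                r=r,
            )
            ca.direction = panel.direction(trait)
            ca_results[(trait, regime)] = ca
            logger.info(
                "anova+griffing: trait=%s regime=%s rows=%d", trait, regime, design.n_entries * r
            )

    _write_anova_tables(anova_results, ca_results, out, digits)
    _write_gca_table(ca_results, traits, regimes, design, out, digits)
    _write_sca_table(ca_results, traits, regimes, design, out, digits)

    # tolerance classification on the yield trait across the two regimes
    if config.yield_trait not in panel.traits:
        raise ConfigError(f"yield trait {config.yield_trait!r} not in panel")
    if len(regimes) < 2:
        raise ConfigError("tolerance indices need a control and a stress regime")
    yp = panel.entry_means(config.yield_trait, regimes[0]).means
    ys = panel.entry_means(config.yield_trait, regimes[1]).means
    tol = tolerance_indices(yp, ys)
    tol.index = [f"{a}x{b}" if a != b else a for a, b in tol.index]
    clf = ToleranceClassifier(
        n_groups=config.cluster_k, linkage=config.cluster_linkage
    ).fit(tol[list(("gmp", "mp", "yi", "sti"))])
    tol["group"] = clf.groups_
    tol_out = tol.copy()
    if digits is not None:
        num = tol_out.select_dtypes("number").columns
        tol_out[num] = tol_out[num].round(digits)
    tol_out.rename_axis("entry").to_csv(out / "tolerance.tsv", sep="\t")
    if config.write_newick:
        (out / "tolerance_dendrogram.nwk").write_text(dendrogram_newick(clf) + "\n")
    logger.info("tolerance: %d entries in %d groups", len(tol), tol["group"].nunique())

    # associations
    pct = percent_change(panel, control=regimes[0], stress=regimes[1])
    pca_regime = config.pca_regime or regimes[-1]
    corr = trait_correlations(panel, pca_regime)
    pca = trait_pca(panel, pca_regime)
    pct.round(digits or 10).rename_axis("trait").to_frame().to_csv(
        out / "percent_change.tsv", sep="\t"
    )
    corr.r.loc[corr.order, corr.order].to_csv(out / "correlations.tsv", sep="\t")
    corr.p.loc[corr.order, corr.order].to_csv(out / "correlation_pvalues.tsv", sep="\t")
    pca.scores_.rename_axis("entry").to_csv(out / "pca_scores.tsv", sep="\t")
    pca.loadings_.rename_axis("trait").to_csv(out / "pca_loadings.tsv", sep="\t")
    pd.Series(
        pca.explained_variance_ratio_,
        index=pca.scores_.columns,
        name="explained_variance_fraction",
    ).rename_axis("component").to_csv(out / "pca_variance.tsv", sep="\t")
    logger.info("associations: %d traits, PCA on regime %s", len(pct), pca_regime)

    first = next(iter(anova_results.values()))
    first_ca = next(iter(ca_results.values()))
    summary = {
        "design": {
            "n_parents": design.n_parents,
            "n_blocks": design.n_blocks,
            "n_entries": design.n_entries,
            "n_crosses": design.n_crosses,
            "regimes": list(design.regimes),
        },
        "traits": list(traits),
        "regimes": list(regimes),
        "anova_df": {
            "genotypes": first.dof("Genotypes"),
            "parents": first.dof("Parents"),
            "crosses": first.dof("Crosses"),
            "p_vs_c": first.dof("P vs C"),
            "error": first.dof("Error"),
        },
        "combining_df": {"gca": first_ca.df_gca, "sca": first_ca.df_sca},
        "gca_sca_ratio": {
            f"{t}::{m}": ca_results[(t, m)].gca_sca_ratio for t in traits for m in regimes
        },
        "tolerance_groups": tol["group"].value_counts().sort_index().to_dict(),
        "percent_change": {k: float(v) for k, v in pct.items()},
        "pca_explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio_],
    }
    validate_summary(summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))

    return ReportBundle(
        anova=anova_results,
        combining=ca_results,
        tolerance=tol,
        percent_change=pct,
        correlations=corr,
        pca=pca,
        summary=summary,
    )


def _write_anova_tables(anova_results, ca_results, out: Path, digits) -> None:
    """One TSV per trait x regime: RCBD rows plus the combining-ability block."""
    for (trait, regime), table in anova_results.items():
        ca = ca_results[(trait, regime)]
        rows = table.rows.copy()
        extra = pd.DataFrame(
            [
                {
                    "source": "GCA",
                    "df": ca.df_gca,
                    "SS": ca.ss_gca,
                    "MS": ca.ms_gca,
                    "F": ca.f_gca,
                    "p": ca.p_gca,
                },
                {
                    "source": "SCA",
                    "df": ca.df_sca,
                    "SS": ca.ss_sca,
                    "MS": ca.ms_sca,
                    "F": ca.f_sca,
                    "p": ca.p_sca,
                },
                {
                    "source": "Error term",
                    "df": ca.df_error,
                    "SS": np.nan,
                    "MS": ca.ms_error_term,
                    "F": np.nan,
                    "p": np.nan,
                },
                {
                    "source": "GCA/SCA",
                    "df": np.nan,
                    "SS": np.nan,
                    "MS": ca.gca_sca_ratio,
                    "F": np.nan,
                    "p": np.nan,
                },
            ]
        )
        full = pd.concat([rows, extra], ignore_index=True)
        full["sig"] = [significance_stars(p) for p in full["p"]]
        if digits is not None:
            for c in ("SS", "MS", "F"):
                full[c] = full[c].round(digits)
        full.to_csv(out / "anova" / f"{trait}__{regime}.tsv", sep="\t", index=False)


def _write_gca_table(ca_results, traits, regimes, design, out: Path, digits) -> None:
    """Parents x (trait, regime) GCA effects with stars, plus LSD rows."""
    cols = {}
    for trait in traits:
        for regime in regimes:
            ca = ca_results[(trait, regime)]
            col = [
                _effect_cell(float(ca.gca[pid]), ca.lsd_gi_05, ca.lsd_gi_01, digits)
                for pid in design.parent_ids
            ]
            col.append(f"{_fmt(ca.lsd_gi_05, digits)}")
            col.append(f"{_fmt(ca.lsd_gi_01, digits)}")
            cols[f"{trait}::{regime}"] = col
    index = list(design.parent_ids) + ["LSD(gi)_0.05", "LSD(gi)_0.01"]
    pd.DataFrame(cols, index=index).rename_axis("parent").to_csv(
        out / "gca_effects.tsv", sep="\t"
    )


def _write_sca_table(ca_results, traits, regimes, design, out: Path, digits) -> None:
    """Crosses x (trait, regime) SCA effects with stars; selfs in a second file."""
    crosses = design.crosses()
    selfs = design.parents()
    for entries, fname in ((crosses, "sca_effects.tsv"), (selfs, "sca_self_effects.tsv")):
        cols = {}
        for trait in traits:
            for regime in regimes:
                ca = ca_results[(trait, regime)]
                col = [
                    _effect_cell(
                        float(ca.sca.loc[e.parent_a, e.parent_b]),
                        ca.lsd_sij_05,
                        ca.lsd_sij_01,
                        digits,
                    )
                    for e in entries
                ]
                col.append(f"{_fmt(ca.lsd_sij_05, digits)}")
                col.append(f"{_fmt(ca.lsd_sij_01, digits)}")
                cols[f"{trait}::{regime}"] = col
        index = [str(e) for e in entries] + ["LSD(sij)_0.05", "LSD(sij)_0.01"]
        pd.DataFrame(cols, index=index).rename_axis("entry").to_csv(out / fname, sep="\t")


def classify_all(bundle: ReportBundle, alpha: float = 0.05) -> dict[tuple[str, str], tuple]:
    """Favorable / unfavorable / non-significant labels for every trait x regime."""
    return {
        key: classify_combiners(ca, alpha=alpha, direction=ca.direction)
        for key, ca in bundle.combining.items()
    }
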
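"""Synthetic half-diallel RCBD trials with known combining-ability structure.

The generator mirrors the fixed-effects model the analysis assumes: for each
trait and regime an entry mean ``x_ij = mu_m + g_i + g_j + s_ij`` (selfs:
``mu_m + 2 g_i + s_ii``), plus centered block effects and iid Gaussian plot
error.  Raw GCA draws are Normal(0, sigma_gca^2) and raw SCA draws
Normal(0, sigma_sca^2); both are then projected onto the estimator's
constraint space (sum g = 0; per-array sum_j s_ij + s_ii = 0) by the same
closed-form decomposition the analysis uses, and the grand mean is re-pinned
to the programmed ``mu_m``.  The stored :class:`GroundTruth` is this
post-projection truth — the raw draws are not identifiable and are discarded.

``mu_m = mu * regime_effect`` for every regime after the first, so a
``regime_effect`` of 0.747 programs a 25.3% reduction under stress.  GCA
effects are correlated across regimes through a shared standard-normal
vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import HIGHER, DiallelDesign, PhenotypePanel
from .errors import ConfigError
from .griffing import decompose_means


@dataclass
class TraitSettings:
    """Generative settings of one trait.

    All sigmas are standard deviations in trait units under the control
    regime; under other regimes they are multiplied by ``regime_effect``
    when ``scale_sigmas_with_regime`` (default), keeping coefficients of
    variation constant across regimes.
    """

    mu: float
    sigma_gca: float = 0.0
    sigma_sca: float = 0.0
    sigma_block: float = 0.0
    sigma_error: float = 0.0
    regime_effect: float = 1.0
    gca_regime_correlation: float = 0.8
    direction: str = HIGHER
    scale_sigmas_with_regime: bool = True

    def validate(self, name: str) -> None:
        for attr in ("sigma_gca", "sigma_sca", "sigma_block", "sigma_error"):
            if getattr(self, attr) < 0:
                raise ConfigError(f"trait {name!r}: {attr} must be >= 0")
        if self.regime_effect <= 0:
            raise ConfigError(f"trait {name!r}: regime_effect must be > 0")
        if not -1.0 <= self.gca_regime_correlation <= 1.0:
            raise ConfigError(f"trait {name!r}: gca_regime_correlation must be in [-1, 1]")

    def regime_multiplier(self, regime_position: int) -> float:
        return 1.0 if regime_position == 0 else self.regime_effect


@dataclass
class GeneratorConfig:
    design: DiallelDesign
    traits: Mapping[str, TraitSettings]
    seed: int | None = None

    def validate(self) -> None:
        if not self.traits:
            raise ConfigError("generator config names no traits")
        for name, ts in self.traits.items():
            ts.validate(name)


@dataclass
class TraitRegimeTruth:
    """Identifiable (post-projection) truth for one trait under one regime."""

    mu: float
    gca: np.ndarray  # (p,), sums to zero
    sca: np.ndarray  # (p, p) symmetric, per-array constraint satisfied
    block_effects: np.ndarray  # (r,), centered
    entry_means: pd.Series  # noiseless x_ij keyed by (parent_a, parent_b)


@dataclass
class GroundTruth:
    design: DiallelDesign
    per_trait: dict[tuple[str, str], TraitRegimeTruth] = field(default_factory=dict)

    def truth(self, trait: str, regime: str) -> TraitRegimeTruth:
        return self.per_trait[(trait, regime)]

    def to_json(self, path: str | Path) -> None:
        payload = {}
        for (trait, regime), t in self.per_trait.items():
            payload[f"{trait}::{regime}"] = {
                "mu": t.mu,
                "gca": t.gca.tolist(),
                "sca": t.sca.tolist(),
                "block_effects": t.block_effects.tolist(),
                "entry_means": {str(k): float(v) for k, v in t.entry_means.items()},
            }
        Path(path).write_text(json.dumps(payload, indent=1))


def _symmetric_draw(rng: np.random.Generator, p: int, sigma: float) -> np.ndarray:
    s = np.zeros((p, p))
    iu = np.triu_indices(p)
    s[iu] = rng.normal(0.0, sigma, size=len(iu[0]))
    return s + np.triu(s, 1).T


def simulate_trial(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[PhenotypePanel, GroundTruth]:
    """Generate one balanced trial and its identifiable ground truth.

    Fully reproducible: the same seed gives a bit-identical panel.  ``seed``
    overrides ``config.seed``.
    """
    config.validate()
    design = config.design
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = design.n_parents
    r = design.n_blocks
    entries = design.entries()
    idx = design.parent_index

    truth = GroundTruth(design=design)
    columns: dict[str, np.ndarray] = {}
    n_rows = len(design.regimes) * len(entries) * r
    key_rows = [
        (e.parent_a, e.parent_b, b, m)
        for m in design.regimes
        for e in entries
        for b in design.blocks
    ]

    for trait, ts in config.traits.items():
        z_shared = rng.normal(size=p)  # couples GCA across regimes
        values = np.empty(n_rows)
        pos = 0
        for mi, regime in enumerate(design.regimes):
            mult = ts.regime_multiplier(mi)
            scale = mult if ts.scale_sigmas_with_regime else 1.0
            mu_m = ts.mu * mult
            rho = ts.gca_regime_correlation
            if mi == 0:
                z = z_shared
            else:
                z = rho * z_shared + np.sqrt(1.0 - rho * rho) * rng.normal(size=p)
            g_raw = ts.sigma_gca * scale * z
            g_true = g_raw - g_raw.mean()  # center: sum g = 0
            s_raw = _symmetric_draw(rng, p, ts.sigma_sca * scale)
            # keep only the pure-SCA component of the raw draw, so the truth
            # satisfies the estimator's constraints and sigma_gca = 0 is a
            # genuine null for the GCA test
            _, _, s_true, _, _ = decompose_means(s_raw)

            x = mu_m + g_true[:, None] + g_true[None, :] + s_true
            np.fill_diagonal(x, mu_m + 2.0 * g_true + np.diag(s_true))
            x = (x + x.T) / 2.0

            b_eff = rng.normal(0.0, ts.sigma_block * scale, size=r)
            b_eff = b_eff - b_eff.mean() if r > 1 else np.zeros(r)
            eps = rng.normal(0.0, ts.sigma_error * scale, size=(len(entries), r))

            entry_vals = np.array([x[idx[e.parent_a], idx[e.parent_b]] for e in entries])
            values[pos : pos + len(entries) * r] = (
                entry_vals[:, None] + b_eff[None, :] + eps
            ).ravel()
            pos += len(entries) * r

            truth.per_trait[(trait, regime)] = TraitRegimeTruth(
                mu=mu_m,
                gca=g_true,
                sca=s_true,
                block_effects=b_eff,
                entry_means=pd.Series(
                    entry_vals,
                    index=pd.MultiIndex.from_tuples(
                        entries, names=["parent_a", "parent_b"]
                    ),
                ),
            )
        columns[trait] = values

    data = pd.DataFrame(key_rows, columns=["parent_a", "parent_b", "block", "regime"])
    for trait in config.traits:
        data[trait] = columns[trait]
    panel = PhenotypePanel(
        design=design,
        data=data,
        trait_catalog={t: ts.direction for t, ts in config.traits.items()},
    )
    return panel, truth


# ---------------------------------------------------------------------------
# "paper-like" preset: 8 parents x 3 blocks x 2 regimes, 18 traits whose
# regime effects follow the reported stress responses (reductions for
# photosynthetic/agronomic traits, increases for osmolytes, antioxidant
# enzymes, protein and gluten).
# ---------------------------------------------------------------------------

#: (control mean, percent change under water deficit, direction)
PAPER_LIKE_TRAITS: dict[str, tuple[float, float, str]] = {
    "chlorophyll_a": (3.0, -31.4, "higher"),
    "chlorophyll_b": (1.5, -22.9, "higher"),
    "total_chlorophyll": (4.5, -28.6, "higher"),
    "fv_fm": (0.80, -24.1, "higher"),
    "relative_water_content": (85.0, -16.3, "higher"),
    "proline": (0.50, 90.2, "higher"),
    "catalase": (15.0, 107.5, "higher"),
    "peroxidase": (0.05, 155.7, "higher"),
    "superoxide_dismutase": (30.0, 47.4, "higher"),
    "plant_height": (100.0, -12.3, "lower"),
    "spike_length": (12.0, -19.0, "higher"),
    "grains_per_spike": (60.0, -20.0, "higher"),
    "thousand_grain_weight": (45.0, -19.9, "higher"),
    "grain_yield": (30.0, -25.3, "higher"),
    "carbohydrates": (70.0, -5.5, "higher"),
    "grain_protein": (12.0, 22.0, "higher"),
    "wet_gluten": (30.0, 9.7, "higher"),
    "dry_gluten": (10.0, 16.4, "higher"),
}

#: genetic and environmental coefficients of variation of the preset
PRESET_CV = {"gca": 0.05, "sca": 0.04, "block": 0.02, "error": 0.06}


def paper_like_config(seed: int | None = None, traits: list[str] | None = None) -> GeneratorConfig:
    """The default study-shaped preset: p=8, r=3, two regimes, 18 traits."""
    design = DiallelDesign(
        parent_ids=tuple(f"P{i}" for i in range(1, 9)),
        n_blocks=3,
        regimes=("well_watered", "water_deficit"),
    )
    chosen = traits or list(PAPER_LIKE_TRAITS)
    settings = {}
    for name in chosen:
        mu, pct, direction = PAPER_LIKE_TRAITS[name]
        settings[name] = TraitSettings(
            mu=mu,
            sigma_gca=PRESET_CV["gca"] * mu,
            sigma_sca=PRESET_CV["sca"] * mu,
            sigma_block=PRESET_CV["block"] * mu,
            sigma_error=PRESET_CV["error"] * mu,
            regime_effect=1.0 + pct / 100.0,
            gca_regime_correlation=0.8,
            direction=direction,
        )
    return GeneratorConfig(design=design, traits=settings, seed=seed)


def config_from_yaml(source: str | Path | Mapping) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a YAML/JSON file or mapping."""
    import yaml

    if isinstance(source, (str, Path)):
        spec = yaml.safe_load(Path(source).read_text())
    else:
        spec = dict(source)
    design = DiallelDesign(
        parent_ids=tuple(spec["parents"]),
        n_blocks=int(spec["blocks"]),
        regimes=tuple(spec.get("regimes", ("well_watered", "water_deficit"))),
    )
    settings = {}
    for name, raw in spec["traits"].items():
        raw = dict(raw)
        settings[name] = TraitSettings(direction=raw.pop("direction", "higher"), **raw)
    return GeneratorConfig(design=design, traits=settings, seed=spec.get("seed"))
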
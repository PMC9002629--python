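"""Core data types for half-diallel RCBD trials.

A half-diallel crosses ``p`` parents in every unordered pair without
reciprocals, and (in Griffing's method 2) evaluates the selfed parents
alongside the ``p(p-1)/2`` F1s, giving ``p(p+1)/2`` entries.  Each entry is
grown once per block of a randomized complete block design, under one or
more irrigation regimes.  The :class:`PhenotypePanel` is the single
long-format container every analysis stage consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd
import yaml

from .errors import (
    DesignError,
    DuplicateObservationError,
    IncompleteDesignError,
    PanelParseError,
    UnknownLabelError,
)

HIGHER = "higher-is-better"
LOWER = "lower-is-better"

#: reserved (non-trait) columns of the tidy panel CSV
KEY_COLUMNS = ("parent_a", "parent_b", "block", "regime")


class EntryKey(NamedTuple):
    """Canonical identifier of a diallel entry.

    ``parent_a == parent_b`` denotes a selfed parent; for crosses the pair is
    stored with ``parent_a`` preceding ``parent_b`` in the design's parent
    order, so ``(i, j)`` and ``(j, i)`` name the same entry.  Construct via
    :meth:`DiallelDesign.entry_key` to get canonicalization.
    """

    parent_a: str
    parent_b: str

    @property
    def is_parent(self) -> bool:
        return self.parent_a == self.parent_b

    def __str__(self) -> str:
        if self.is_parent:
            return self.parent_a
        return f"{self.parent_a}x{self.parent_b}"


@dataclass(frozen=True)
class DiallelDesign:
    """Mating structure: parents, blocks and regimes of the trial.

    Parameters
    ----------
    parent_ids
        Ordered unique parent labels; their order fixes entry canonicalization
        and the 1-based ``P_i`` numbering used in reports.
    n_blocks
        Number of complete blocks (replications), ``r``.
    regimes
        Ordered regime labels.  The two-regime drought study uses
        ``("well_watered", "water_deficit")``; at least one is required.
    """

    parent_ids: tuple[str, ...]
    n_blocks: int
    regimes: tuple[str, ...] = ("well_watered", "water_deficit")

    def __post_init__(self) -> None:
        object.__setattr__(self, "parent_ids", tuple(str(p) for p in self.parent_ids))
        object.__setattr__(self, "regimes", tuple(str(g) for g in self.regimes))
        if len(self.parent_ids) < 2:
            raise DesignError("a diallel needs at least two parents")
        if len(set(self.parent_ids)) != len(self.parent_ids):
            raise DesignError("parent_ids contains duplicates")
        if self.n_blocks < 1:
            raise DesignError("n_blocks must be a positive integer")
        if len(self.regimes) < 1:
            raise DesignError("at least one regime label is required")
        if len(set(self.regimes)) != len(self.regimes):
            raise DesignError("regime labels contain duplicates")

    @property
    def n_parents(self) -> int:
        return len(self.parent_ids)

    @property
    def n_entries(self) -> int:
        """p(p+1)/2: selfed parents plus unordered crosses."""
        p = self.n_parents
        return p * (p + 1) // 2

    @property
    def n_crosses(self) -> int:
        p = self.n_parents
        return p * (p - 1) // 2

    @property
    def parent_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.parent_ids)}

    def entry_key(self, parent_a: str, parent_b: str) -> EntryKey:
        """Canonical :class:`EntryKey` for an (unordered) parent pair."""
        idx = self.parent_index
        try:
            ia, ib = idx[str(parent_a)], idx[str(parent_b)]
        except KeyError as exc:
            raise UnknownLabelError(f"unknown parent label {exc.args[0]!r}") from None
        if ia <= ib:
            return EntryKey(self.parent_ids[ia], self.parent_ids[ib])
        return EntryKey(self.parent_ids[ib], self.parent_ids[ia])

    def entries(self) -> list[EntryKey]:
        """All p(p+1)/2 entries in canonical order (selfs on the diagonal)."""
        out = []
        for i, a in enumerate(self.parent_ids):
            for b in self.parent_ids[i:]:
                out.append(EntryKey(a, b))
        return out

    def parents(self) -> list[EntryKey]:
        return [EntryKey(p, p) for p in self.parent_ids]

    def crosses(self) -> list[EntryKey]:
        return [e for e in self.entries() if not e.is_parent]

    @property
    def blocks(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_blocks + 1))


@dataclass
class TraitMeanTable:
    """Entry means of one trait under one regime (the x_ij feeding Griffing)."""

    trait: str
    regime: str
    means: pd.Series  # index: MultiIndex (parent_a, parent_b), canonical
    design: DiallelDesign

    def __post_init__(self) -> None:
        if len(self.means) != self.design.n_entries:
            raise DesignError(
                f"mean table for {self.trait!r}/{self.regime!r} has "
                f"{len(self.means)} entries, expected {self.design.n_entries}"
            )

    def value(self, key: EntryKey) -> float:
        return float(self.means.loc[key])

    def matrix(self) -> np.ndarray:
        """Symmetric p x p matrix of entry means (diagonal = selfed parents)."""
        p = self.design.n_parents
        idx = self.design.parent_index
        x = np.empty((p, p))
        for (a, b), v in self.means.items():
            i, j = idx[a], idx[b]
            x[i, j] = x[j, i] = v
        return x


def _validate_catalog(trait_catalog: Mapping[str, str]) -> dict[str, str]:
    catalog = {}
    for name, direction in trait_catalog.items():
        d = str(direction).lower()
        if d in {"higher", "higher-is-better", "+"}:
            catalog[str(name)] = HIGHER
        elif d in {"lower", "lower-is-better", "-"}:
            catalog[str(name)] = LOWER
        else:
            raise DesignError(
                f"trait {name!r}: direction must be higher- or lower-is-better, got {direction!r}"
            )
    return catalog


@dataclass
class PhenotypePanel:
    """Plot-level observations of a balanced half-diallel RCBD trial.

    ``data`` is tidy/long: one row per (entry, block, regime) with one numeric
    column per trait.  The layout must be complete — every entry in every
    block under every regime — and all values finite; violations raise at
    construction so downstream balanced-design formulas are always valid.
    """

    design: DiallelDesign
    data: pd.DataFrame
    trait_catalog: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True).copy()
        missing_cols = [c for c in KEY_COLUMNS if c not in df.columns]
        if missing_cols:
            raise PanelParseError(f"panel is missing key columns: {missing_cols}")
        traits = [c for c in df.columns if c not in KEY_COLUMNS]
        if not traits:
            raise PanelParseError("panel has no trait columns")

        # canonicalize entry keys; rejects unknown parents
        keys = [
            self.design.entry_key(a, b)
            for a, b in zip(df["parent_a"], df["parent_b"])
        ]
        df["parent_a"] = [k.parent_a for k in keys]
        df["parent_b"] = [k.parent_b for k in keys]

        df["block"] = pd.to_numeric(df["block"], errors="raise").astype(int)
        bad_blocks = set(df["block"]) - set(self.design.blocks)
        if bad_blocks:
            raise UnknownLabelError(f"unknown block labels {sorted(bad_blocks)}")
        bad_regimes = set(df["regime"].astype(str)) - set(self.design.regimes)
        if bad_regimes:
            raise UnknownLabelError(f"unknown regime labels {sorted(bad_regimes)}")
        df["regime"] = df["regime"].astype(str)

        for t in traits:
            col = pd.to_numeric(df[t], errors="coerce")
            bad = ~np.isfinite(col.to_numpy(dtype=float))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise PanelParseError(
                    f"trait {t!r}: non-numeric or non-finite value "
                    f"{df[t].iloc[row]!r} in data row {row}"
                )
            df[t] = col.astype(float)

        cells = list(zip(keys, df["block"], df["regime"]))
        seen: set[tuple] = set()
        for c in cells:
            if c in seen:
                raise DuplicateObservationError(
                    f"duplicate observation for entry {c[0]}, block {c[1]}, regime {c[2]!r}"
                )
            seen.add(c)
        for regime in self.design.regimes:
            for entry in self.design.entries():
                for block in self.design.blocks:
                    if (entry, block, regime) not in seen:
                        raise IncompleteDesignError(
                            f"missing cell: entry {entry}, block {block}, regime {regime!r}"
                        )
        if len(cells) != len(seen):  # pragma: no cover - guarded above
            raise DuplicateObservationError("duplicate observations present")

        catalog = _validate_catalog(self.trait_catalog) if self.trait_catalog else {}
        for t in traits:
            catalog.setdefault(t, HIGHER)
        unknown = set(catalog) - set(traits)
        if unknown:
            raise UnknownLabelError(
                f"trait catalog names traits absent from the panel: {sorted(unknown)}"
            )
        self.trait_catalog = catalog
        self.data = df.sort_values(["regime", "parent_a", "parent_b", "block"]).reset_index(
            drop=True
        )

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in KEY_COLUMNS]

    def direction(self, trait: str) -> str:
        try:
            return self.trait_catalog[trait]
        except KeyError:
            raise UnknownLabelError(f"unknown trait {trait!r}") from None

    def _check_labels(self, trait: str, regime: str) -> None:
        if trait not in self.traits:
            raise UnknownLabelError(f"unknown trait {trait!r}")
        if regime not in self.design.regimes:
            raise UnknownLabelError(f"unknown regime {regime!r}")

    def observations(self, trait: str, regime: str) -> pd.DataFrame:
        """Long (entry, block, value) table for one trait under one regime."""
        self._check_labels(trait, regime)
        sub = self.data.loc[self.data["regime"] == regime, ["parent_a", "parent_b", "block", trait]]
        return sub.rename(columns={trait: "value"}).reset_index(drop=True)

    def entry_means(self, trait: str, regime: str) -> TraitMeanTable:
        """Average over the r blocks for each of the p(p+1)/2 entries."""
        obs = self.observations(trait, regime)
        means = obs.groupby(["parent_a", "parent_b"], sort=True)["value"].mean()
        order = pd.MultiIndex.from_tuples(self.design.entries(), names=["parent_a", "parent_b"])
        return TraitMeanTable(trait=trait, regime=regime, means=means.reindex(order), design=self.design)


def entry_means(panel: PhenotypePanel, trait: str, regime: str) -> TraitMeanTable:
    """Functional alias of :meth:`PhenotypePanel.entry_means`."""
    return panel.entry_means(trait, regime)


def load_design_spec(source: str | Path | Mapping) -> tuple[DiallelDesign, dict[str, str]]:
    """Load a design spec (YAML/JSON file or mapping) -> (design, trait catalog).

    The spec names ``parents`` (list), ``blocks`` (count), ``regimes`` (list)
    and optionally ``traits`` as a mapping trait -> direction
    (``higher``/``lower``).
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        spec = yaml.safe_load(text)  # YAML is a superset of JSON
    else:
        spec = dict(source)
    try:
        design = DiallelDesign(
            parent_ids=tuple(spec["parents"]),
            n_blocks=int(spec["blocks"]),
            regimes=tuple(spec.get("regimes", ("well_watered", "water_deficit"))),
        )
    except KeyError as exc:
        raise DesignError(f"design spec is missing key {exc.args[0]!r}") from None
    catalog = _validate_catalog(spec.get("traits", {}))
    return design, catalog


def read_panel(path: str | Path, design_spec: str | Path | Mapping | DiallelDesign) -> PhenotypePanel:
    """Read and validate a tidy plot-level CSV into a :class:`PhenotypePanel`.

    The CSV carries columns ``parent_a, parent_b, block, regime`` plus one
    column per trait.  Entry keys are canonicalized; unknown labels, missing
    cells, duplicates and non-numeric values raise specific errors.
    """
    if isinstance(design_spec, DiallelDesign):
        design, catalog = design_spec, {}
    else:
        design, catalog = load_design_spec(design_spec)
    df = pd.read_csv(
        path,
        dtype={"parent_a": str, "parent_b": str, "regime": str},
        float_precision="round_trip",
    )
    return PhenotypePanel(design=design, data=df, trait_catalog=catalog)


def write_panel(panel: PhenotypePanel, path: str | Path) -> None:
    """Write the panel back to the tidy CSV dialect (round-trips bit-exactly)."""
    # 17 significant digits round-trip float64 bit-exactly
    panel.data.to_csv(path, index=False, float_format="%.17g")


def write_design_spec(
    design: DiallelDesign, trait_catalog: Mapping[str, str], path: str | Path
) -> None:
    spec = {
        "parents": list(design.parent_ids),
        "blocks": design.n_blocks,
        "regimes": list(design.regimes),
        "traits": {t: ("lower" if d == LOWER else "higher") for t, d in trait_catalog.items()},
    }
    p = Path(path)
    if p.suffix == ".json":
        p.write_text(json.dumps(spec, indent=2))
    else:
        p.write_text(yaml.safe_dump(spec, sort_keys=False))
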
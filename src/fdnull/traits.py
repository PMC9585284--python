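"""Mixed-type functional traits and the Gower dissimilarity.

The ten vineyard weed traits are: five vegetative traits tied to resource
acquisition (Raunkiaer life form RLF, vegetative plant height PHV in cm,
specific leaf area SLA in mm^2/mg, leaf dry matter content LDMC in mg/g, leaf
area LA in mm^2) and five regenerative traits (seed mass SM in mg, seed bank
longevity index SLI in [0,1], onset of flowering OFL, duration of the
flowering period DFP in months, dispersal syndrome DS).

Gower's coefficient averages per-trait dissimilarities with equal weights:
range-normalized absolute difference for quantitative traits, level-rank
difference divided by (L-1) for ordinal traits, and a 0/1 mismatch for
nominal traits, so every pairwise value lies in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from skbio import DistanceMatrix

from .errors import DegenerateTraitWarning, MissingValueError, TraitSchemaError

TRAIT_KINDS = ("quantitative", "ordinal", "nominal")

RLF_LEVELS = ("therophyte", "therophyte/hemicryptophyte", "hemicryptophyte", "geophyte")
OFL_LEVELS = ("earlier", "medium", "late")
DS_LEVELS = ("unspecialized", "anemochorous", "zoochorous")


@dataclass(frozen=True)
class TraitDefinition:
    """Name, measurement kind, units and (for categorical traits) level set."""

    name: str
    kind: str
    units: str = ""
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise TraitSchemaError(f"unknown trait kind {self.kind!r} for {self.name}")
        if self.kind == "quantitative" and self.levels is not None:
            raise TraitSchemaError(f"quantitative trait {self.name} must not declare levels")
        if self.kind != "quantitative" and (self.levels is None or len(self.levels) < 2):
            raise TraitSchemaError(f"categorical trait {self.name} needs >= 2 levels")


def vineyard_trait_schema(
    ordinal_life_form: bool = True, ordinal_flowering_onset: bool = True
) -> dict[str, TraitDefinition]:
    """The default ten-trait schema.

    RLF is ordered along the Raunkiaer continuum and OFL along the season by
    default; both can be demoted to nominal (the choice changes d_ij, so it is
    explicit here rather than buried in the distance code). DS is nominal.
    """
    rlf_kind = "ordinal" if ordinal_life_form else "nominal"
    ofl_kind = "ordinal" if ordinal_flowering_onset else "nominal"
    defs = [
        TraitDefinition("RLF", rlf_kind, "", RLF_LEVELS),
        TraitDefinition("PHV", "quantitative", "cm"),
        TraitDefinition("SLA", "quantitative", "mm^2/mg"),
        TraitDefinition("LDMC", "quantitative", "mg/g"),
        TraitDefinition("LA", "quantitative", "mm^2"),
        TraitDefinition("SM", "quantitative", "mg"),
        TraitDefinition("SLI", "quantitative", ""),
        TraitDefinition("OFL", ofl_kind, "", OFL_LEVELS),
        TraitDefinition("DFP", "quantitative", "months"),
        TraitDefinition("DS", "nominal", "", DS_LEVELS),
    ]
    return {d.name: d for d in defs}


@dataclass
class TraitTable:
    """Species x trait values validated against a schema (complete cases only)."""

    data: pd.DataFrame
    schema: Mapping[str, TraitDefinition] = field(default_factory=vineyard_trait_schema)

    def __post_init__(self) -> None:
        unknown = set(self.data.columns) - set(self.schema)
        if unknown:
            raise TraitSchemaError(f"traits not in schema: {sorted(unknown)}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise TraitSchemaError(f"duplicate species identifier: {dup!r}")
        for name in self.data.columns:
            col = self.data[name]
            if col.isna().any():
                sp = col.index[col.isna()][0]
                raise MissingValueError(f"missing value for trait {name} of species {sp!r}")
            d = self.schema[name]
            if d.kind == "quantitative":
                vals = pd.to_numeric(col, errors="coerce")
                if vals.isna().any():
                    sp = col.index[vals.isna()][0]
                    raise TraitSchemaError(
                        f"non-numeric value {col[sp]!r} for quantitative trait {name} ({sp!r})"
                    )
                if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                    raise TraitSchemaError(f"non-finite value in quantitative trait {name}")
                if name == "SLI" and ((vals < 0) | (vals > 1)).any():
                    raise TraitSchemaError("SLI values must lie in [0, 1]")
                self.data[name] = vals.astype(float)
            else:
                bad = set(col) - set(d.levels)
                if bad:
                    raise TraitSchemaError(
                        f"value(s) {sorted(bad)} outside declared levels of trait {name}"
                    )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def subset_species(self, species: Sequence[str]) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise MissingValueError(f"species without trait rows: {missing}")
        return TraitTable(self.data.loc[list(species)].copy(), self.schema)

    def ranges(self) -> pd.DataFrame:
        """Observed min/max per quantitative trait (the Gower normalizers)."""
        quant = [n for n in self.data.columns if self.schema[n].kind == "quantitative"]
        return pd.DataFrame(
            {"min": self.data[quant].min(), "max": self.data[quant].max()}
        )

    # -- serialization ---------------------------------------------------------
    def to_csv(self, path: str | Path, schema_path: str | Path | None = None) -> None:
        self.data.to_csv(path)
        if schema_path is not None:
            write_trait_schema(self.schema, schema_path)

    @classmethod
    def from_csv(cls, path: str | Path, schema_path: str | Path) -> "TraitTable":
        return cls(pd.read_csv(path, index_col=0), read_trait_schema(schema_path))


def write_trait_schema(schema: Mapping[str, TraitDefinition], path: str | Path) -> None:
    payload = {
        name: {
            "kind": d.kind,
            "units": d.units,
            **({"levels": list(d.levels)} if d.levels else {}),
        }
        for name, d in schema.items()
    }
    text = (
        yaml.safe_dump(payload, sort_keys=False)
        if str(path).endswith((".yml", ".yaml"))
        else json.dumps(payload, indent=1)
    )
    Path(path).write_text(text)


def read_trait_schema(path: str | Path) -> dict[str, TraitDefinition]:
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    return {
        name: TraitDefinition(
            name,
            spec["kind"],
            spec.get("units", ""),
            tuple(spec["levels"]) if "levels" in spec else None,
        )
        for name, spec in payload.items()
    }


def _trait_dissimilarity(table: TraitTable, name: str, log: bool) -> np.ndarray:
    d = table.schema[name]
    col = table.data[name]
    if d.kind == "quantitative":
        x = col.to_numpy(dtype=float)
        if log:
            if (x <= 0).any():
                raise TraitSchemaError(f"log transform of trait {name} requires positive values")
            x = np.log(x)
        rng = x.max() - x.min()
        if rng == 0:
            warnings.warn(
                f"quantitative trait {name} has zero range; it contributes 0 to the distance",
                DegenerateTraitWarning,
                stacklevel=3,
            )
            return np.zeros((len(x), len(x)))
        return np.abs(x[:, None] - x[None, :]) / rng
    if d.kind == "ordinal":
        ranks = np.array([d.levels.index(v) for v in col], dtype=float)
        return np.abs(ranks[:, None] - ranks[None, :]) / (len(d.levels) - 1)
    codes = pd.Categorical(col, categories=d.levels).codes
    return (codes[:, None] != codes[None, :]).astype(float)


def gower_distance(
    table: TraitTable,
    subset: Iterable[str] | None = None,
    log_traits: Iterable[str] = (),
) -> DistanceMatrix:
    """Equal-weight Gower dissimilarity over ``subset`` (default: all traits).

    ``log_traits`` names quantitative traits to compare on the log scale
    (useful for heavy-tailed traits such as SM or LA); the result is still
    range-normalized, so values stay in [0, 1].
    """
    names = list(subset) if subset is not None else table.trait_names
    if not names:
        raise ValueError("empty trait subset")
    unknown = [n for n in names if n not in table.data.columns]
    if unknown:
        raise TraitSchemaError(f"unknown trait name(s): {unknown}")
    log_set = set(log_traits)
    acc = np.zeros((len(table.species),) * 2)
    for name in names:
        acc += _trait_dissimilarity(table, name, log=name in log_set)
    acc /= len(names)
    np.fill_diagonal(acc, 0.0)
    return DistanceMatrix((acc + acc.T) / 2.0, ids=table.species)


def single_trait_distance(table: TraitTable, trait: str, **kwargs) -> DistanceMatrix:
    """Gower dissimilarity restricted to one trait."""
    return gower_distance(table, subset=[trait], **kwargs)
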
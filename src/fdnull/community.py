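"""Plot x species abundance tables: ingestion, validation and cover-based filters.

Abundances are percent cover per plot (non-negative reals; rows need not sum
to 100 because covers are pooled means and canopies overlap). Relative
abundances p_i used by the diversity indices are always recomputed downstream
from the retained species.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdentifierError,
    EmptyCommunityError,
    MissingValueError,
    NegativeAbundanceError,
    ValidationError,
)

#: the five weed-management x irrigation treatment classes
TREATMENT_CLASSES = ("HI", "MNI", "MI", "TNI", "TI")

#: class -> (weed_management, irrigation)
CLASS_FACTORS = {
    "HI": ("herbicide", "irrigated"),
    "MNI": ("mowing", "non-irrigated"),
    "MI": ("mowing", "irrigated"),
    "TNI": ("tillage", "non-irrigated"),
    "TI": ("tillage", "irrigated"),
}

WEED_MANAGEMENTS = ("herbicide", "mowing", "tillage")
IRRIGATION_LEVELS = ("irrigated", "non-irrigated")
SITES = tuple(range(1, 9))


def _check_unique(labels: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DuplicateIdentifierError(f"duplicate {what} identifier: {lab!r}")
        seen.add(lab)


@dataclass
class CommunityMatrix:
    """A validated plot x species percent-cover matrix with optional plot metadata.

    Parameters
    ----------
    abundance
        DataFrame with plots as the index and species as columns; all cells
        finite and >= 0; every plot must hold at least one positive cover.
    metadata
        Optional DataFrame indexed like ``abundance`` carrying opaque plot
        labels. Columns ``weed_management``, ``irrigation``, ``site`` and
        ``treatment_class``, when present, are validated against the design
        enumerations.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        ab = self.abundance
        _check_unique(ab.index, "plot")
        _check_unique(ab.columns, "species")
        values = ab.to_numpy(dtype=float, copy=False)
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise MissingValueError(
                f"non-finite abundance at (plot {ab.index[r]!r}, species {ab.columns[c]!r})"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise NegativeAbundanceError(
                f"negative abundance at (plot {ab.index[r]!r}, species {ab.columns[c]!r})"
            )
        empty = ab.index[(values > 0).sum(axis=1) == 0]
        if len(empty):
            raise EmptyCommunityError(f"plot {empty[0]!r} has no species with positive cover")
        if self.metadata is not None:
            md = self.metadata
            if not md.index.equals(ab.index):
                raise ValidationError("metadata index does not match abundance plots")
            _validate_metadata(md)

    # -- convenience accessors -------------------------------------------------
    @property
    def plots(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def plot_relative_abundance(self, plot: str) -> pd.Series:
        """Relative abundances p_i over species present in ``plot`` (sum to 1)."""
        row = self.abundance.loc[plot]
        row = row[row > 0]
        return row / row.sum()

    # -- serialization ---------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        self.abundance.to_csv(path)

    def to_json(self) -> str:
        payload = {
            "plots": self.plots,
            "species": self.species,
            "abundance": self.values.tolist(),
        }
        if self.metadata is not None:
            payload["metadata"] = json.loads(self.metadata.to_json(orient="index"))
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CommunityMatrix":
        payload = json.loads(text)
        ab = pd.DataFrame(
            payload["abundance"], index=payload["plots"], columns=payload["species"], dtype=float
        )
        md = None
        if "metadata" in payload:
            md = pd.DataFrame.from_dict(payload["metadata"], orient="index").loc[ab.index]
        return cls(ab, md)


def _validate_metadata(md: pd.DataFrame) -> None:
    if "weed_management" in md.columns:
        bad = set(md["weed_management"]) - set(WEED_MANAGEMENTS)
        if bad:
            raise ValidationError(f"unknown weed_management value(s): {sorted(bad)}")
    if "irrigation" in md.columns:
        bad = set(md["irrigation"]) - set(IRRIGATION_LEVELS)
        if bad:
            raise ValidationError(f"unknown irrigation value(s): {sorted(bad)}")
    if "site" in md.columns:
        bad = set(int(s) for s in md["site"]) - set(SITES)
        if bad:
            raise ValidationError(f"site identifiers outside 1..8: {sorted(bad)}")
    if "treatment_class" in md.columns:
        bad = set(md["treatment_class"]) - set(TREATMENT_CLASSES)
        if bad:
            raise ValidationError(f"unknown treatment class(es): {sorted(bad)}")


def treatment_class(weed_management: str, irrigation: str) -> str:
    """Map (management, irrigation) to one of the five treatment classes."""
    for cls, (wm, irr) in CLASS_FACTORS.items():
        if (wm, irr) == (weed_management, irrigation):
            return cls
    raise ValidationError(
        f"no treatment class for ({weed_management!r}, {irrigation!r}); "
        "herbicide is applied in irrigated rows only"
    )


def read_community_matrix(
    path: str | Path | io.StringIO,
    plots_as_rows: bool = True,
    metadata_path: str | Path | None = None,
) -> CommunityMatrix:
    """Read a delimited abundance table (header row + leading identifier column).

    ``plots_as_rows=False`` accepts the transposed dialect (species as rows).
    Non-numeric and negative cells are rejected with the offending plot and
    species named.
    """
    if isinstance(path, (str, Path)) and not Path(path).exists():
        raise FileNotFoundError(f"community matrix file not found: {path}")
    raw = pd.read_csv(path, index_col=0)
    if not plots_as_rows:
        raw = raw.T
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric abundance {raw.iloc[r, c]!r} at "
            f"(plot {raw.index[r]!r}, species {raw.columns[c]!r})"
        )
    metadata = None
    if metadata_path is not None:
        metadata = pd.read_csv(metadata_path, index_col=0)
        metadata = metadata.loc[numeric.index]
    return CommunityMatrix(numeric.astype(float), metadata)


def relative_cover(cm: CommunityMatrix, scope: str = "overall") -> pd.Series | pd.DataFrame:
    """Relative cover in percent.

    ``scope='overall'``: 100 * column sum / grand sum (a Series over species,
    summing to 100). ``scope='per-plot'``: row-normalized percentages (a
    DataFrame whose rows each sum to 100).
    """
    values = cm.values
    if scope == "overall":
        total = values.sum()
        if total <= 0:
            raise EmptyCommunityError("all-zero abundance matrix")
        return pd.Series(100.0 * values.sum(axis=0) / total, index=cm.abundance.columns)
    if scope == "per-plot":
        row_sums = values.sum(axis=1, keepdims=True)
        return pd.DataFrame(
            100.0 * values / row_sums, index=cm.abundance.index, columns=cm.abundance.columns
        )
    raise ValueError(f"unknown scope {scope!r}; expected 'overall' or 'per-plot'")


def filter_rare_species(cm: CommunityMatrix, threshold_pct: float = 0.25) -> CommunityMatrix:
    """Drop species whose overall relative cover is strictly below ``threshold_pct``.

    The cover basis is computed once on the supplied matrix (a single
    pre-analysis screen, not an iterative one); retained covers are left
    unchanged and plots are kept as-is.
    """
    if threshold_pct < 0:
        raise ValueError("threshold_pct must be >= 0")
    cover = relative_cover(cm, scope="overall")
    keep = cover[cover >= threshold_pct].index
    if len(keep) == 0:
        raise EmptyCommunityError(
            f"rare-species filter at {threshold_pct}% removed every species"
        )
    return CommunityMatrix(cm.abundance[keep].copy(), cm.metadata)


def abundant_species(
    cm: CommunityMatrix, threshold_pct: float = 3.0, scope: str = "overall"
) -> list[str] | dict[str, list[str]]:
    """Species with relative cover strictly greater than ``threshold_pct``.

    Overall scope returns a species list; per-plot scope returns a mapping
    plot -> species list.
    """
    cover = relative_cover(cm, scope=scope)
    if scope == "overall":
        return list(cover[cover > threshold_pct].index)
    return {
        plot: list(row[row > threshold_pct].index) for plot, row in cover.iterrows()
    }
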
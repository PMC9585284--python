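"""Randomization null models for community matrices.

Two schemes are provided, each targeting the statistic it is used with:

* ``independent_swap`` — trial swaps of 2x2 checkerboard submatrices of the
  binary occurrence matrix, preserving every plot's richness (row sums) and
  every species' occurrence frequency (column sums) exactly. Used for FRic.
* ``richness_shuffle`` — within each plot, the multiset of abundance values
  (zeros included) is permuted across the full species pool, preserving the
  plot's richness and abundance distribution while randomizing which species
  carry them. Used for RaoQ.

Each replicate restarts from the observed matrix and draws its generator
from a replicate-indexed substream of the master seed, so a run is
reproducible bit-for-bit and independent of evaluation order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .errors import NoCheckerboardWarning, ValidationError
from .indices import default_fric_axes, hull_volume
from .ordination import pcoa
from .traits import TraitTable, gower_distance

NULL_KINDS = ("independent_swap", "richness_shuffle")


@dataclass(frozen=True)
class NullSpec:
    """Which null model to run and how."""

    kind: str
    n_rand: int = 1000
    swap_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NULL_KINDS:
            raise ValueError(f"unknown null kind {self.kind!r}")
        if self.n_rand < 1 or self.swap_iterations < 1:
            raise ValueError("n_rand and swap_iterations must be >= 1")


@dataclass
class NullDistribution:
    """Observed value plus the n_rand null values for one plot/statistic."""

    plot: str
    statistic: str
    observed: float
    nulls: np.ndarray
    spec: NullSpec
    flagged: bool = field(default=False)  # statistic undefined on > 50% of replicates

    def summary(self) -> dict:
        finite = self.nulls[np.isfinite(self.nulls)]
        return {
            "plot": self.plot,
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": float(finite.mean()) if finite.size else float("nan"),
            "null_sd": float(finite.std(ddof=1)) if finite.size > 1 else float("nan"),
            "null_q025": float(np.quantile(finite, 0.025)) if finite.size else float("nan"),
            "null_q975": float(np.quantile(finite, 0.975)) if finite.size else float("nan"),
            "n_rand": self.spec.n_rand,
            "flagged": self.flagged,
        }


def replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    """Counter-based substream: one independent generator per replicate."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(replicate,)))


def independent_swap(
    occurrence: np.ndarray,
    iterations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Randomize a binary matrix by 2x2 checkerboard swaps.

    Failed trial swaps (the selected submatrix is not a checkerboard) count
    toward the iteration budget. Row and column sums are preserved exactly.
    """
    occ = np.asarray(occurrence)
    if not np.isin(occ, (0, 1)).all():
        raise ValidationError("independent swap requires a binary occurrence matrix")
    occ = occ.astype(np.int8).copy()
    n_rows, n_cols = occ.shape
    if n_rows < 2 or n_cols < 2 or not _has_checkerboard(occ):
        warnings.warn(
            "no 2x2 checkerboard submatrix; matrix returned unchanged",
            NoCheckerboardWarning,
            stacklevel=2,
        )
        return occ
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = rng.integers(0, n_rows, size=(iterations, 2))
    cols = rng.integers(0, n_cols, size=(iterations, 2))
    for (r0, r1), (c0, c1) in zip(rows, cols):
        if r0 == r1 or c0 == c1:
            continue
        a, b = occ[r0, c0], occ[r0, c1]
        c, d = occ[r1, c0], occ[r1, c1]
        if a == d and b == c and a != b:
            occ[r0, c0] = b
            occ[r0, c1] = a
            occ[r1, c0] = d
            occ[r1, c1] = c
    return occ


def _has_checkerboard(occ: np.ndarray) -> bool:
    # a checkerboard exists iff some column pair has both (1,0) and (0,1) rows
    n_cols = occ.shape[1]
    for i in range(n_cols):
        for j in range(i + 1, n_cols):
            ci, cj = occ[:, i], occ[:, j]
            if ((ci == 1) & (cj == 0)).any() and ((ci == 0) & (cj == 1)).any():
                return True
    return False


def shuffle_rows(abundance: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Permute each row's values independently across all columns."""
    out = np.empty_like(abundance)
    n_cols = abundance.shape[1]
    for i, row in enumerate(abundance):
        out[i] = row[rng.permutation(n_cols)]
    return out


def richness_shuffle(cm: CommunityMatrix, seed: int | np.random.Generator = 0) -> CommunityMatrix:
    """Return a matrix with each plot's abundances permuted over the species pool."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shuffled = shuffle_rows(cm.values, rng)
    return CommunityMatrix(
        pd.DataFrame(shuffled, index=cm.abundance.index, columns=cm.abundance.columns),
        cm.metadata,
    )


# --------------------------------------------------------------------------
# per-plot statistics evaluated on (possibly randomized) matrices


def raoq_per_plot(abundance: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vector of per-plot RaoQ values; each row renormalized over its species."""
    p = abundance / abundance.sum(axis=1, keepdims=True)
    return np.einsum("ps,st,pt->p", p, d, p)


def fric_per_plot(
    occurrence: np.ndarray, coords: np.ndarray, k: int, pool_volume: float
) -> np.ndarray:
    """Vector of per-plot standardized hull volumes; NaN where undefined."""
    out = np.full(occurrence.shape[0], np.nan)
    for i, row in enumerate(occurrence):
        idx = np.flatnonzero(row)
        if len(idx) <= k:
            continue
        vol, degenerate = hull_volume(coords[idx, :k])
        out[i] = 0.0 if degenerate else vol / pool_volume
    return out


def null_distribution(
    cm: CommunityMatrix,
    traits: TraitTable,
    statistic: str | tuple[str, str],
    spec: NullSpec,
    pcoa_correction: str = "sqrt",
    fric_k: int | None = None,
) -> list[NullDistribution]:
    """Null distributions of a plot-level statistic under the chosen model.

    ``statistic`` is ``"FRic"``, ``"RaoQ"`` (multi-trait), or
    ``("RaoQ", trait_name)`` for a single-trait RaoQ. FRic is randomized with
    the independent swap on the binarized matrix; RaoQ with the richness
    shuffle on abundances.
    """
    table = traits.subset_species(cm.species)
    abundance = cm.values
    results: list[NullDistribution] = []

    if statistic == "FRic":
        if spec.kind != "independent_swap":
            raise ValueError("FRic null distributions use the independent_swap model")
        dm = gower_distance(table)
        ordination = pcoa(dm, correction=pcoa_correction)
        occ = (abundance > 0).astype(np.int8)
        k = fric_k or default_fric_axes(occ.shape[1], int(occ.sum(axis=1).min()))
        k = min(k, ordination.n_axes)
        coords = ordination.coordinates.to_numpy()
        pool_volume, degenerate = hull_volume(coords[:, :k])
        if degenerate:
            raise ValidationError("species pool hull is degenerate; cannot standardize FRic")
        observed = fric_per_plot(occ, coords, k, pool_volume)
        nulls = np.empty((spec.n_rand, occ.shape[0]))
        for r in range(spec.n_rand):
            rng = replicate_rng(spec.seed, r)
            rand = independent_swap(occ, spec.swap_iterations, rng)
            nulls[r] = fric_per_plot(rand, coords, k, pool_volume)
        name = "FRic"
    else:
        if isinstance(statistic, tuple):
            stat, trait = statistic
            if stat != "RaoQ":
                raise ValueError(f"unknown statistic {statistic!r}")
            dm = gower_distance(table, subset=[trait])
            name = f"RaoQ_{trait}"
        elif statistic == "RaoQ":
            dm = gower_distance(table)
            name = "RaoQ_multitrait"
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        if spec.kind != "richness_shuffle":
            raise ValueError("RaoQ null distributions use the richness_shuffle model")
        d = dm.data
        observed = raoq_per_plot(abundance, d)
        nulls = np.empty((spec.n_rand, abundance.shape[0]))
        for r in range(spec.n_rand):
            rng = replicate_rng(spec.seed, r)
            nulls[r] = raoq_per_plot(shuffle_rows(abundance, rng), d)

    for i, plot in enumerate(cm.plots):
        col = nulls[:, i]
        flagged = (~np.isfinite(col)).sum() > 0.5 * spec.n_rand or not np.isfinite(
            observed[i]
        )
        results.append(
            NullDistribution(
                plot=plot,
                statistic=name,
                observed=float(observed[i]),
                nulls=col,
                spec=spec,
                flagged=bool(flagged),
            )
        )
    return results


def null_distributions_to_frame(dists: list[NullDistribution]) -> pd.DataFrame:
    """Wide layout: plot, statistic, observed, null_1..null_n."""
    rows = []
    for nd in dists:
        row = {"plot": nd.plot, "statistic": nd.statistic, "observed": nd.observed}
        row.update({f"null_{i + 1}": v for i, v in enumerate(nd.nulls)})
        rows.append(row)
    return pd.DataFrame(rows)
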
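"""Per-plot functional diversity indices: FRic, FEve, RaoQ, FDis, CWM, CWV.

FRic is the convex-hull volume of the community in the first k ordination
axes, standardized by the hull volume of the full species pool on the same
axes. FEve walks the minimum spanning tree linking the community's species in
that space and measures how evenly abundance is spread along its branches.
RaoQ is computed on the Gower distances directly (it is distance-native);
FEve and FDis use the corrected coordinates, which provide the geometry the
MST and centroid need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform, pdist
from skbio import DistanceMatrix

from .community import CommunityMatrix
from .errors import ValidationError
from .ordination import Ordination, pcoa
from .traits import TraitTable, gower_distance


def _as_probabilities(abundances) -> np.ndarray:
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = p.sum()
    if total <= 0:
        raise ValidationError("abundances sum to zero")
    return p / total


def hull_volume(points: np.ndarray) -> tuple[float, bool]:
    """Convex-hull volume of an n x k point set; (0.0, True) when degenerate."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] <= points.shape[1]:
        return 0.0, True
    try:
        return float(ConvexHull(points).volume), False
    except QhullError:
        return 0.0, True


def fric(
    ordination: Ordination,
    present_species: list[str],
    k: int,
    standardize: bool = True,
) -> float:
    """Standardized functional richness of ``present_species`` on the first k axes.

    The raw hull volume is divided by the pool hull volume so the index lies
    in (0, 1]; degenerate (zero-volume) communities return 0.0.
    """
    if k < 2:
        raise ValueError("FRic needs k >= 2 axes")
    if len(present_species) <= k:
        raise ValidationError(
            f"FRic undefined: {len(present_species)} species <= {k} axes"
        )
    coords = ordination.coordinates
    pts = coords.loc[present_species].to_numpy()[:, :k]
    vol, _ = hull_volume(pts)
    if not standardize:
        return vol
    pool_vol, pool_degenerate = hull_volume(coords.to_numpy()[:, :k])
    if pool_degenerate:
        raise ValidationError("species pool is degenerate on the requested axes")
    return vol / pool_vol


def default_fric_axes(pool_size: int, min_richness: int) -> int:
    """Axis count rule: min(S_min - 1, floor(log2(S_pool))), at least 2."""
    return max(2, min(min_richness - 1, int(math.floor(math.log2(pool_size)))))


def feve(coords_or_distances, abundances) -> float:
    """Villeger's functional evenness over the community's minimum spanning tree.

    Each MST branch l linking species i and j gets the abundance-deflated
    weight EW_l = d(i,j)/(w_i + w_j); with PEW_l = EW_l / sum(EW),
    FEve = [sum_l min(PEW_l, 1/(S-1)) - 1/(S-1)] / [1 - 1/(S-1)].
    Returns NaN (undefined, never zero) for S < 3.
    """
    w = _as_probabilities(abundances)
    s = len(w)
    if s < 3:
        return float("nan")
    arr = np.asarray(
        coords_or_distances.data
        if isinstance(coords_or_distances, DistanceMatrix)
        else coords_or_distances,
        dtype=float,
    )
    if arr.ndim != 2:
        raise ValidationError("expected a coordinate matrix or square distance matrix")
    dist = arr if arr.shape[0] == arr.shape[1] and np.allclose(arr, arr.T) else squareform(pdist(arr))
    if dist.shape[0] != s:
        raise ValidationError("abundance length does not match the species count")
    # +1 on every edge keeps zero-distance branches in the sparse graph while
    # leaving the MST unchanged (every spanning tree has exactly S-1 edges)
    graph = dist + 1.0
    np.fill_diagonal(graph, 0.0)
    mst = minimum_spanning_tree(graph).tocoo()
    ew = np.array([dist[i, j] / (w[i] + w[j]) for i, j in zip(mst.row, mst.col)])
    total = ew.sum()
    if total == 0:  # all species identical in trait space
        pew = np.full(len(ew), 1.0 / len(ew))
    else:
        pew = ew / total
    ref = 1.0 / (s - 1)
    return float((np.minimum(pew, ref).sum() - ref) / (1.0 - ref))


def rao_q(dm: DistanceMatrix | np.ndarray, abundances) -> float:
    """Rao's quadratic entropy Q = sum_ij p_i p_j d_ij (both orders counted)."""
    p = _as_probabilities(abundances)
    d = np.asarray(dm.data if isinstance(dm, DistanceMatrix) else dm, dtype=float)
    if d.shape != (len(p), len(p)):
        raise ValidationError(
            f"distance matrix {d.shape} does not match {len(p)} abundances"
        )
    return float(p @ d @ p)


def fdis(coords: np.ndarray | pd.DataFrame, abundances) -> float:
    """Abundance-weighted mean distance to the abundance-weighted centroid."""
    p = _as_probabilities(abundances)
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != len(p):
        raise ValidationError("coordinate rows do not match abundance length")
    centroid = p @ x
    return float(p @ np.linalg.norm(x - centroid, axis=1))


def cwm(values, abundances):
    """Community-weighted mean: sum p_i x_i (quantitative) or per-level
    abundance shares (categorical values)."""
    p = _as_probabilities(abundances)
    vals = pd.Series(values)
    if len(vals) != len(p):
        raise ValidationError("trait values do not match abundance length")
    if vals.isna().any():
        raise ValidationError("missing trait value in CWM input")
    if pd.api.types.is_numeric_dtype(vals):
        return float(p @ vals.to_numpy(dtype=float))
    shares = pd.Series(p, index=vals.to_numpy()).groupby(level=0).sum()
    return shares


def cwv(values, abundances) -> float:
    """Community-weighted variance: sum p_i (x_i - CWM)^2 (quantitative only)."""
    vals = pd.Series(values)
    if not pd.api.types.is_numeric_dtype(vals):
        raise ValidationError("CWV is defined for quantitative traits only")
    p = _as_probabilities(abundances)
    x = vals.to_numpy(dtype=float)
    mean = p @ x
    return float(p @ (x - mean) ** 2)


@dataclass
class FDConfig:
    """Knobs for the per-plot index battery."""

    pcoa_correction: str = "sqrt"
    fric_k: int | None = None  # None -> default_fric_axes rule
    fric_standardize: bool = True
    log_traits: tuple[str, ...] = ()


@dataclass
class FDResult:
    """One plot's indices. FEve is NaN for S < 3; FRic is NaN (with
    ``fric_defined=False``) when the plot's richness does not exceed the axis
    count."""

    plot: str
    richness: int
    fric: float
    feve: float
    raoq: float
    fdis: float
    fric_defined: bool
    fric_degenerate: bool
    k_axes: int
    cwm: dict = field(default_factory=dict)
    cwv: dict = field(default_factory=dict)


def compute_all(
    cm: CommunityMatrix, traits: TraitTable, config: FDConfig | None = None
) -> pd.DataFrame:
    """Compute every index for every plot; one row per plot.

    Per-plot relative abundances are renormalized over the species present in
    that plot. Columns: richness, fric, feve, raoq, fdis, k_axes, flags, and
    cwm_<trait> / cwv_<trait> for each trait (per-level shares for
    categorical CWMs, e.g. ``cwm_DS=anemochorous``).
    """
    config = config or FDConfig()
    table = traits.subset_species(cm.species)
    dm = gower_distance(table, log_traits=config.log_traits)
    ordination = pcoa(dm, correction=config.pcoa_correction)
    presence = cm.values > 0
    richness = presence.sum(axis=1)
    k = config.fric_k or default_fric_axes(len(cm.species), int(richness.min()))
    k = min(k, ordination.n_axes)

    sp_index = pd.Index(cm.species)
    rows = []
    for plot in cm.plots:
        p_rel = cm.plot_relative_abundance(plot)
        present = list(p_rel.index)
        idx = sp_index.get_indexer(present)
        w = p_rel.to_numpy()
        s = len(present)
        sub_d = dm.data[np.ix_(idx, idx)]
        sub_x = ordination.coordinates.to_numpy()[idx]

        fric_defined = s > k >= 2
        fric_val, degenerate = float("nan"), False
        if fric_defined:
            vol, degenerate = hull_volume(sub_x[:, :k])
            if degenerate:
                fric_val = 0.0
            else:
                pool_vol, _ = hull_volume(ordination.coordinates.to_numpy()[:, :k])
                fric_val = vol / pool_vol if config.fric_standardize else vol

        row = {
            "plot": plot,
            "richness": s,
            "fric": fric_val,
            "feve": feve(sub_x, w) if s >= 3 else float("nan"),
            "raoq": rao_q(sub_d, w) if s > 1 else 0.0,
            "fdis": fdis(sub_x, w) if s > 1 else 0.0,
            "fric_defined": fric_defined,
            "fric_degenerate": degenerate,
            "k_axes": k,
        }
        for name in table.trait_names:
            vals = table.data[name].loc[present]
            m = cwm(vals, w)
            if isinstance(m, pd.Series):
                for level, share in m.items():
                    row[f"cwm_{name}={level}"] = share
            else:
                row[f"cwm_{name}"] = m
                row[f"cwv_{name}"] = cwv(vals, w)
        rows.append(row)
    return pd.DataFrame(rows).set_index("plot")
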
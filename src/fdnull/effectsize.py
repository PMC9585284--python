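"""Bounded effect sizes against null distributions, and convergence verdicts.

The effect size locates the observed index value within its null
distribution:

    p  = (number(NULL < obs) + number(NULL = obs)/2) / n_rand
    ES = (p - 0.5) * 2

so ES runs from -1 (observed below every null value: trait convergence when
the statistic is RaoQ) to +1 (observed above every null value: trait
divergence). Unlike a z-score (SES), the statistic needs no symmetry
assumption about the null distribution; with n_rand randomizations its
resolution is 1/(2 n_rand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityMatrix
from .errors import ValidationError
from .nullmodels import (
    NullDistribution,
    NullSpec,
    null_distribution,
    raoq_per_plot,
    replicate_rng,
    shuffle_rows,
)
from .traits import TraitTable, gower_distance

#: relative tolerance declaring NULL = obs (floating-point RaoQ ties are
#: otherwise never detected, biasing p at the +/-1 boundaries)
TIE_RTOL = 1e-12


@dataclass
class EffectSizeResult:
    """ES for one plot/statistic with its provenance."""

    es: float
    p: float
    n_rand: int
    n_below: int
    n_equal: int
    plot: str | None = None
    statistic: str | None = None
    null_kind: str | None = None
    seed: int | None = None


def effect_size(observed: float, null_values, tie_rtol: float = TIE_RTOL) -> EffectSizeResult:
    """Compute ES = (p - 0.5) * 2 with ties counted at half weight."""
    nulls = np.asarray(null_values, dtype=float)
    nulls = nulls[np.isfinite(nulls)]
    if nulls.size == 0:
        raise ValidationError("empty null vector")
    if not np.isfinite(observed):
        raise ValidationError("observed value is not finite")
    tol = tie_rtol * max(1.0, abs(observed))
    n_equal = int((np.abs(nulls - observed) <= tol).sum())
    n_below = int((nulls < observed - tol).sum())
    n_rand = nulls.size
    p = (n_below + n_equal / 2.0) / n_rand
    return EffectSizeResult(
        es=(p - 0.5) * 2.0, p=p, n_rand=n_rand, n_below=n_below, n_equal=n_equal
    )


def effect_size_from_null(nd: NullDistribution) -> EffectSizeResult:
    res = effect_size(nd.observed, nd.nulls)
    res.plot = nd.plot
    res.statistic = nd.statistic
    res.null_kind = nd.spec.kind
    res.seed = nd.spec.seed
    return res


def standardized_effect_size(observed: float, null_values) -> float:
    """Classical SES (z-score) for comparison; assumes a symmetric null."""
    nulls = np.asarray(null_values, dtype=float)
    sd = nulls.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((observed - nulls.mean()) / sd)


def es_battery(
    cm: CommunityMatrix,
    traits: TraitTable,
    spec: NullSpec,
    trait_sets: tuple = ("multitrait",),
    include_fric: bool = False,
    fric_spec: NullSpec | None = None,
) -> pd.DataFrame:
    """ES table: one row per plot x statistic.

    ``trait_sets`` mixes the token ``"multitrait"`` with single trait names;
    all RaoQ variants use the richness shuffle, and within each replicate the
    *same* shuffled matrix feeds every trait set, so the per-trait columns are
    directly comparable. ES FRic (optional) uses the independent swap.
    """
    if not trait_sets:
        raise ValidationError("trait_sets must not be empty")
    if spec.kind != "richness_shuffle":
        raise ValueError("the RaoQ battery uses the richness_shuffle null")
    table = traits.subset_species(cm.species)
    dms = {}
    for ts in trait_sets:
        if ts == "multitrait":
            dms["RaoQ_multitrait"] = gower_distance(table).data
        else:
            dms[f"RaoQ_{ts}"] = gower_distance(table, subset=[ts]).data

    abundance = cm.values
    observed = {name: raoq_per_plot(abundance, d) for name, d in dms.items()}
    # accumulate tie/below counts replicate by replicate; the shuffled matrix
    # is shared across trait sets within a replicate
    n_below = {name: np.zeros(abundance.shape[0], dtype=int) for name in dms}
    n_equal = {name: np.zeros(abundance.shape[0], dtype=int) for name in dms}
    for r in range(spec.n_rand):
        rng = replicate_rng(spec.seed, r)
        shuffled = shuffle_rows(abundance, rng)
        for name, d in dms.items():
            q = raoq_per_plot(shuffled, d)
            obs = observed[name]
            tol = TIE_RTOL * np.maximum(1.0, np.abs(obs))
            n_equal[name] += np.abs(q - obs) <= tol
            n_below[name] += q < obs - tol

    rows = []
    for name in dms:
        p = (n_below[name] + n_equal[name] / 2.0) / spec.n_rand
        es = (p - 0.5) * 2.0
        for i, plot in enumerate(cm.plots):
            rows.append(
                {
                    "plot": plot,
                    "statistic": f"ES_{name}",
                    "es": es[i],
                    "p": p[i],
                    "n_rand": spec.n_rand,
                    "n_below": int(n_below[name][i]),
                    "n_equal": int(n_equal[name][i]),
                    "null_kind": spec.kind,
                    "seed": spec.seed,
                }
            )

    if include_fric:
        fspec = fric_spec or NullSpec(
            "independent_swap",
            n_rand=spec.n_rand,
            swap_iterations=spec.swap_iterations,
            seed=spec.seed,
        )
        for nd in null_distribution(cm, traits, "FRic", fspec):
            if nd.flagged or not np.isfinite(nd.observed):
                rows.append(
                    {
                        "plot": nd.plot,
                        "statistic": "ES_FRic",
                        "es": float("nan"),
                        "p": float("nan"),
                        "n_rand": fspec.n_rand,
                        "n_below": 0,
                        "n_equal": 0,
                        "null_kind": fspec.kind,
                        "seed": fspec.seed,
                    }
                )
                continue
            res = effect_size_from_null(nd)
            rows.append(
                {
                    "plot": nd.plot,
                    "statistic": "ES_FRic",
                    "es": res.es,
                    "p": res.p,
                    "n_rand": res.n_rand,
                    "n_below": res.n_below,
                    "n_equal": res.n_equal,
                    "null_kind": fspec.kind,
                    "seed": fspec.seed,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ConvergenceVerdict:
    """Group-level test of whether ES values sit below/above zero."""

    n: int
    center: float  # mean under the t-test, median under Wilcoxon
    test: str  # "t", "wilcoxon" or "degenerate"
    p_value: float
    verdict: str  # "convergent", "divergent" or "neutral"


def convergence_test(
    es_values, alpha: float = 0.05, normality_alpha: float = 0.05
) -> ConvergenceVerdict:
    """Shapiro-gated one-sample test of ES against zero.

    Normally distributed samples get a one-sample t-test (center = mean);
    otherwise a Wilcoxon signed-rank test (center = median). Convergent if
    the center is below zero and p < alpha; divergent if above; else neutral.
    """
    es = np.asarray(es_values, dtype=float)
    es = es[np.isfinite(es)]
    n = es.size
    if n < 3:
        raise ValidationError(f"convergence test needs >= 3 values, got {n}")
    if np.ptp(es) == 0:
        center = float(es[0])
        verdict = "neutral" if center == 0 else ("convergent" if center < 0 else "divergent")
        return ConvergenceVerdict(n, center, "degenerate", float("nan"), verdict)
    normal = stats.shapiro(es).pvalue >= normality_alpha
    if normal:
        center = float(es.mean())
        p_value = float(stats.ttest_1samp(es, 0.0).pvalue)
        test = "t"
    else:
        center = float(np.median(es))
        p_value = float(stats.wilcoxon(es).pvalue)
        test = "wilcoxon"
    if p_value < alpha and center < 0:
        verdict = "convergent"
    elif p_value < alpha and center > 0:
        verdict = "divergent"
    else:
        verdict = "neutral"
    return ConvergenceVerdict(n, center, test, p_value, verdict)


def divergence_species_association(
    es_per_plot, species_cover_per_plot, normality_alpha: float = 0.05
) -> dict:
    """Normality-gated correlation between per-plot ES and a species' cover.

    Pearson when both vectors pass Shapiro-Wilk, Spearman otherwise.
    Returns ``{"coefficient", "p", "method"}``; a constant input yields an
    undefined coefficient flagged via ``method="undefined"``.
    """
    x = np.asarray(es_per_plot, dtype=float)
    y = np.asarray(species_cover_per_plot, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValidationError("need two equal-length vectors of >= 4 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"coefficient": float("nan"), "p": float("nan"), "method": "undefined"}
    normal = (
        stats.shapiro(x).pvalue >= normality_alpha
        and stats.shapiro(y).pvalue >= normality_alpha
    )
    if normal:
        r = stats.pearsonr(x, y)
        return {"coefficient": float(r.statistic), "p": float(r.pvalue), "method": "pearson"}
    r = stats.spearmanr(x, y)
    return {"coefficient": float(r.statistic), "p": float(r.pvalue), "method": "spearman"}


def verdicts_by_group(
    es_table: pd.DataFrame, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One ConvergenceVerdict per (group x statistic) from an es_battery table."""
    merged = es_table.merge(
        groups.rename("group"), left_on="plot", right_index=True, how="left"
    )
    rows = []
    for (group, statistic), sub in merged.groupby(["group", "statistic"]):
        es = sub["es"].to_numpy()
        es = es[np.isfinite(es)]
        if es.size < 3:  # too few plots for any one-sample test
            rows.append(
                {
                    "group": group,
                    "statistic": statistic,
                    "n": es.size,
                    "center": float(np.median(es)) if es.size else float("nan"),
                    "test": "none",
                    "p_value": float("nan"),
                    "verdict": "undetermined",
                }
            )
            continue
        v = convergence_test(es, alpha=alpha)
        rows.append(
            {
                "group": group,
                "statistic": statistic,
                "n": v.n,
                "center": v.center,
                "test": v.test,
                "p_value": v.p_value,
                "verdict": v.verdict,
            }
        )
    return pd.DataFrame(rows)
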
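"""Community-weighted competitiveness and its relation to functional divergence.

Each species carries a C-dimension score in [0, 1] — its position on the
competitor axis of Grime's CSR triangle, supplied as an input table. The
plot-level index is the community-weighted mean

    C_index = sum_i p_i * C_i

with p_i the relative abundance of species i. The ES RaoQ ~ C_index
relationship is fitted with ordinary least squares polynomials of degree
1..max_degree, the degree chosen by small-sample-corrected AIC.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .community import CommunityMatrix
from .errors import MissingValueError, ValidationError


def validate_c_table(c_values: pd.Series) -> pd.Series:
    c = pd.Series(c_values, dtype=float)
    if c.index.has_duplicates:
        raise ValidationError("duplicate species in C-dimension table")
    if ((c < 0) | (c > 1)).any() or c.isna().any():
        raise ValidationError("C-dimension values must lie in [0, 1]")
    return c


def c_index(abundances: pd.Series, c_values: pd.Series) -> float:
    """C_index = sum_i p_i C_i over the species present (p_i summing to 1)."""
    c = validate_c_table(c_values)
    p = pd.Series(abundances, dtype=float)
    p = p[p > 0]
    missing = [s for s in p.index if s not in c.index]
    if missing:
        raise MissingValueError(f"species without C-dimension value: {missing}")
    p = p / p.sum()
    return float((p * c.loc[p.index]).sum())


def c_index_per_plot(cm: CommunityMatrix, c_values: pd.Series) -> pd.Series:
    """C_index for every plot of a community matrix."""
    return pd.Series(
        {plot: c_index(cm.plot_relative_abundance(plot), c_values) for plot in cm.plots},
        name="c_index",
    )


def es_cindex_relation(
    c_index_per_plot_values, es_per_plot, max_degree: int = 3
) -> dict:
    """Polynomial OLS of ES on C_index with AICc degree selection.

    Returns ``{"degree", "coefficients" (ascending powers), "r2", "aicc",
    "degenerate"}``. A constant response yields R^2 = 0 with the degenerate
    flag set; degrees the data cannot support (fewer distinct C_index values
    than degree + 1) are skipped, and an error is raised if even a line
    cannot be fitted.
    """
    x = np.asarray(c_index_per_plot_values, dtype=float)
    y = np.asarray(es_per_plot, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < max_degree + 2:
        raise ValidationError(f"need >= {max_degree + 2} plots for degree {max_degree}")
    if np.ptp(y) == 0:
        return {
            "degree": 0,
            "coefficients": [float(y[0]) if n else float("nan")],
            "r2": 0.0,
            "aicc": float("nan"),
            "degenerate": True,
        }
    n_distinct = np.unique(x).size
    best = None
    for degree in range(1, max_degree + 1):
        n_params = degree + 2  # coefficients + intercept + error variance
        if n_distinct < degree + 1 or n - n_params - 1 <= 0:
            continue
        design = sm.add_constant(np.vander(x, degree + 1, increasing=True)[:, 1:])
        fit = sm.OLS(y, design).fit()
        aicc = fit.aic + 2.0 * n_params * (n_params + 1) / (n - n_params - 1)
        if best is None or aicc < best["aicc"]:
            best = {
                "degree": degree,
                "coefficients": list(map(float, fit.params)),
                "r2": float(fit.rsquared),
                "aicc": float(aicc),
                "degenerate": False,
            }
    if best is None:
        raise ValidationError(
            f"only {n_distinct} distinct C_index values; cannot fit any polynomial"
        )
    return best
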
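"""Synthetic species pools and plot communities with known assembly processes.

The generator emulates a Mediterranean vineyard weed survey: a pool of ~59
herbaceous species carrying the ten-trait schema (of which roughly half
survive the rare-cover screen in a typical realization), assembled into 32
plots labelled with the five management x irrigation classes. Three assembly
rules are available:

* ``neutral`` — species drawn uniformly without replacement; abundances
  independent of traits. Feeds type-I-error checks of the effect size.
* ``filtering`` — inclusion probability proportional to a Gaussian kernel
  exp(-dz^2 / 2 sigma^2) on the standardized distance between a species'
  (log-scaled where heavy-tailed) trait values and a plot optimum; a narrow
  sigma produces trait convergence.
* ``overdispersion`` — sequential acceptance proportional to the Gower
  distance to the nearest already-accepted species raised to a strength
  exponent; produces trait divergence (limiting similarity).

Optionally one competitor species with extreme height/leaf/seed traits and a
high C score is injected and its relative cover swept across plots,
emulating the role dominant competitive weeds (e.g. large-seeded bindweed or
tall sow-thistle) play in driving single-trait divergence.

Abundances are log-normal percent covers assigned to the selected species
independently of their traits, which yields the dominance structure
(species above the 3% relative-cover line) the mechanism analyses need.
All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .community import CLASS_FACTORS, CommunityMatrix
from .errors import ValidationError
from .traits import (
    DS_LEVELS,
    OFL_LEVELS,
    RLF_LEVELS,
    TraitTable,
    gower_distance,
    vineyard_trait_schema,
)

ASSEMBLY_KINDS = ("neutral", "filtering", "overdispersion")

#: traits compared on the log scale when standardizing for the filter kernel
HEAVY_TAILED = ("PHV", "LA", "SM")

#: site -> treatment class, mirroring the 8-site, 4-block field layout
SITE_CLASS = {1: "TNI", 2: "HI", 3: "TNI", 4: "TI", 5: "MNI", 6: "HI", 7: "MNI", 8: "MI"}

_EXHAUSTIVE_CAP = 200_000


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic dataset."""

    s_pool: int = 59
    n_plots: int = 32
    richness_range: tuple[int, int] = (6, 14)
    assembly: str = "neutral"
    #: optional per-treatment-class override of ``assembly`` (e.g. mown plots
    #: filtering, herbicide-irrigated plots neutral with an injected competitor)
    assembly_by_class: dict | None = field(default=None, hash=False, compare=False)
    filter_traits: tuple[str, ...] = ("PHV",)
    filter_sigma: float = 0.3  # kernel width in pool-SD units
    #: filter optimum in pool-SD units; None draws a fresh optimum per plot
    filter_optimum: float | None = None
    overdispersion_strength: float = 5.0
    abundance_sigma: float = 1.0  # sd of log percent cover
    total_cover_range: tuple[float, float] = (40.0, 90.0)
    trait_c_correlation: float = 0.7
    inject_competitor: bool = False
    competitor_trait_factors: dict = field(
        default_factory=lambda: {"SM": 10.0}, hash=False, compare=False
    )
    competitor_c: float = 0.85
    competitor_cover_range: tuple[float, float] = (0.0, 0.25)  # relative-cover sweep
    #: restrict the cover sweep to these treatment classes (None = all plots)
    competitor_classes: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        kinds = {self.assembly}
        if self.assembly_by_class:
            kinds |= set(self.assembly_by_class.values())
        for kind in kinds:
            if kind not in ASSEMBLY_KINDS:
                raise ValueError(f"unknown assembly {kind!r}")
        if self.richness_range[1] > self.s_pool:
            raise ValueError("richness range exceeds pool size")
        if self.filter_sigma <= 0:
            raise ValueError("filter_sigma must be > 0")


def mechanism_scenario(seed: int = 0, n_plots: int = 32) -> ScenarioConfig:
    """The competitiveness-mechanism study conditions: mown plots filter for
    short, small-leaved (low-C) species while a tall, large-leaved,
    heavy-seeded competitor with a high C score sweeps up in cover across the
    herbicide-irrigated and tilled-irrigated plots."""
    return ScenarioConfig(
        n_plots=n_plots,
        s_pool=29,
        assembly="neutral",
        assembly_by_class={"MNI": "filtering", "MI": "filtering"},
        filter_traits=("PHV", "LA"),
        filter_sigma=0.3,
        filter_optimum=-1.2,
        trait_c_correlation=0.9,
        inject_competitor=True,
        competitor_classes=("HI", "TI"),
        competitor_trait_factors={"SM": 10.0, "PHV": 3.0, "LA": 5.0},
        competitor_c=0.9,
        competitor_cover_range=(0.05, 0.4),
        seed=seed,
    )


@dataclass
class SyntheticDataset:
    traits: TraitTable
    community: CommunityMatrix
    c_table: pd.Series
    truth: pd.Series  # plot -> assembly label


def _substream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def generate_species_pool(
    s_pool: int = 59, seed: int = 0, trait_c_correlation: float = 0.7
) -> tuple[TraitTable, pd.Series]:
    """Draw a species pool and its C-dimension scores.

    Heavy-tailed size traits (PHV, LA, SM) are log-normal; leaf-economics
    traits (SLA, LDMC) and flowering duration are normal; SLI is uniform on
    [0, 1]; the categorical traits are multinomial with a therophyte-heavy
    life-form mix typical of disturbed Mediterranean plots. C scores are the
    normal CDF of a latent axis correlated with log height and log leaf area
    (taller, larger-leaved species compete better), plus independent noise.
    """
    rng = _substream(seed, 0)
    species = [f"sp{i + 1:03d}" for i in range(s_pool)]
    data = pd.DataFrame(
        {
            "RLF": rng.choice(RLF_LEVELS, s_pool, p=[0.60, 0.15, 0.15, 0.10]),
            "PHV": rng.lognormal(math.log(25.0), 0.6, s_pool),
            "SLA": np.clip(rng.normal(25.0, 6.0, s_pool), 5.0, None),
            "LDMC": np.clip(rng.normal(200.0, 50.0, s_pool), 50.0, None),
            "LA": rng.lognormal(math.log(300.0), 1.0, s_pool),
            "SM": rng.lognormal(math.log(1.0), 1.2, s_pool),
            "SLI": rng.uniform(0.0, 1.0, s_pool),
            "OFL": rng.choice(OFL_LEVELS, s_pool, p=[0.30, 0.40, 0.30]),
            "DFP": np.clip(rng.normal(4.0, 1.5, s_pool), 1.0, 10.0),
            "DS": rng.choice(DS_LEVELS, s_pool, p=[0.40, 0.30, 0.30]),
        },
        index=species,
    )
    table = TraitTable(data, vineyard_trait_schema())
    z = _zscore(0.5 * _zscore(np.log(data["PHV"])) + 0.5 * _zscore(np.log(data["LA"])))
    rho = trait_c_correlation
    latent = rho * z + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(s_pool)
    c = pd.Series(norm.cdf(latent), index=species, name="c_value")
    return table, c


def _zscore(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _filter_zmatrix(pool: TraitTable, filter_traits: tuple[str, ...]) -> np.ndarray:
    cols = []
    for name in filter_traits:
        if pool.schema[name].kind != "quantitative":
            raise ValidationError(
                f"filtering targets quantitative traits only, got {name}"
            )
        x = pool.data[name].to_numpy(dtype=float)
        if name in HEAVY_TAILED:
            x = np.log(x)
        cols.append(_zscore(x))
    return np.column_stack(cols)


def _select_filtering(
    z: np.ndarray,
    richness: int,
    sigma: float,
    rng: np.random.Generator,
    optimum_value: float | None = None,
) -> np.ndarray:
    if optimum_value is not None:
        optimum = np.full(z.shape[1], optimum_value)
    else:
        optimum = np.array(
            [rng.uniform(np.quantile(col, 0.1), np.quantile(col, 0.9)) for col in z.T]
        )
    logw = -((z - optimum) ** 2).sum(axis=1) / (2.0 * sigma**2)
    feasible = np.isfinite(logw) & (np.exp(logw - logw.max()) > 0)
    if feasible.sum() < richness:
        raise ValidationError(
            f"filter too narrow: only {int(feasible.sum())} species have "
            f"non-zero inclusion probability, need {richness}"
        )
    # Gumbel top-k draws a size-k sample without replacement with
    # probabilities proportional to exp(logw)
    keys = logw + rng.gumbel(size=len(logw))
    return np.sort(np.argsort(keys)[::-1][:richness])


def _select_overdispersed(
    d: np.ndarray, richness: int, strength: float, rng: np.random.Generator
) -> np.ndarray:
    n = d.shape[0]
    if math.isinf(strength):
        return _maxmin_set(d, richness, rng)
    accepted = [int(rng.integers(n))]
    while len(accepted) < richness:
        remaining = np.setdiff1d(np.arange(n), accepted)
        dmin = d[np.ix_(remaining, accepted)].min(axis=1)
        w = dmin**strength
        if w.sum() == 0:
            w = np.ones_like(w)
        accepted.append(int(rng.choice(remaining, p=w / w.sum())))
    return np.sort(accepted)


def _maxmin_set(d: np.ndarray, richness: int, rng: np.random.Generator) -> np.ndarray:
    """Set maximizing the minimum pairwise distance: exact for small problems."""
    n = d.shape[0]
    if math.comb(n, richness) <= _EXHAUSTIVE_CAP:
        best, best_val = None, -1.0
        for combo in itertools.combinations(range(n), richness):
            sub = d[np.ix_(combo, combo)]
            val = sub[np.triu_indices(richness, 1)].min()
            if val > best_val:
                best, best_val = combo, val
        return np.array(best)
    # greedy farthest-point fallback for large pools
    accepted = [int(rng.integers(n))]
    while len(accepted) < richness:
        remaining = np.setdiff1d(np.arange(n), accepted)
        dmin = d[np.ix_(remaining, accepted)].min(axis=1)
        accepted.append(int(remaining[np.argmax(dmin)]))
    return np.sort(accepted)


def assemble_plot(
    pool: TraitTable,
    scenario: ScenarioConfig,
    seed_or_rng: int | np.random.Generator = 0,
    gower: np.ndarray | None = None,
    filter_z: np.ndarray | None = None,
    assembly: str | None = None,
) -> np.ndarray:
    """One plot's abundance vector (percent cover, length = pool size).

    ``gower`` and ``filter_z`` allow precomputed matrices to be reused across
    plots; they are derived from the pool when absent. ``assembly`` overrides
    the scenario-level rule for this plot.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    assembly = assembly or scenario.assembly
    n = len(pool.species)
    richness = int(rng.integers(scenario.richness_range[0], scenario.richness_range[1] + 1))
    if assembly == "neutral":
        idx = np.sort(rng.choice(n, size=richness, replace=False))
    elif assembly == "filtering":
        if filter_z is None:
            filter_z = _filter_zmatrix(pool, scenario.filter_traits)
        idx = _select_filtering(
            filter_z, richness, scenario.filter_sigma, rng, scenario.filter_optimum
        )
    else:
        if gower is None:
            gower = gower_distance(pool).data
        idx = _select_overdispersed(
            gower, richness, scenario.overdispersion_strength, rng
        )
    covers = rng.lognormal(0.0, scenario.abundance_sigma, richness)
    covers *= rng.uniform(*scenario.total_cover_range) / covers.sum()
    abundance = np.zeros(n)
    abundance[rng.permutation(idx)] = covers  # cover ranks independent of traits
    return abundance


def _plot_metadata(n_plots: int) -> pd.DataFrame:
    rows = []
    for i in range(n_plots):
        site = (i % 8) + 1
        block = (i // 8) + 1
        cls = SITE_CLASS[site]
        wm, irr = CLASS_FACTORS[cls]
        rows.append(
            {
                "plot": f"p{i + 1:02d}",
                "weed_management": wm,
                "irrigation": irr,
                "site": site,
                "block": block,
                "year": 2018,
                "treatment_class": cls,
            }
        )
    return pd.DataFrame(rows).set_index("plot")


def generate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Full dataset: trait table, plot x species matrix with metadata,
    C-dimension table and per-plot ground-truth assembly labels."""
    pool, c_table = generate_species_pool(
        config.s_pool, seed=config.seed, trait_c_correlation=config.trait_c_correlation
    )
    metadata = _plot_metadata(config.n_plots)
    by_class = config.assembly_by_class or {}
    assemblies = [
        by_class.get(cls, config.assembly) for cls in metadata["treatment_class"]
    ]
    gower = gower_distance(pool).data if "overdispersion" in assemblies else None
    filter_z = (
        _filter_zmatrix(pool, config.filter_traits)
        if "filtering" in assemblies
        else None
    )
    rows = []
    for j, assembly in enumerate(assemblies):
        rng = _substream(config.seed, 1, j)
        rows.append(
            assemble_plot(
                pool, config, rng, gower=gower, filter_z=filter_z, assembly=assembly
            )
        )
    abundance = pd.DataFrame(rows, index=metadata.index, columns=pool.species)
    traits = pool
    if config.inject_competitor:
        traits, c_table, abundance = _inject_competitor(
            pool, c_table, abundance, metadata, config
        )
    community = CommunityMatrix(abundance, metadata)
    truth = pd.Series(assemblies, index=metadata.index, name="assembly")
    return SyntheticDataset(traits, community, c_table, truth)


def _inject_competitor(
    pool: TraitTable,
    c_table: pd.Series,
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    config: ScenarioConfig,
) -> tuple[TraitTable, pd.Series, pd.DataFrame]:
    """Add one competitor species with extreme trait values and sweep its
    relative cover linearly across the targeted plots."""
    rng = _substream(config.seed, 2)
    base = pool.data.iloc[int(rng.integers(len(pool.species)))].copy()
    for name, factor in config.competitor_trait_factors.items():
        if pool.schema[name].kind != "quantitative":
            raise ValidationError(f"competitor trait factor on non-quantitative {name}")
        base[name] = float(pool.data[name].max()) * factor
    base.name = "competitor"
    data = pd.concat([pool.data, base.to_frame().T])
    for col in data.columns:
        if pool.schema[col].kind == "quantitative":
            data[col] = data[col].astype(float)
    traits = TraitTable(data, pool.schema)
    c_table = pd.concat(
        [c_table, pd.Series({"competitor": config.competitor_c}, name=c_table.name)]
    )
    lo, hi = config.competitor_cover_range
    if config.competitor_classes is None:
        target = np.ones(len(abundance), dtype=bool)
    else:
        target = metadata["treatment_class"].isin(config.competitor_classes).to_numpy()
    fractions = np.zeros(len(abundance))
    fractions[target] = np.linspace(lo, hi, int(target.sum()))
    comp = np.zeros(len(abundance))
    totals = abundance.sum(axis=1).to_numpy()
    nonzero = fractions > 0
    comp[nonzero] = totals[nonzero] * fractions[nonzero] / (1.0 - fractions[nonzero])
    abundance = abundance.copy()
    abundance["competitor"] = comp
    return traits, c_table, abundance
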
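import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fdnull.errors import ValidationError
from fdnull.synthetic import (
    ScenarioConfig,
    SITE_CLASS,
    assemble_plot,
    generate_dataset,
    generate_species_pool,
)
from fdnull.traits import gower_distance

from conftest import one_trait_table


class TestSpeciesPool:
    def test_fixed_seed_reproducible(self):
        a, ca = generate_species_pool(30, seed=7)
        b, cb = generate_species_pool(30, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_series_equal(ca, cb)

    def test_sli_and_c_bounds(self):
        table, c = generate_species_pool(200, seed=1)
        assert table.data["SLI"].between(0, 1).all()
        assert c.between(0, 1).all()

    def test_trait_means_match_configuration_at_large_n(self):
        """Law-of-large-numbers check on the configured distributions."""
        table, _ = generate_species_pool(10_000, seed=3)
        n = 10_000
        # log PHV ~ Normal(log 25, 0.6)
        lp = np.log(table.data["PHV"])
        assert abs(lp.mean() - np.log(25.0)) < 3 * 0.6 / np.sqrt(n)
        # SLA ~ Normal(25, 6) (clipping at 5 is > 3 sd away, negligible)
        assert abs(table.data["SLA"].mean() - 25.0) < 3.5 * 6 / np.sqrt(n)
        # SLI uniform mean 1/2, sd 1/sqrt(12)
        assert abs(table.data["SLI"].mean() - 0.5) < 3 / np.sqrt(12 * n)

    def test_c_correlates_with_size_traits(self):
        table, c = generate_species_pool(2000, seed=5, trait_c_correlation=0.7)
        r = np.corrcoef(np.log(table.data["PHV"]), c)[0, 1]
        assert r > 0.3


class TestAssembly:
    def test_neutral_richness_within_range(self, pool20):
        table, _ = pool20
        cfg = ScenarioConfig(s_pool=20, richness_range=(4, 8))
        for seed in range(10):
            ab = assemble_plot(table, cfg, seed)
            assert 4 <= (ab > 0).sum() <= 8
            assert (ab >= 0).all()

    def test_wide_filter_equals_neutral_distribution(self, pool20):
        """sigma -> infinity: filtered trait means match neutral draws (KS)."""
        table, _ = pool20
        wide = ScenarioConfig(
            s_pool=20, richness_range=(6, 6), assembly="filtering",
            filter_traits=("PHV",), filter_sigma=1e6,
        )
        neutral = ScenarioConfig(s_pool=20, richness_range=(6, 6))
        phv = np.log(table.data["PHV"].to_numpy())

        def mean_draws(cfg, base):
            out = []
            for s in range(800):
                ab = assemble_plot(table, cfg, np.random.default_rng(base + s))
                out.append(phv[ab > 0].mean())
            return out

        ks = stats.ks_2samp(mean_draws(wide, 0), mean_draws(neutral, 10_000))
        assert ks.pvalue > 0.01

    def test_narrow_filter_shrinks_trait_variance(self, pool20):
        table, _ = pool20
        cfg = ScenarioConfig(
            s_pool=20, richness_range=(6, 6), assembly="filtering",
            filter_traits=("PHV",), filter_sigma=0.1,
        )
        phv = np.log(table.data["PHV"].to_numpy())
        pool_var = phv.var()
        shrunk = sum(
            phv[assemble_plot(table, cfg, np.random.default_rng(s)) > 0].var()
            < pool_var
            for s in range(100)
        )
        assert shrunk >= 95

    def test_fixed_optimum_centers_selection(self, pool20):
        table, _ = pool20
        cfg = ScenarioConfig(
            s_pool=20, richness_range=(5, 5), assembly="filtering",
            filter_traits=("PHV",), filter_sigma=0.2, filter_optimum=-1.0,
        )
        phv = np.log(table.data["PHV"].to_numpy())
        z = (phv - phv.mean()) / phv.std()
        means = [
            z[assemble_plot(table, cfg, np.random.default_rng(s)) > 0].mean()
            for s in range(50)
        ]
        assert np.mean(means) < -0.5

    def test_infinite_strength_matches_exhaustive_maxmin(self):
        """Overdispersion at infinite strength solves max-min dispersion."""
        rng = np.random.default_rng(4)
        for trial in range(5):
            values = rng.uniform(0, 100, size=10)
            table = one_trait_table(values)
            d = gower_distance(table).data
            cfg = ScenarioConfig(
                s_pool=10, richness_range=(4, 4), assembly="overdispersion",
                overdispersion_strength=float("inf"),
            )
            ab = assemble_plot(table, cfg, np.random.default_rng(trial))
            got = np.flatnonzero(ab > 0)
            best = max(
                (
                    min(d[a, b] for a, b in itertools.combinations(combo, 2))
                    for combo in itertools.combinations(range(10), 4)
                )
            )
            achieved = min(d[a, b] for a, b in itertools.combinations(got, 2))
            assert achieved == pytest.approx(best, abs=1e-12)

    def test_overdispersion_spreads_relative_to_neutral(self, pool20):
        table, _ = pool20
        d = gower_distance(table).data
        over = ScenarioConfig(
            s_pool=20, richness_range=(5, 5), assembly="overdispersion",
            overdispersion_strength=8.0,
        )
        neutral = ScenarioConfig(s_pool=20, richness_range=(5, 5))

        def mean_min_dist(cfg, base):
            vals = []
            for s in range(60):
                idx = np.flatnonzero(
                    assemble_plot(table, cfg, np.random.default_rng(base + s)) > 0
                )
                sub = d[np.ix_(idx, idx)]
                vals.append(sub[np.triu_indices(len(idx), 1)].min())
            return np.mean(vals)

        assert mean_min_dist(over, 0) > mean_min_dist(neutral, 5000)

    def test_infeasible_richness_raises(self, pool20):
        table, _ = pool20
        cfg = ScenarioConfig(
            s_pool=20, richness_range=(15, 15), assembly="filtering",
            filter_traits=("PHV",), filter_sigma=1e-4,
        )
        with pytest.raises(ValidationError):
            assemble_plot(table, cfg, 0)

    def test_categorical_filter_target_rejected(self, pool20):
        table, _ = pool20
        cfg = ScenarioConfig(
            s_pool=20, assembly="filtering", filter_traits=("DS",)
        )
        with pytest.raises(ValidationError):
            assemble_plot(table, cfg, 0)


class TestDataset:
    def test_class_counts_follow_site_layout(self):
        ds = generate_dataset(ScenarioConfig(n_plots=32, s_pool=20, seed=2))
        counts = ds.community.metadata["treatment_class"].value_counts()
        expected = pd.Series(
            [SITE_CLASS[s] for s in list(range(1, 9)) * 4]
        ).value_counts()
        assert counts.sort_index().equals(expected.sort_index())

    def test_fixed_seed_identical_dataset(self):
        a = generate_dataset(ScenarioConfig(n_plots=8, s_pool=15, seed=9))
        b = generate_dataset(ScenarioConfig(n_plots=8, s_pool=15, seed=9))
        pd.testing.assert_frame_equal(a.community.abundance, b.community.abundance)
        pd.testing.assert_frame_equal(a.traits.data, b.traits.data)

    def test_truth_labels_follow_class_map(self):
        ds = generate_dataset(
            ScenarioConfig(
                n_plots=16, s_pool=15, seed=1,
                assembly="neutral", assembly_by_class={"MNI": "filtering"},
            )
        )
        md = ds.community.metadata
        assert (ds.truth[md.treatment_class == "MNI"] == "filtering").all()
        assert (ds.truth[md.treatment_class != "MNI"] == "neutral").all()

    def test_injected_competitor_cover_sweep(self):
        cfg = ScenarioConfig(
            n_plots=8, s_pool=15, seed=3, inject_competitor=True,
            competitor_cover_range=(0.0, 0.25),
        )
        ds = generate_dataset(cfg)
        assert "competitor" in ds.community.species
        rel = (
            ds.community.abundance["competitor"]
            / ds.community.abundance.sum(axis=1)
        ).to_numpy()
        assert np.allclose(rel, np.linspace(0, 0.25, 8), atol=1e-9)
        sm = ds.traits.data["SM"]
        assert sm["competitor"] == pytest.approx(10 * sm.drop("competitor").max())
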
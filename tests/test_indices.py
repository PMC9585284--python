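import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdnull.community import CommunityMatrix
from fdnull.errors import ValidationError
from fdnull.indices import (
    FDConfig,
    compute_all,
    cwm,
    cwv,
    default_fric_axes,
    fdis,
    feve,
    fric,
    hull_volume,
    rao_q,
)
from fdnull.ordination import Ordination
from fdnull.synthetic import ScenarioConfig, generate_dataset


def make_ordination(points, ids=None) -> Ordination:
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    frame = pd.DataFrame(pts, index=ids, columns=[f"PCo{i+1}" for i in range(pts.shape[1])])
    ev = np.ones(pts.shape[1])
    return Ordination(frame, ev, ev / ev.sum(), "none", 0.0)


def reference_feve(dist: np.ndarray, w: np.ndarray) -> float:
    """Exhaustive-MST FEve oracle: enumerate all spanning trees."""
    s = len(w)
    edges = list(itertools.combinations(range(s), 2))
    best, best_total = None, np.inf
    for combo in itertools.combinations(edges, s - 1):
        # connectivity check by union-find
        parent = list(range(s))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for i, j in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[ri] = rj
        if not ok:
            continue
        total = sum(dist[i, j] for i, j in combo)
        if total < best_total - 1e-15:
            best_total, best = total, combo
    ew = np.array([dist[i, j] / (w[i] + w[j]) for i, j in best])
    pew = ew / ew.sum()
    ref = 1.0 / (s - 1)
    return (np.minimum(pew, ref).sum() - ref) / (1 - ref)


class TestFRic:
    def square_pool(self):
        return make_ordination([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])

    def test_full_pool_is_one(self):
        ordn = self.square_pool()
        assert fric(ordn, list(ordn.coordinates.index), k=2) == pytest.approx(1.0)

    def test_three_corners_of_unit_square_half(self):
        ordn = self.square_pool()
        assert fric(ordn, ["s0", "s1", "s2"], k=2) == pytest.approx(0.5)

    def test_collinear_community_degenerate_zero(self):
        ordn = make_ordination([[0, 0], [1, 0], [2, 0], [1, 1], [0, 2]])
        assert fric(ordn, ["s0", "s1", "s2"], k=2) == 0.0

    def test_too_few_species_rejected(self):
        ordn = self.square_pool()
        with pytest.raises(ValidationError):
            fric(ordn, ["s0", "s1"], k=2)

    def test_hull_volume_monotone_under_species_addition(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 2))
        vols = []
        for n in range(3, 13):
            vols.append(hull_volume(pts[:n])[0])
        assert all(b >= a - 1e-12 for a, b in zip(vols, vols[1:]))

    def test_shoelace_oracle_on_circle_points(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = rng.integers(4, 9)
            ang = np.sort(rng.uniform(0, 2 * np.pi, n))
            pts = np.c_[np.cos(ang), np.sin(ang)] * rng.uniform(1, 5)
            area, degenerate = hull_volume(pts)
            x, y = pts[:, 0], pts[:, 1]
            shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
            assert not degenerate
            assert area == pytest.approx(shoelace, abs=1e-10)

    def test_default_axis_rule(self):
        assert default_fric_axes(29, 6) == 4  # floor(log2(29))
        assert default_fric_axes(29, 4) == 3  # S_min - 1 binds
        assert default_fric_axes(4, 2) == 2  # floor at 2


class TestFEve:
    def test_equidistant_line_equal_abundance_is_one(self):
        coords = np.array([[0.0], [1.0], [2.0], [3.0]])
        assert feve(coords, [0.25] * 4) == pytest.approx(1.0)

    def test_undefined_below_three_species(self):
        assert np.isnan(feve(np.array([[0.0], [1.0]]), [0.5, 0.5]))

    def test_hand_evaluated_s3(self):
        # chain 0-1-2 with distances 1 and 1; w = (0.9, 0.05, 0.05)
        coords = np.array([[0.0], [1.0], [2.0]])
        w = np.array([0.9, 0.05, 0.05])
        ew = np.array([1 / 0.95, 1 / 0.1])
        pew = ew / ew.sum()
        expected = (np.minimum(pew, 0.5).sum() - 0.5) / 0.5
        assert feve(coords, w) == pytest.approx(expected, abs=1e-12)

    def test_duplicate_species_lowers_evenness(self):
        regular = feve(np.array([[0.0], [1.0], [2.0], [3.0]]), [0.25] * 4)
        with_dup = feve(np.array([[0.0], [0.0], [2.0], [3.0]]), [0.25] * 4)
        assert with_dup < regular

    def test_matches_exhaustive_mst_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            s = int(rng.integers(3, 6))
            coords = rng.normal(size=(s, 2))
            from scipy.spatial.distance import pdist, squareform

            dist = squareform(pdist(coords))
            w = rng.dirichlet(np.ones(s))
            assert feve(coords, w) == pytest.approx(
                reference_feve(dist, w), abs=1e-10
            )


class TestRaoQ:
    def test_monoculture_zero(self):
        assert rao_q(np.zeros((1, 1)), [1.0]) == 0.0

    def test_two_species_half(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert rao_q(d, [0.5, 0.5]) == pytest.approx(0.5)

    def test_bruteforce_double_sum(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = int(rng.integers(2, 8))
            m = rng.uniform(0, 1, (s, s))
            d = (m + m.T) / 2
            np.fill_diagonal(d, 0)
            p = rng.dirichlet(np.ones(s))
            expected = sum(
                p[i] * p[j] * d[i, j] for i in range(s) for j in range(s)
            )
            assert rao_q(d, p) == pytest.approx(expected, abs=1e-10)

    def test_bounded_by_max_distance(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(0, 1, (6, 6))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        p = rng.dirichlet(np.ones(6))
        assert rao_q(d, p) <= d.max()

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_species_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        s = 5
        m = rng.uniform(0, 1, (s, s))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        p = rng.dirichlet(np.ones(s))
        perm = rng.permutation(s)
        assert rao_q(d, p) == pytest.approx(
            rao_q(d[np.ix_(perm, perm)], p[perm]), abs=1e-12
        )

    def test_equal_abundance_reduces_to_unweighted_mean(self):
        rng = np.random.default_rng(8)
        s = 6
        m = rng.uniform(0, 1, (s, s))
        d = (m + m.T) / 2
        np.fill_diagonal(d, 0)
        assert rao_q(d, np.full(s, 1 / s)) == pytest.approx(d.sum() / s**2)


class TestFDisCwmCwv:
    def test_fdis_two_points(self):
        assert fdis(np.array([[0.0], [1.0]]), [0.5, 0.5]) == pytest.approx(0.5)

    def test_fdis_geometry_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5, 2))
        p = rng.dirichlet(np.ones(5))
        centroid = (p[:, None] * x).sum(axis=0)
        expected = (p * np.sqrt(((x - centroid) ** 2).sum(axis=1))).sum()
        assert fdis(x, p) == pytest.approx(expected, abs=1e-12)

    def test_cwm_quantitative(self):
        assert cwm([0.2, 0.6], [0.5, 0.5]) == pytest.approx(0.4)

    def test_cwm_bruteforce(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=8)
        p = rng.dirichlet(np.ones(8))
        assert cwm(x, p) == pytest.approx(float((x * p).sum()))

    def test_cwm_categorical_shares(self):
        shares = cwm(["a", "b", "a"], [0.5, 0.3, 0.2])
        assert shares["a"] == pytest.approx(0.7)
        assert shares["b"] == pytest.approx(0.3)

    def test_cwv_examples_and_identity(self):
        assert cwv([0.0, 2.0], [0.5, 0.5]) == pytest.approx(1.0)
        rng = np.random.default_rng(11)
        x = rng.normal(size=7)
        p = rng.dirichlet(np.ones(7))
        identity = float((p * x**2).sum() - ((p * x).sum()) ** 2)
        assert cwv(x, p) == pytest.approx(identity, abs=1e-10)

    def test_cwv_rejects_categorical(self):
        with pytest.raises(ValidationError):
            cwv(["a", "b"], [0.5, 0.5])

    def test_fdis_cwv_relation_1d(self):
        # in 1-D, FDis^2 <= CWV (Jensen)
        rng = np.random.default_rng(12)
        x = rng.normal(size=6)
        p = rng.dirichlet(np.ones(6))
        assert fdis(x[:, None], p) ** 2 <= cwv(x, p) + 1e-12


class TestComputeAll:
    def test_identical_plots_identical_rows(self, pool20):
        table, _ = pool20
        row = np.zeros(20)
        row[[0, 3, 5, 8, 11, 14]] = [5, 3, 2, 2, 1, 1]
        ab = pd.DataFrame([row, row], index=["p1", "p2"], columns=table.species)
        result = compute_all(CommunityMatrix(ab), table)
        pd.testing.assert_series_equal(
            result.loc["p1"], result.loc["p2"], check_names=False
        )

    def test_monoculture_edge_values(self, pool20):
        table, _ = pool20
        ab = pd.DataFrame(
            [np.r_[5.0, np.zeros(19)], np.r_[np.zeros(10), np.ones(10)]],
            index=["mono", "rich"],
            columns=table.species,
        )
        result = compute_all(CommunityMatrix(ab), table)
        mono = result.loc["mono"]
        assert mono["raoq"] == 0.0 and mono["fdis"] == 0.0
        assert np.isnan(mono["feve"]) and not mono["fric_defined"]

    def test_composition_matches_standalone_calls(self):
        ds = generate_dataset(ScenarioConfig(n_plots=6, s_pool=15, seed=21))
        from fdnull.ordination import pcoa
        from fdnull.traits import gower_distance

        result = compute_all(ds.community, ds.traits, FDConfig())
        dm = gower_distance(ds.traits)
        sp = pd.Index(ds.community.species)
        for plot in ds.community.plots:
            p = ds.community.plot_relative_abundance(plot)
            idx = sp.get_indexer(p.index)
            expected = rao_q(dm.data[np.ix_(idx, idx)], p.to_numpy())
            assert result.loc[plot, "raoq"] == pytest.approx(expected, abs=1e-12)
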
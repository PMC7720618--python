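"""Recombination-fraction EM vs a brute-force likelihood oracle, the Kosambi
map function, grouping/ordering, crossover counting and map diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from f2radmap import linkage, synth
from f2radmap.io import A, B, H, MISSING
from f2radmap.linkage import (
    GeneticMap,
    LinkageConfig,
    LinkageGroup,
    build_map,
    count_crossovers,
    estimate_rf,
    group_markers,
    inflation_diagnostics,
    kosambi_cM,
    kosambi_inverse,
    order_correlation,
    order_markers,
    pairwise_rf,
)
from tests.conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def two_locus_probs(r):
    """Nine F2 class probabilities written out independently of the package
    (locus1-major order AA, AH, AB, HA, HH, HB, BA, BH, BB)."""
    return np.array([
        (1 - r) ** 2 / 4, r * (1 - r) / 2, r**2 / 4,
        r * (1 - r) / 2, ((1 - r) ** 2 + r**2) / 2, r * (1 - r) / 2,
        r**2 / 4, r * (1 - r) / 2, (1 - r) ** 2 / 4,
    ])


def grid_search_rf(counts):
    grid = np.arange(0.0001, 0.5, 0.0001)
    probs = np.stack([two_locus_probs(r) for r in grid])  # (G, 9)
    with np.errstate(divide="ignore"):
        logp = np.log(probs)
    logp[np.isneginf(logp)] = -1e30
    ll = logp @ np.asarray(counts, dtype=float)
    return grid[int(np.argmax(ll))]


def simulate_pair(r, n, rng):
    """Two-locus F2 genotypes straight from the gamete definition."""
    g1a = rng.integers(0, 2, n)
    g1b = rng.integers(0, 2, n)
    rec_a = rng.random(n) < r
    rec_b = rng.random(n) < r
    g2a = np.where(rec_a, 1 - g1a, g1a)
    g2b = np.where(rec_b, 1 - g1b, g1b)
    return (g1a + g1b).astype(np.int8), (g2a + g2b).astype(np.int8)


# ---------------------------------------------------------------------------
# Kosambi
# ---------------------------------------------------------------------------

class TestKosambi:
    @pytest.mark.parametrize(
        "r,d",
        [(0.0, 0.0), (0.1, 25 * np.log(1.5)), (0.25, 25 * np.log(3.0))],
    )
    def test_closed_form(self, r, d):
        assert kosambi_cM(r) == pytest.approx(d, abs=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kosambi_cM(0.5)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)

    @given(st.floats(min_value=0.0, max_value=0.49))
    @settings(max_examples=200, derandomize=True)
    def test_mutual_inverses(self, r):
        assert kosambi_inverse(kosambi_cM(r)) == pytest.approx(r, abs=1e-10)
        d = kosambi_cM(r)
        assert kosambi_cM(kosambi_inverse(d)) == pytest.approx(d, abs=1e-10)


# ---------------------------------------------------------------------------
# EM recombination fraction
# ---------------------------------------------------------------------------

class TestEstimateRF:
    def test_identical_columns_give_zero(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, 200).astype(np.int8)
        est = estimate_rf(g, g)
        assert est.r == pytest.approx(0.0, abs=1e-6)
        assert est.lod > 20

    def test_independent_markers_near_half(self):
        rng = np.random.default_rng(1)
        g1, _ = simulate_pair(0.5, 500, rng)
        g2, _ = simulate_pair(0.5, 500, np.random.default_rng(2))
        est = estimate_rf(g1, g2)
        assert est.r == pytest.approx(0.5, abs=0.05)

    def test_em_equals_grid_search_oracle(self):
        # 100 random datasets: EM must land on the brute-force maximiser
        rng = np.random.default_rng(3)
        for _ in range(100):
            r_true = rng.uniform(0.02, 0.45)
            g1, g2 = simulate_pair(r_true, 200, rng)
            est = estimate_rf(g1, g2)
            r_grid = grid_search_rf(_counts(g1, g2))
            assert abs(est.r - r_grid) <= 1e-4

    def test_missing_calls_excluded(self):
        rng = np.random.default_rng(4)
        g1, g2 = simulate_pair(0.1, 300, rng)
        g1[:50] = MISSING
        est = estimate_rf(g1, g2)
        assert est.n_informative == 250

    def test_too_few_informative_rejected(self):
        g = np.array([A, B, H], dtype=np.int8)
        with pytest.raises(ValueError, match="jointly called"):
            estimate_rf(g, g)


def _counts(g1, g2):
    ok = (g1 != MISSING) & (g2 != MISSING)
    return np.bincount(3 * g1[ok].astype(int) + g2[ok], minlength=9)


def test_pairwise_rf_consistent_with_single_pairs():
    rng = np.random.default_rng(5)
    calls = np.column_stack(
        [simulate_pair(0.2, 150, rng)[0] for _ in range(6)]
    ).astype(np.int8)
    r, lod, n = pairwise_rf(calls)
    for i in range(6):
        for j in range(i + 1, 6):
            est = estimate_rf(calls[:, i], calls[:, j])
            # both solve the same likelihood to the EM tolerance of 1e-6
            assert r[i, j] == pytest.approx(est.r, abs=2e-6)
            assert lod[i, j] == pytest.approx(est.lod, abs=1e-5)


# ---------------------------------------------------------------------------
# grouping / ordering
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def two_chromosome_data():
    m = synth.SimMap.uniform(2, 25, length_cM=60.0, length_bp=2_000_000)
    b = synth.simulate_population(m, 200, 0, 0, np.random.default_rng(6))
    calls = b.truth.calls
    r, lod, _ = pairwise_rf(calls)
    return b.truth, r, lod


class TestGrouping:
    def test_two_chromosomes_give_two_groups(self, two_chromosome_data):
        matrix, r, lod = two_chromosome_data
        groups, _ = group_markers(r, lod)
        assert len(groups) == 2
        chroms = matrix.markers["chrom"].to_numpy()
        for g in groups:
            assert len(set(chroms[g])) == 1

    def test_unlinked_markers_all_discarded(self):
        # every marker on its own chromosome: all groups below min size
        m = synth.SimMap.uniform(10, 1, length_cM=50.0)
        b = synth.simulate_population(m, 150, 0, 0, np.random.default_rng(7))
        r, lod, _ = pairwise_rf(b.truth.calls)
        groups, discarded = group_markers(r, lod)
        assert groups == []
        assert sum(len(d) for d in discarded) == 10


class TestOrdering:
    def test_three_marker_chain_places_middle(self):
        r = np.array([[0, 0.01, 0.03], [0.01, 0, 0.02], [0.03, 0.02, 0]])
        order = order_markers(np.arange(3), r)
        # exhaustive: 0-1-2 (cost 0.03) beats 1-0-2 (0.04) and 0-2-1 (0.05)
        assert order[1] == 1

    def test_error_free_chromosome_order_recovered(self):
        m = synth.SimMap.uniform(1, 30, length_cM=90.0)
        b = synth.simulate_population(m, 250, 0, 0, np.random.default_rng(8))
        r, lod, _ = pairwise_rf(b.truth.calls)
        bp = b.truth.markers["bp"].to_numpy()
        order = order_markers(np.arange(30), r, bp=bp)
        assert list(order) == list(range(30)) or list(order) == list(range(29, -1, -1))

    def test_reference_mode_is_bp_order(self, two_chromosome_data):
        matrix, r, _ = two_chromosome_data
        cfg = LinkageConfig(ordering="reference")
        bp = matrix.markers["bp"].to_numpy()
        idx = np.arange(25)
        rng = np.random.default_rng(9)
        shuffled = rng.permutation(idx)
        order = order_markers(shuffled, r, cfg, bp)
        assert list(bp[order]) == sorted(bp[order])

    def test_single_marker_group_rejected(self):
        with pytest.raises(ValueError):
            order_markers(np.array([3]), np.zeros((5, 5)))


# ---------------------------------------------------------------------------
# map building and diagnostics
# ---------------------------------------------------------------------------

class TestBuildMap:
    def test_two_markers_at_r01(self, tiny_matrix_factory):
        mat = tiny_matrix_factory(np.zeros((4, 2), dtype=np.int8))
        r = np.array([[0, 0.1], [0.1, 0]])
        gmap = build_map(mat, [np.array([0, 1])], r)
        assert gmap.total_length_cM == pytest.approx(25 * np.log(1.5), abs=1e-9)

    def test_error_free_length_unbiased(self):
        m = synth.SimMap.uniform(1, 101, length_cM=100.0)
        b = synth.simulate_population(m, 200, 0, 0, np.random.default_rng(10))
        r, lod, _ = pairwise_rf(b.truth.calls)
        gmap = build_map(b.truth, [np.arange(101)], r)
        assert abs(gmap.total_length_cM - 100.0) < 15.0

    def test_empty_map(self):
        assert GeneticMap([]).total_length_cM == 0.0

    def test_error_injection_only_inflates(self):
        m = synth.SimMap.uniform(1, 150, length_cM=100.0)
        lengths = []
        for e in (0.0, 0.01, 0.03, 0.06):
            b = synth.simulate_bundle(
                m, 192, synth.ErrorModel(u_het_to_hom=e, e_hom_to_het=e), seed=11
            )
            obs = b.observed if e else b.truth
            r, lod = linkage.adjacent_rf(obs.calls[obs.progeny_index])
            lengths.append(kosambi_cM(np.clip(r, 0, 0.4999)).sum())
        assert lengths == sorted(lengths)


class TestOutliers:
    def test_permuted_marker_removed_clean_kept(self):
        m = synth.SimMap.uniform(1, 20, length_cM=40.0)
        b = synth.simulate_population(m, 250, 0, 0, np.random.default_rng(12))
        calls = b.truth.calls.copy()
        rng = np.random.default_rng(13)
        calls[:, 10] = calls[rng.permutation(250), 10]  # destroy linkage
        mat = b.truth.copy()
        mat.calls = calls
        r, lod, _ = pairwise_rf(calls)
        groups = [np.arange(20)]
        kept, removed = linkage.remove_outlier_markers(mat, groups, r)
        assert removed == ["chr1_M11"]
        # untouched data: nothing removed
        r2, lod2, _ = pairwise_rf(b.truth.calls)
        _, removed2 = linkage.remove_outlier_markers(b.truth, groups, r2)
        assert removed2 == []

    def test_threshold_half_removes_nothing(self):
        m = synth.SimMap.uniform(1, 10, length_cM=40.0)
        b = synth.simulate_population(m, 100, 0, 0, np.random.default_rng(14))
        r, lod, _ = pairwise_rf(b.truth.calls)
        cfg = LinkageConfig(outlier_rf_threshold=0.5)
        _, removed = linkage.remove_outlier_markers(b.truth, [np.arange(10)], r, cfg)
        assert removed == []


class TestCrossovers:
    def _map_for(self, matrix):
        table = matrix.markers.copy()
        table["cM"] = np.arange(len(table), dtype=float)
        return GeneticMap([LinkageGroup("c1", table[["id", "chrom", "bp", "cM"]])])

    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([A, A, A, A, A], 0),
            ([A, A, H, H, B], 2),
            ([A, B, A, A, A], 4),  # two double recombinants
            ([A, MISSING, H, MISSING, B], 2),  # missing skipped
        ],
    )
    def test_transition_counting(self, calls, expected, tiny_matrix_factory):
        mat = tiny_matrix_factory(np.array([calls], dtype=np.int8))
        xo = count_crossovers(mat, self._map_for(mat))
        assert xo.iloc[0, 0] == expected

    def test_two_marker_ab_counts_two(self, tiny_matrix_factory):
        mat = tiny_matrix_factory(np.array([[A, B]], dtype=np.int8))
        xo = count_crossovers(mat, self._map_for(mat))
        assert xo.iloc[0, 0] == 2


class TestOrderCorrelation:
    def _map_from_bp(self, bp):
        import pandas as pd
        table = pd.DataFrame(
            {"id": [f"m{i}" for i in range(len(bp))], "chrom": "c1",
             "bp": bp, "cM": np.arange(len(bp), dtype=float)}
        )
        return GeneticMap([LinkageGroup("c1", table)])

    def test_identical_orders(self):
        rho = order_correlation(self._map_from_bp(np.arange(10) * 100))
        assert rho["c1"] == pytest.approx(1.0)

    def test_one_adjacent_swap_closed_form(self):
        bp = np.arange(10) * 100
        bp[4], bp[5] = bp[5], bp[4]
        rho = order_correlation(self._map_from_bp(bp))
        assert rho["c1"] == pytest.approx(1 - 12 / 990, abs=1e-9)

    def test_random_order_uncorrelated(self):
        hits = 0
        for seed in range(60):
            bp = np.random.default_rng(seed).permutation(100) * 50
            rho = order_correlation(self._map_from_bp(bp))
            hits += abs(rho["c1"]) < 0.3
        assert hits >= 57  # >= 95%


class TestInflation:
    def _const_map(self, length, n=11):
        import pandas as pd
        table = pd.DataFrame(
            {"id": [f"m{i}" for i in range(n)], "chrom": "c1",
             "bp": np.arange(n) * 100 + 1,
             "cM": np.linspace(0, length, n)}
        )
        return GeneticMap([LinkageGroup("c1", table)])

    def test_identical_maps_ratio_one(self):
        d = inflation_diagnostics(self._const_map(50.0), self._const_map(50.0))
        assert d["ratio"] == pytest.approx(1.0)
        assert d["excess_per_interval_cM"] == pytest.approx(0.0)

    def test_empty_maps_rejected(self):
        with pytest.raises(ValueError):
            inflation_diagnostics(GeneticMap([]), GeneticMap([]))
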
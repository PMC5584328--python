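import numpy as np
import pytest

import invarnorm as iv
from invarnorm.selector import (
    SelectorConfig,
    _rank_ordered_values,
    edge_cost,
    inversion_count,
    normalized_distance,
    rank_genes,
    solve_cheapest_path,
)
from _oracles import brute_force_cheapest_path


def _solve(matrix, config):
    index = rank_genes(matrix, config)
    logv, raw = _rank_ordered_values(matrix, index, config)
    return index, logv, raw, solve_cheapest_path(index, logv, raw, config)


def _random_instance(rng, n=None, n_s=None, ref_prob=0.2):
    n = n or int(rng.integers(2, 13))
    n_s = n_s or int(rng.integers(2, 7))
    vals = rng.gamma(2.0, 10.0, size=(n, n_s))
    ids = [f"g{i}" for i in range(n)]
    refs = frozenset(np.array(ids)[rng.random(n) < ref_prob])
    cfg = SelectorConfig(
        m=float(rng.uniform(0, 6)),
        h=float(rng.uniform(0, 8)),
        r=float(rng.choice([0.0, 5.0, 800.0])),
        known_reference_ids=refs,
    )
    return iv.make_toy_matrix(vals, gene_ids=ids, kind="rpkm"), cfg


class TestRanking:
    def test_orders_by_mean_ascending(self):
        m = iv.make_toy_matrix([[5, 5], [1, 1], [3, 3]], gene_ids=list("abc"))
        index = rank_genes(m, SelectorConfig())
        assert index.gene_ids == ["b", "c", "a"]

    def test_all_zero_gene_excluded_and_recorded(self):
        m = iv.make_toy_matrix([[1, 1], [0, 0], [2, 2]], gene_ids=list("abc"))
        index = rank_genes(m, SelectorConfig())
        assert index.excluded_zero_genes == ["b"]
        assert "b" not in index.gene_ids

    def test_fewer_than_two_nonzero_genes_is_error(self):
        m = iv.make_toy_matrix([[1, 1], [0, 0]], gene_ids=list("ab"))
        with pytest.raises(ValueError):
            rank_genes(m, SelectorConfig())

    def test_counts_kind_rejected(self):
        m = iv.make_toy_matrix([[1, 1], [2, 2]], kind="counts")
        with pytest.raises(ValueError, match="rpkm"):
            rank_genes(m, SelectorConfig())

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 100, size=(100, 5))
        ids = [f"g{i:03d}" for i in range(100)]
        m = iv.make_toy_matrix(vals, gene_ids=ids)
        index = rank_genes(m, SelectorConfig())
        oracle = sorted(range(100), key=lambda i: (vals[i].mean(), ids[i]))
        assert index.gene_ids == [ids[i] for i in oracle]

    def test_unknown_or_zero_reference_dropped_with_warning(self):
        m = iv.make_toy_matrix([[1, 1], [0, 0], [2, 2]], gene_ids=list("abc"))
        cfg = SelectorConfig(known_reference_ids=frozenset({"b", "z", "a"}))
        with pytest.warns(UserWarning):
            index = rank_genes(m, cfg)
        flagged = [g for g, f in zip(index.gene_ids, index.is_known_reference) if f]
        assert flagged == ["a"]


class TestEdgeCostTerms:
    def test_identical_profiles_have_zero_distance(self):
        p = np.log2(np.array([3.0, 8.0, 1.0]) + 1)
        assert normalized_distance(p, p) == 0.0

    def test_constant_log_offset_has_zero_distance(self):
        p = np.array([1.0, 2.5, 4.0])
        assert normalized_distance(p, p + 3.7) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        # centered (+1,-1) vs (-1,+1), two samples: per-sample differences
        # (2, -2), so sqrt((2^2 + 2^2) / 2) = 2
        assert normalized_distance(
            np.array([1.0, -1.0]), np.array([-1.0, 1.0])
        ) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "ei,ej,k",
        [
            ((1, 2, 3), (2, 3, 4), 0),
            ((1, 2, 3), (0.5, 3, 4), 1),
            ((2, 2), (2, 2), 0),  # ties are not inversions
        ],
    )
    def test_inversion_count(self, ei, ej, k):
        assert inversion_count(np.array(ei), np.array(ej)) == k

    def test_adjacent_edge_cost_is_distance_only(self):
        m = iv.make_toy_matrix([[1, 2], [2, 4], [4, 8]])
        cfg = SelectorConfig()
        index = rank_genes(m, cfg)
        logv, raw = _rank_ordered_values(m, index, cfg)
        e = edge_cost(1, 2, index, logv, raw, cfg)
        assert e.cost == pytest.approx(e.d)

    def test_skip_and_inversion_penalties_with_defaults(self):
        # j = i+3 with k=2 adds 2*4.0 + 2*5.0 = 18 on top of d
        rng = np.random.default_rng(8)
        m = iv.make_toy_matrix(rng.uniform(1, 50, size=(5, 4)))
        cfg = SelectorConfig()
        index = rank_genes(m, cfg)
        logv, raw = _rank_ordered_values(m, index, cfg)
        e = edge_cost(1, 4, index, logv, raw, cfg)
        assert e.cost == pytest.approx(e.d + 2 * 4.0 + e.k * 5.0)

    def test_total_matches_from_scratch_recomputation(self):
        rng = np.random.default_rng(9)
        m = iv.make_toy_matrix(rng.uniform(1, 50, size=(8, 5)))
        cfg = SelectorConfig(m=2.5, h=3.5)
        index = rank_genes(m, cfg)
        logv, raw = _rank_ordered_values(m, index, cfg)
        for i, j in [(1, 2), (2, 7), (3, 8)]:
            e = edge_cost(i, j, index, logv, raw, cfg)
            pi, pj = logv[i - 1], logv[j - 1]
            d = float(
                np.sqrt(np.mean(((pi - pi.mean()) - (pj - pj.mean())) ** 2))
            )
            k = int(np.sum(raw[j - 1] < raw[i - 1]))
            assert e.cost == pytest.approx(d + (j - i - 1) * 2.5 + k * 3.5)

    def test_backward_edge_rejected(self):
        m = iv.make_toy_matrix([[1, 2], [2, 4]])
        cfg = SelectorConfig()
        index = rank_genes(m, cfg)
        logv, raw = _rank_ordered_values(m, index, cfg)
        with pytest.raises(ValueError):
            edge_cost(2, 2, index, logv, raw, cfg)


class TestCheapestPath:
    def test_identical_profiles_visit_every_gene(self):
        # with d = k = 0 everywhere, skipping costs m > 0, so take all nodes
        m = iv.make_toy_matrix([[1, 2], [2, 4], [4, 8]])
        _, _, _, sol = _solve(m, SelectorConfig())
        assert sol.ranks == [1, 2, 3]

    def test_path_is_strictly_increasing_from_source_to_target(self):
        rng = np.random.default_rng(10)
        m, cfg = _random_instance(rng, n=10, n_s=4)
        index, _, _, sol = _solve(m, cfg)
        assert sol.ranks[0] == 1 and sol.ranks[-1] == index.n
        assert all(b > a for a, b in zip(sol.ranks, sol.ranks[1:]))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            m, cfg = _random_instance(rng)
            index, logv, raw, sol = _solve(m, cfg)
            obj, path = brute_force_cheapest_path(index, logv, raw, cfg)
            assert sol.reward_adjusted == pytest.approx(obj, abs=1e-9)

    def test_large_reward_forces_reference_onto_path(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 100, size=(8, 3))
        ids = [f"g{i}" for i in range(8)]
        m = iv.make_toy_matrix(vals, gene_ids=ids)
        index = rank_genes(m, SelectorConfig())
        mid_gene = index.gene_ids[4]
        cfg = SelectorConfig(r=800.0, known_reference_ids=frozenset({mid_gene}))
        _, _, _, sol = _solve(m, cfg)
        assert mid_gene in sol.gene_ids
        assert sol.rejected_references == []

    def test_deterministic_byte_for_byte(self):
        rng1, rng2 = np.random.default_rng(77), np.random.default_rng(77)
        m1, c1 = _random_instance(rng1, n=12, n_s=5)
        m2, c2 = _random_instance(rng2, n=12, n_s=5)
        _, _, _, s1 = _solve(m1, c1)
        _, _, _, s2 = _solve(m2, c2)
        assert repr(s1) == repr(s2)


@pytest.fixture(scope="module")
def planted_small():
    """500 genes, 10 noise-free planted invariant genes, strong DE elsewhere."""
    cfg = iv.SimulationConfig(
        n_genes=500,
        n_invariant=10,
        fraction_de=1.0,
        responder_fraction=1.0,
        background_effect_sd=0.8,
        seed=0,
    )
    counts, lengths, truth = iv.simulate_dataset(cfg)
    return iv.compute_rpkm(counts, lengths), truth


@pytest.fixture(scope="module")
def fixed_instance():
    rng = np.random.default_rng(21)
    return iv.make_toy_matrix(rng.gamma(2.0, 20.0, size=(40, 6)))


class TestSelectInvariantGenes:
    def test_planted_genes_mostly_on_path(self, normalized_fixture):
        # exact-set recovery is a dense-plants, large-n property: assert it
        # on the canonical study-sized fixture
        _, _, truth, _, _, selected, _ = normalized_fixture
        missing = set(truth.invariant_gene_ids) - set(selected)
        assert len(missing) <= 0.2 * len(truth.invariant_gene_ids)

    def test_supplied_references_with_bounded_cost_all_kept(self, planted_small):
        rpkm, truth = planted_small
        refs = frozenset(truth.invariant_gene_ids[:6])
        sol, selected = iv.select_invariant_genes(
            rpkm, SelectorConfig(known_reference_ids=refs)
        )
        assert refs <= set(selected)

    def test_costly_reference_rejected_and_reported(self, planted_small):
        rpkm, truth = planted_small
        # the most strongly DE gene is a terrible "reference"
        worst = max(
            truth.de_effects,
            key=lambda g: sum(abs(e) for e in truth.de_effects[g].values()),
        )
        cfg = SelectorConfig(r=1.0, known_reference_ids=frozenset({worst}))
        with pytest.warns(UserWarning, match="rejected"):
            sol, selected = iv.select_invariant_genes(rpkm, cfg)
        assert worst in sol.rejected_references
        assert worst not in selected


class TestPenaltyResponse:
    def test_path_size_non_decreasing_in_m(self, fixed_instance):
        sizes = []
        for m_pen in (0.0, 1.0, 4.0, 16.0):
            _, sel = iv.select_invariant_genes(
                fixed_instance, SelectorConfig(m=m_pen)
            )
            sizes.append(len(sel))
        assert sizes == sorted(sizes)

    def test_path_inversions_non_increasing_in_h(self, fixed_instance):
        totals = []
        for h_pen in (0.0, 1.0, 5.0, 20.0):
            sol, _ = iv.select_invariant_genes(
                fixed_instance, SelectorConfig(h=h_pen)
            )
            totals.append(sol.total_inversions)
        assert totals == sorted(totals, reverse=True)

    def test_gene_count_varies_over_penalty_grid(self, fixed_instance):
        counts = {
            (m_pen, h_pen): len(
                iv.select_invariant_genes(
                    fixed_instance, SelectorConfig(m=m_pen, h=h_pen)
                )[1]
            )
            for m_pen in (0.5, 4.0)
            for h_pen in (0.5, 5.0)
        }
        assert len(set(counts.values())) > 1
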
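"""Subtree search: statistics, matching, recursion and its exhaustive oracle."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcss.community_tree import build_tree, classify_entities
from mcss.fixtures import sample_entity_preserving_subset
from mcss.subtree_search import (
    MatchInfeasibleError,
    ReferenceTooSmallError,
    TargetDrawer,
    brute_force_subtree,
    genus_stats,
    get_subtree,
    match_genus,
    sample_tree,
)
from conftest import make_search_db
from mcss.cli import _build_reference_tree
from mcss.reference_io import Lineage


class TestGenusStats:
    def test_constant_distances(self):
        stats = genus_stats([2, 2, 2], [1, 2, 3])
        assert stats.u == 2 and stats.sigma == 0
        assert stats.d_nref.tolist() == [2]

    def test_window_filter(self):
        stats = genus_stats([1, 3], [0.5, 1.5, 2.5, 3.5])
        assert stats.u == 2 and stats.sigma == 1
        assert stats.d_nref.tolist() == [1.5, 2.5]

    def test_empty_real_is_error(self):
        with pytest.raises(ValueError):
            genus_stats([], [1.0])

    @settings(max_examples=100, derandomize=True)
    @given(
        d_real=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=10),
        d_ref=st.lists(st.floats(0, 10, allow_nan=False), max_size=15),
    )
    def test_filter_matches_brute_force(self, d_real, d_ref):
        stats = genus_stats(d_real, d_ref)
        lo, hi = stats.u - stats.sigma, stats.u + stats.sigma
        expected = [y for y in d_ref if lo <= y <= hi]
        assert stats.d_nref.tolist() == pytest.approx(expected)
        assert stats.sigma >= 0


class TestTargetDrawer:
    def test_accurate_passes_through(self):
        drawer = TargetDrawer("accurate", seed=1)
        assert drawer.targets("g", "r", [1.0, 2.0], [5.0]).tolist() == [1.0, 2.0]

    def test_forced_p0_single_pool_element(self):
        drawer = TargetDrawer("prolific", seed=1, force_coin=0)
        targets = drawer.targets("g", "r", [1.0, 2.0], [1.5, 9.9])
        assert targets.tolist() == [1.5, 1.5]  # only 1.5 survives the window

    def test_forced_p0_empty_window_falls_back_to_real(self):
        drawer = TargetDrawer("prolific", seed=1, force_coin=0)
        targets = drawer.targets("g", "r", [1.0, 1.0], [9.9])
        assert set(targets.tolist()) <= {1.0}

    def test_draws_cached_and_deterministic(self):
        a = TargetDrawer("prolific", seed=7)
        b = TargetDrawer("prolific", seed=7)
        real, ref = [1.0, 2.0, 3.0], [0.5, 1.5, 2.5, 3.5]
        t1 = a.targets("g1", "rA", real, ref)
        assert a.targets("g1", "rA", real, ref) is t1  # cached
        assert b.targets("g1", "rA", real, ref).tolist() == t1.tolist()
        assert a.coin("g1") == b.coin("g1")


class TestMatchGenus:
    def test_documented_example(self):
        cost, assignment = match_genus([1.0, 2.0], [("a", 0.9), ("b", 2.2), ("c", 5.0)])
        assert cost == pytest.approx(0.3)
        assert assignment == [0, 1]

    def test_perfect_match_costs_zero(self):
        cost, _ = match_genus([1.0, 2.0], [("a", 1.0), ("b", 2.0)])
        assert cost == 0.0

    def test_too_few_candidates(self):
        with pytest.raises(MatchInfeasibleError):
            match_genus([1.0, 2.0], [("a", 1.0)])

    @settings(max_examples=60, derandomize=True)
    @given(st.data())
    def test_optimal_equals_enumeration_and_bounds_greedy(self, data):
        n_t = data.draw(st.integers(1, 5))
        n_c = data.draw(st.integers(n_t, 7))
        targets = data.draw(
            st.lists(st.floats(0, 5, allow_nan=False), min_size=n_t, max_size=n_t)
        )
        dists = data.draw(
            st.lists(st.floats(0, 5, allow_nan=False), min_size=n_c, max_size=n_c)
        )
        cand = [(f"c{i}", d) for i, d in enumerate(dists)]
        opt_cost, opt_assign = match_genus(targets, cand, method="optimal")
        greedy_cost, greedy_assign = match_genus(targets, cand, method="greedy")
        best = min(
            sum(abs(t - dists[j]) for t, j in zip(targets, perm))
            for perm in itertools.permutations(range(n_c), n_t)
        )
        assert opt_cost == pytest.approx(best, abs=1e-9)
        assert greedy_cost >= opt_cost - 1e-9
        assert len(set(opt_assign)) == n_t  # injective
        assert len(set(greedy_assign)) == n_t


class TestSampleTree:
    def test_single_tree_returned_as_copy(self, learned):
        trees, _ = learned
        chosen = sample_tree(trees[:1], np.random.default_rng(0))
        assert chosen.role == "T_sample"
        assert chosen.species() == trees[0].species()
        assert chosen.root is not trees[0].root

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            sample_tree([], np.random.default_rng(0))

    def test_deterministic_under_seed(self, learned):
        trees, _ = learned
        a = sample_tree(trees, np.random.default_rng(42))
        b = sample_tree(trees, np.random.default_rng(42))
        assert a.species() == b.species()

    def test_uniform_over_trees(self, db):
        lineages = db.species_lineages()
        names = db.species_names[:4]
        trees = [build_tree([sp], lineages, "T_real") for sp in names]
        rng = np.random.default_rng(3)
        counts = {sp: 0 for sp in names}
        for _ in range(4000):
            counts[sample_tree(trees, rng).species()[0]] += 1
        for sp in names:
            assert counts[sp] / 4000 == pytest.approx(0.25, abs=0.03)


def _annotated_ref(db):
    return _build_reference_tree(db)


def _sample_from_subset(db, species, role="T_sample"):
    from mcss.community_tree import annotate_distances

    tree = classify_entities(build_tree(species, db.species_lineages(), role))
    annotate_distances(tree, db.distance_oracle, db.representative)
    tree.role = role
    return tree


class TestGetSubtree:
    def test_embedded_identity_recovers_species(self, tmp_path):
        db, _ = make_search_db(51, tmp_path)
        t_ref = _annotated_ref(db)
        rng = np.random.default_rng(9)
        species = sample_entity_preserving_subset(t_ref, rng)
        t_sample = _sample_from_subset(db, species)
        result = get_subtree(t_sample, t_ref, mode="accurate", seed=0)
        assert result.min_dis == pytest.approx(0.0, abs=1e-9)
        assert sorted(result.species()) == sorted(species)

    def test_prolific_deterministic_under_seed(self, search_db):
        t_ref = _annotated_ref(search_db)
        rng = np.random.default_rng(4)
        species = sample_entity_preserving_subset(t_ref, rng)
        t_sample = _sample_from_subset(search_db, species)
        r1 = get_subtree(t_sample, t_ref, mode="prolific", seed=12)
        r2 = get_subtree(t_sample, t_ref, mode="prolific", seed=12)
        assert r1.min_dis == r2.min_dis
        assert r1.choice_node == r2.choice_node
        assert r1.species() == r2.species()

    def test_reference_too_small(self, search_db):
        t_ref = _annotated_ref(search_db)
        # a sampled genus with more species than any reference genus holds
        lineages = {
            f"X{i}": Lineage.from_string(
                f"d__D1;p__D1_P1;c__D1_C1;o__D1_O1;f__D1_F1;g__D1_F1_G1;s__X{i}"
            )
            for i in range(9)
        }
        t_sample = classify_entities(build_tree(list(lineages), lineages, "T_sample"))
        for node in t_sample.iter_nodes():
            node.entity_parent_distance = 0.1 if node.rank == "s" else None
        with pytest.raises(ReferenceTooSmallError):
            get_subtree(t_sample, t_ref, mode="accurate", seed=0)

    def test_species_counts_preserved_and_injective(self, search_db):
        t_ref = _annotated_ref(search_db)
        rng = np.random.default_rng(17)
        all_species = search_db.species_names
        for trial in range(10):
            k = int(rng.integers(3, min(12, len(all_species))))
            subset = list(rng.choice(all_species, size=k, replace=False))
            t_sample = _sample_from_subset(search_db, subset)
            result = get_subtree(t_sample, t_ref, mode="accurate", seed=trial)
            assert len(result.species()) == len(t_sample.species())
            by_parent: dict[str, list[str]] = {}
            for sample_path, (ref_path, _) in result.choice_node.items():
                parent = sample_path.rsplit("/", 1)[0] if "/" in sample_path else ""
                by_parent.setdefault(parent, []).append(ref_path)
            for chosen in by_parent.values():
                assert len(chosen) == len(set(chosen))

    def test_mapping_serialization(self, search_db, tmp_path):
        t_ref = _annotated_ref(search_db)
        species = search_db.species_names[:5]
        t_sample = _sample_from_subset(search_db, species)
        result = get_subtree(t_sample, t_ref, mode="accurate", seed=0)
        out = tmp_path / "mapping.tsv"
        result.write_mapping(out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("#min_dis\t")
        assert float(lines[0].split("\t")[1]) == result.min_dis
        assert len(lines) == 2 + len(result.choice_node)


class TestBruteForceOracle:
    def test_identity_embedding_costs_zero(self, tmp_path):
        db, _ = make_search_db(61, tmp_path)
        t_ref = _annotated_ref(db)
        species = sample_entity_preserving_subset(t_ref, np.random.default_rng(2))
        t_sample = _sample_from_subset(db, species)
        result = brute_force_subtree(t_sample, t_ref, mode="accurate", seed=0)
        assert result.min_dis == pytest.approx(0.0, abs=1e-9)

    def test_matches_recursive_search_both_modes(self, tmp_path):
        rng = np.random.default_rng(77)
        for i in range(10):
            db, _ = make_search_db(100 + i, tmp_path)
            t_ref = _annotated_ref(db)
            all_species = db.species_names
            k = int(rng.integers(3, min(12, len(all_species)) + 1))
            subset = list(rng.choice(all_species, size=k, replace=False))
            t_sample = _sample_from_subset(db, subset)
            for mode in ("accurate", "prolific"):
                opt = get_subtree(t_sample, t_ref, mode=mode, matching="optimal", seed=i)
                bf = brute_force_subtree(t_sample, t_ref, mode=mode, seed=i)
                assert opt.min_dis == pytest.approx(bf.min_dis, abs=1e-9), (i, mode)
                greedy = get_subtree(t_sample, t_ref, mode=mode, matching="greedy", seed=i)
                assert greedy.min_dis >= opt.min_dis - 1e-9

    def test_size_guard(self, db):
        t_ref = _annotated_ref(db)
        species = db.species_names[:5]
        t_sample = _sample_from_subset(db, species)
        with pytest.raises(ValueError, match="too large"):
            brute_force_subtree(t_sample, t_ref, max_species=10)
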
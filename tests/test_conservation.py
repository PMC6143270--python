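"""Overlap statistics, permutation nulls, Fisher baseline, Venn counts."""

from fractions import Fraction

import numpy as np
import pytest

import adenoconserv as ac
from adenoconserv.conservation import ConservationError

GENERA = ("mouse", "rat", "human")


def triad(universe, up, down=None):
    if down is None:
        used = set().union(*up.values())
        free = [a for a in sorted(universe.anchors) if a not in used]
        down = {g: frozenset({free[i]}) for i, g in enumerate(GENERA)}
    return ac.TriadLists(
        up={g: frozenset(s) for g, s in up.items()},
        down={g: frozenset(s) for g, s in down.items()},
        universe=universe,
    )


class TestOverlapFraction:
    def test_half(self):
        assert ac.overlap_fraction({"a", "b", "c", "d"}, {"a", "b"}) == 0.5

    def test_identity_and_disjoint(self):
        assert ac.overlap_fraction({"a", "b"}, {"a", "b"}) == 1.0
        assert ac.overlap_fraction({"a"}, {"b"}) == 0.0

    def test_empty_source_error(self):
        with pytest.raises(ConservationError):
            ac.overlap_fraction(set(), {"a"})


class TestMeanOverlap:
    def test_hand_enumerated_six_pairs(self):
        stat = ac.mean_overlap(
            {"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3, 4, 5}}
        )
        assert stat.mean_fraction == pytest.approx(10 / 18)
        assert len(stat.pair_fractions) == 6

    def test_identical_and_disjoint(self):
        assert ac.mean_overlap({k: {1, 2} for k in "ABC"}).mean_fraction == 1.0
        assert (
            ac.mean_overlap({"A": {1}, "B": {2}, "C": {3}}).mean_fraction == 0.0
        )

    def test_relabeling_invariance(self):
        """Applying one bijection to every list leaves the statistic fixed."""
        rng = np.random.default_rng(0)
        lists = {
            k: set(rng.choice(100, size=m, replace=False))
            for k, m in zip("ABC", (10, 20, 30))
        }
        perm = rng.permutation(1000)
        relabeled = {k: {int(perm[x]) for x in s} for k, s in lists.items()}
        assert (
            ac.mean_overlap(lists).mean_fraction
            == ac.mean_overlap(relabeled).mean_fraction
        )


class TestFisherBaseline:
    def test_exact_hypergeometric_tail(self):
        """N=20, |A|=|B|=10, overlap 9 -> p = 101 / C(20,10)."""
        a = set(range(10))
        b = set(range(1, 10)) | {15}
        assert len(a & b) == 9
        _, p = ac.fisher_baseline(a, b, 20)
        assert p == pytest.approx(float(Fraction(101, 184756)), rel=1e-9)

    def test_disjoint_lists_p_one(self):
        _, p = ac.fisher_baseline(set(range(5)), set(range(10, 15)), 100)
        assert p == pytest.approx(1.0)

    def test_forced_overlap_degenerate(self):
        universe = set(range(10))
        _, p = ac.fisher_baseline({0, 1, 2}, universe, 10)
        assert p == pytest.approx(1.0)

    def test_universe_too_small(self):
        with pytest.raises(ConservationError):
            ac.fisher_baseline({1, 2, 3}, {4, 5, 6}, 4)


class TestGenePermTest:
    def test_identical_lists_minimal_p(self, make_identity_universe):
        universe = make_identity_universe(200)
        shared = {f"g{i:05d}" for i in range(10)}
        lists = triad(universe, {g: shared for g in GENERA})
        res = ac.gene_perm_test(lists, "up", B=99, seed=1)
        assert res.observed == 1.0
        if res.null_values.max() < 1.0:
            assert res.p_value == pytest.approx(1 / 100)

    def test_null_mean_matches_analytic(self, make_identity_universe):
        universe = make_identity_universe(500)
        rng = np.random.default_rng(3)
        up = {
            g: {f"g{i:05d}" for i in rng.choice(500, size=m, replace=False)}
            for g, m in zip(GENERA, (40, 60, 80))
        }
        lists = triad(universe, up)
        res = ac.gene_perm_test(lists, "up", B=400, seed=5)
        expected = ac.analytic_null_mean({g: len(up[g]) for g in GENERA}, 500)
        se = res.null_values.std(ddof=1) / np.sqrt(res.B)
        assert abs(res.null_values.mean() - expected) < 3 * se

    def test_determinism_and_p_convention(self, make_identity_universe):
        universe = make_identity_universe(100)
        rng = np.random.default_rng(7)
        up = {
            g: {f"g{i:05d}" for i in rng.choice(100, size=20, replace=False)}
            for g in GENERA
        }
        lists = triad(universe, up)
        r1 = ac.gene_perm_test(lists, "up", B=49, seed=11)
        r2 = ac.gene_perm_test(lists, "up", B=49, seed=11)
        np.testing.assert_array_equal(r1.null_values, r2.null_values)
        r = int(np.sum(r1.null_values >= r1.observed))
        assert r1.p_value == (r + 1) / 50


class TestGoPermTest:
    def _setup(self, make_identity_universe, n=300, seed=0):
        universe = make_identity_universe(n)
        anchors = sorted(universe.anchors)
        rng = np.random.default_rng(seed)
        categories = {}
        for k in range(12):
            members = rng.choice(anchors, size=15, replace=False)
            categories[f"C{k:02d}"] = (f"cat {k}", frozenset(members))
        annotation = ac.GeneSetCollection(categories)
        return universe, anchors, annotation

    def test_replicates_preserve_category_sizes_and_lists(self, make_identity_universe):
        universe, anchors, annotation = self._setup(make_identity_universe)
        # lists strongly aligned with category C00 in every genus
        base = set(annotation.members("C00"))
        lists = triad(universe, {g: base for g in GENERA})
        res = ac.go_perm_test(
            lists, annotation, "up",
            {"z_min": 2.0, "min_size": 5, "min_count": 3}, B=30, seed=2,
        )
        assert res.flag is None
        assert res.observed == 1.0  # identical gene lists -> identical enriched lists
        assert res.p_value == pytest.approx(
            (int(np.sum(res.null_values >= 1.0)) + 1) / 31
        )

    def test_agrees_with_enrichment_module_at_observed_stage(self, make_identity_universe):
        universe, anchors, annotation = self._setup(make_identity_universe, seed=4)
        rng = np.random.default_rng(9)
        up = {
            g: set(rng.choice(anchors, size=40, replace=False)) for g in GENERA
        }
        lists = triad(universe, up)
        params = {"z_min": 1.0, "min_size": 5, "min_count": 1}
        res = ac.go_perm_test(lists, annotation, "up", params, B=5, seed=0)
        for genus in GENERA:
            rows = ac.enrich_all(lists.up[genus], annotation, universe)
            expected = set(
                ac.enriched_terms(rows, z_min=1.0, min_size=5, min_count=1)
            )
            assert set(res.extra["enriched_ids"][genus]) == expected

    def test_everything_enriched_gives_p_one(self, make_identity_universe):
        """A gate every category always passes makes the statistic constant."""
        universe, anchors, annotation = self._setup(make_identity_universe)
        lists = triad(universe, {g: set(anchors[:30]) for g in GENERA})
        res = ac.go_perm_test(
            lists, annotation, "up",
            {"z_min": -100.0, "min_size": 1, "min_count": 0}, B=19, seed=1,
        )
        assert res.observed == 1.0
        assert np.all(res.null_values == 1.0)
        assert res.p_value == 1.0

    def test_empty_observed_list_flagged(self, make_identity_universe):
        universe, anchors, annotation = self._setup(make_identity_universe)
        lists = triad(universe, {g: {anchors[0]} for g in GENERA})
        res = ac.go_perm_test(
            lists, annotation, "up",
            {"z_min": 50.0, "min_size": 5, "min_count": 3}, B=9, seed=1,
        )
        assert res.flag is not None
        assert np.isnan(res.p_value)


class TestVennCounts:
    def test_hand_enumeration(self, make_identity_universe):
        universe = make_identity_universe(100)
        lists = triad(
            universe,
            up={"mouse": {"g00000", "g00001"}, "rat": {"g00001", "g00002"},
                "human": {"g00001"}},
            down={"mouse": set(), "rat": set(), "human": set()},
        )
        venn = ac.venn_counts(lists)
        assert venn.triple_consistent_up == 1
        assert venn.regions["up"]["mouse_only"] == 1
        assert venn.regions["up"]["all_three"] == 1
        assert venn.triple_consistent_down == 0

    def test_empty_lists_all_zero(self, make_identity_universe):
        universe = make_identity_universe(10)
        lists = triad(universe, {g: set() for g in GENERA},
                      down={g: set() for g in GENERA})
        venn = ac.venn_counts(lists)
        assert all(v == 0 for v in venn.regions["up"].values())

    def test_region_counts_sum_to_list_sizes(self, make_identity_universe):
        universe = make_identity_universe(200)
        rng = np.random.default_rng(13)
        anchors = sorted(universe.anchors)
        up = {g: set(rng.choice(anchors, size=m, replace=False))
              for g, m in zip(GENERA, (30, 40, 50))}
        lists = triad(universe, up)
        venn = ac.venn_counts(lists)
        r = venn.regions["up"]
        assert r["mouse_only"] + r["mouse_rat"] + r["mouse_human"] + r["all_three"] == 30
        assert r["rat_only"] + r["mouse_rat"] + r["rat_human"] + r["all_three"] == 40
        assert r["human_only"] + r["mouse_human"] + r["rat_human"] + r["all_three"] == 50


def test_triad_rejects_overlapping_directions(make_identity_universe):
    universe = make_identity_universe(10)
    with pytest.raises(ConservationError):
        ac.TriadLists(
            up={g: frozenset({"g00001"}) for g in GENERA},
            down={g: frozenset({"g00001"}) for g in GENERA},
            universe=universe,
        )
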
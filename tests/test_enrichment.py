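"""Standardized-hypergeometric scores, gates, and greedy dominant covering."""

import numpy as np
import pytest

import adenoconserv as ac
from adenoconserv.enrichment import EnrichmentError
from conftest import identity_universe


def universe_of(n):
    return identity_universe(n)


def anchors_of(universe):
    return sorted(universe.anchors)


class TestEnrichScore:
    def test_moments_by_hand(self):
        """N=10, m=4, G=5, X=4: expected 2, variance 2/3."""
        row = ac.enrich_score(
            {"a", "b", "c", "d"},
            {"a", "b", "c", "d", "e"},
            10,
        )
        assert row.X == 4 and row.expected == pytest.approx(2.0)
        assert row.z == pytest.approx(2.0 / np.sqrt(2 / 3), rel=1e-12)
        assert row.set_mean == pytest.approx(4 / 5)

    def test_observed_at_expectation_gives_zero(self):
        row = ac.enrich_score({"a", "b"}, {"a", "x", "y", "z", "w"}, 10)
        assert row.X == 1 and row.z == pytest.approx(0.0)

    def test_zero_variance_configurations_rejected(self):
        with pytest.raises(EnrichmentError):
            ac.enrich_score({"a"}, set(), 10)
        with pytest.raises(EnrichmentError):
            ac.enrich_score({"a"}, {f"x{i}" for i in range(10)}, 10)
        with pytest.raises(EnrichmentError):
            ac.enrich_score(set(), {"a"}, 10)

    def test_exact_tail_option(self):
        from scipy import stats

        row = ac.enrich_score(set("abcd"), set("abcde"), 10, exact=True)
        assert row.p == pytest.approx(stats.hypergeom.sf(3, 10, 5, 4))

    def test_mirror_count_flips_z(self):
        """Replacing X by 2*expected - X flips the sign of z exactly."""
        from adenoconserv.conservation import _standardized_counts

        n, m = 40, 12
        g = np.array([10])
        for x in range(0, 11):
            z1 = _standardized_counts(np.array([x]), g, m, n)[0]
            mirror = 2 * (m * g[0] / n) - x
            z2 = _standardized_counts(np.array([mirror]), g, m, n)[0]
            assert z2 == pytest.approx(-z1, abs=1e-12)


class TestEnrichAll:
    def _collection(self):
        return ac.GeneSetCollection(
            {
                "c1": ("one", frozenset({"g00001", "g00002", "g00003"})),
                "c2": ("two", frozenset({"g00004", "g00005"})),
                "c3": ("three", frozenset({"g00001", "g00006", "g00007", "g00008"})),
            }
        )

    def test_size_filter(self):
        universe = universe_of(20)
        rows = ac.enrich_all({"g00001"}, self._collection(), universe, min_size=3)
        assert set(rows["category_id"]) == {"c1", "c3"}

    def test_row_count_independent_of_list(self):
        universe = universe_of(20)
        r1 = ac.enrich_all({"g00001"}, self._collection(), universe)
        r2 = ac.enrich_all({"g00004", "g00009"}, self._collection(), universe)
        assert len(r1) == len(r2) == 3

    def test_tie_break_lexicographic(self):
        universe = universe_of(20)
        collection = ac.GeneSetCollection(
            {
                "b": ("B", frozenset({"g00001", "g00002"})),
                "a": ("A", frozenset({"g00003", "g00004"})),
            }
        )
        rows = ac.enrich_all({"g00010"}, collection, universe)
        assert rows["category_id"].tolist() == ["a", "b"]  # equal z, id order


class TestEnrichedTerms:
    def _rows(self):
        universe = universe_of(1000)
        anchors = anchors_of(universe)
        collection = ac.GeneSetCollection(
            {
                "big_hit": ("bh", frozenset(anchors[:12])),
                "small_hit": ("sh", frozenset(anchors[:9])),
                "weak": ("w", frozenset(anchors[500:515])),
            }
        )
        gene_list = set(anchors[:30])
        return ac.enrich_all(gene_list, collection, universe)

    def test_gates(self):
        rows = self._rows()
        kept = ac.enriched_terms(rows, z_min=5.0, min_size=10, min_count=3)
        assert kept == ["big_hit"]  # small_hit fails min_size, weak fails z

    def test_min_count_gate(self):
        rows = self._rows()
        kept = ac.enriched_terms(rows, z_min=5.0, min_size=10, min_count=13)
        assert kept == []

    def test_monotone_in_z_threshold(self):
        rows = self._rows()
        previous = None
        for z_min in (0.0, 1.0, 3.0, 5.0, 8.0):
            kept = set(ac.enriched_terms(rows, z_min=z_min, min_size=1, min_count=0))
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_requires_a_gate(self):
        with pytest.raises(EnrichmentError):
            ac.enriched_terms(self._rows())


def brute_force_greedy(gene_list, selected):
    """Independent re-derivation of the greedy dominant-category ordering."""
    gene_list = set(gene_list)
    covered, order, gains = set(), [], []
    remaining = {cid: set(m) & gene_list for cid, m in selected.items()}
    while remaining:
        scored = sorted(
            remaining,
            key=lambda cid: (-len(remaining[cid] - covered), -len(remaining[cid]), cid),
        )
        best = scored[0]
        gain = len(remaining[best] - covered)
        if gain == 0:
            break
        order.append(best)
        gains.append(gain)
        covered |= remaining.pop(best)
    return order, gains


class TestGreedyCover:
    def test_hand_example(self):
        cover = ac.greedy_cover(
            {"a", "b", "c", "d", "e"},
            {"C1": {"a", "b", "c"}, "C2": {"c", "d"}, "C3": {"d", "e"}},
        )
        assert cover.category_ids == ["C1", "C3"]
        assert cover.newly_covered == [3, 2]
        assert cover.cumulative_covered == [3, 5]

    def test_single_covering_category(self):
        cover = ac.greedy_cover({"a", "b"}, {"C1": {"a", "b", "z"}})
        assert cover.category_ids == ["C1"] and cover.newly_covered == [1 + 1]

    def test_tie_break_lexicographic(self):
        cover = ac.greedy_cover(
            {"a", "b", "c", "d"}, {"Cb": {"a", "b"}, "Ca": {"c", "d"}}
        )
        assert cover.category_ids == ["Ca", "Cb"]

    def test_empty_list_empty_ordering(self):
        assert ac.greedy_cover(set(), {"C1": {"a"}}).category_ids == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            pool = [f"x{i}" for i in range(rng.integers(5, 25))]
            gene_list = set(rng.choice(pool, size=rng.integers(1, len(pool)), replace=False))
            n_cats = rng.integers(1, 13)
            selected = {
                f"C{k:02d}": set(
                    rng.choice(pool, size=rng.integers(1, len(pool) + 1), replace=False)
                )
                for k in range(n_cats)
            }
            cover = ac.greedy_cover(gene_list, selected)
            ref_order, ref_gains = brute_force_greedy(gene_list, selected)
            assert cover.category_ids == ref_order
            assert cover.newly_covered == ref_gains
            covered_union = set().union(
                *(selected[c] for c in cover.category_ids), set()
            )
            assert sum(cover.newly_covered) == len(gene_list & covered_union)


class TestUnionEnrichment:
    def test_union_and_membership_flags(self, small_dataset, small_universe):
        _, annotation, studies, truth = small_dataset
        lists = ac.TriadLists(
            up={g: truth.up[g] for g in truth.up},
            down={g: truth.down[g] for g in truth.down},
            universe=small_universe,
        )
        rows, cover, membership = ac.union_enrichment(
            lists, "up", annotation, small_universe,
            gates={"z_min": 1.0, "min_size": 3, "min_count": 1},
        )
        union = frozenset().union(*truth.up.values())
        assert set(membership.index) == union
        assert (membership.sum(axis=1) >= 1).all()

    def test_disjoint_lists_union_size(self, make_identity_universe):
        universe = universe_of(100)
        anchors = anchors_of(universe)
        lists = ac.TriadLists(
            up={
                "mouse": frozenset(anchors[0:5]),
                "rat": frozenset(anchors[5:12]),
                "human": frozenset(anchors[12:20]),
            },
            down={g: frozenset() for g in ("mouse", "rat", "human")},
            universe=universe,
        )
        collection = ac.GeneSetCollection({"c1": ("c", frozenset(anchors[:15]))})
        _, _, membership = ac.union_enrichment(
            lists, "up", collection, universe,
            gates={"z_min": 0.0, "min_size": 1, "min_count": 0},
        )
        assert len(membership) == 20

    def test_planted_category_recovered(self):
        """Category-level planting shows up in each genus's enriched terms."""
        cfg = ac.SynthConfig(
            n_genes=800, conservation_mode="category_level",
            n_private_up=40, n_private_down=40,
            n_categories=30, n_planted_categories=3,
            category_size_range=(18, 27),
            effect_log2=1.3, noise_sd=0.2, seed=17,
        )
        omap = ac.generate_universe(cfg)
        annotation = ac.generate_annotation(cfg, omap)
        studies, truth = ac.generate_studies(cfg, omap, annotation)
        universe = ac.link_universe(
            omap, {g: set(s.gene_ids) for g, s in studies.items()}
        )
        hits = []
        for genus, study in studies.items():
            calls = ac.call_directional(ac.paired_de(study))
            up = ac.project_list(universe, genus, set(calls.up))
            rows = ac.enrich_all(up, annotation, universe)
            kept = set(ac.enriched_terms(rows, z_min=2.5, min_size=10, min_count=3))
            hits.append(truth.planted_categories & kept)
        assert all(hits), "every genus should recover at least one planted category"
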
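"""Cross-genus agreement of differential gene lists.

The central statistic is the mean-overlap fraction: for an ordered pair of
genus lists, the proportion of the source list contained in the target
list, averaged over all ordered pairs (six for three genera).  Its
significance is assessed two ways:

* :func:`gene_perm_test` — gene-level null: each replicate redraws every
  genus's list as a uniform random subset of the linked universe of the
  same size, independently per genus.
* :func:`go_perm_test` — functional-category-level null that holds the
  gene-level agreement fixed: gene lists are never touched; instead each
  replicate relabels the universe by one random bijection applied to the
  (anchor-based, hence genus-shared) category memberships, and the
  per-genus enriched-category lists are recomputed.  Category sizes are
  preserved exactly.

Permutation p-values use the (r + 1) / (B + 1) convention with ties counted
as at least as extreme (so the smallest attainable p is 1 / (B + 1)).
:func:`fisher_baseline` provides the pairwise exact-test baseline, and
:func:`venn_counts` the three-set region counts plus the triply consistent
gene tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import GENERA, GeneSetCollection
from .orthomap import LinkedUniverse


class ConservationError(ValueError):
    pass


@dataclass
class TriadLists:
    """Per-genus up/down anchor lists on a shared linked universe."""

    up: dict[str, frozenset[str]]
    down: dict[str, frozenset[str]]
    universe: LinkedUniverse

    def __post_init__(self) -> None:
        for genus in GENERA:
            if genus not in self.up or genus not in self.down:
                raise ConservationError(f"missing genus {genus!r}")
            if self.up[genus] & self.down[genus]:
                raise ConservationError(f"{genus}: up and down lists overlap")
            stray = (self.up[genus] | self.down[genus]) - self.universe.anchors
            if stray:
                raise ConservationError(
                    f"{genus}: {len(stray)} list members outside the universe"
                )

    def direction(self, direction: str) -> dict[str, frozenset[str]]:
        if direction not in ("up", "down"):
            raise ConservationError(f"direction must be 'up' or 'down', got {direction!r}")
        return self.up if direction == "up" else self.down


@dataclass
class OverlapStat:
    pair_fractions: dict[tuple[str, str], float]
    mean_fraction: float


@dataclass
class PermutationResult:
    observed: float
    B: int
    null_values: np.ndarray
    p_value: float
    seed: int
    flag: str | None = None
    extra: dict = field(default_factory=dict)


def overlap_fraction(source: frozenset | set, target: frozenset | set) -> float:
    """Proportion of the source list contained in the target list."""
    if not source:
        raise ConservationError("overlap fraction undefined for an empty source")
    return len(set(source) & set(target)) / len(source)


def mean_overlap(lists: dict[str, frozenset | set]) -> OverlapStat:
    """Mean of the overlap fraction over all ordered pairs of lists."""
    if len(lists) < 2:
        raise ConservationError("need at least two lists")
    empties = [k for k, v in lists.items() if not v]
    if empties:
        raise ConservationError(f"empty list(s): {empties}")
    fractions = {
        (a, b): overlap_fraction(lists[a], lists[b])
        for a in lists
        for b in lists
        if a != b
    }
    return OverlapStat(
        pair_fractions=fractions,
        mean_fraction=float(np.mean(list(fractions.values()))),
    )


def _mean_overlap_zero_on_empty(sets: list[frozenset]) -> float:
    """Ordered-pair mean where an empty source contributes 0 (null replicates)."""
    total, pairs = 0.0, 0
    for i, a in enumerate(sets):
        for j, b in enumerate(sets):
            if i == j:
                continue
            pairs += 1
            if a:
                total += len(a & b) / len(a)
    return total / pairs if pairs else 0.0


def fisher_baseline(
    list_a: frozenset | set, list_b: frozenset | set, universe_size: int
) -> tuple[float, float]:
    """One-sided (enrichment) Fisher exact test of the pairwise overlap.

    Returns (sample odds ratio, upper-tail p).  The odds ratio is NaN when
    its 0/0 form is undefined.
    """
    a, b = set(list_a), set(list_b)
    if universe_size < len(a | b):
        raise ConservationError("universe smaller than the union of the lists")
    x = len(a & b)
    table = [
        [x, len(a) - x],
        [len(b) - x, universe_size - len(a) - len(b) + x],
    ]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def permutation_p(null_values: np.ndarray, observed: float) -> float:
    r = int(np.sum(np.asarray(null_values) >= observed))
    return (r + 1) / (len(null_values) + 1)


def analytic_null_mean(sizes: dict[str, int], universe_size: int) -> float:
    """Expected mean-overlap under independent uniform draws.

    Each source element lands in the target with probability
    |target| / N, so the expectation is the ordered-pair average of
    |target| / N — it does not depend on source sizes.
    """
    labels = list(sizes)
    vals = [
        sizes[b] / universe_size for a in labels for b in labels if a != b
    ]
    return float(np.mean(vals))


def gene_perm_test(
    lists: TriadLists,
    direction: str,
    B: int = 1000,
    seed: int = 0,
    joint_disjoint: bool = False,
) -> PermutationResult:
    """Permutation test of the three-genus mean-overlap at the gene level.

    Each replicate redraws, per genus, a uniform random subset of the
    linked universe with that genus's list size (without replacement,
    independent across genera).  With ``joint_disjoint`` the up and down
    lists of a genus are drawn jointly without replacement, preserving
    their within-genus disjointness.
    """
    if B < 1:
        raise ConservationError("B must be >= 1")
    directional = lists.direction(direction)
    observed = mean_overlap(directional).mean_fraction
    other = lists.direction("down" if direction == "up" else "up")
    anchors = np.array(sorted(lists.universe.anchors))
    n_univ = len(anchors)
    sizes = {g: len(directional[g]) for g in GENERA}
    other_sizes = {g: len(other[g]) for g in GENERA}
    for g, m in sizes.items():
        if m > n_univ:
            raise ConservationError(f"{g}: list larger than the universe")

    rng = np.random.default_rng(seed)
    null_values = np.empty(B)
    for b in range(B):
        drawn = []
        for g in GENERA:
            if joint_disjoint:
                both = rng.choice(n_univ, size=sizes[g] + other_sizes[g], replace=False)
                idx = both[: sizes[g]]
            else:
                idx = rng.choice(n_univ, size=sizes[g], replace=False)
            drawn.append(frozenset(anchors[idx]))
        null_values[b] = _mean_overlap_zero_on_empty(drawn)
    return PermutationResult(
        observed=observed,
        B=B,
        null_values=null_values,
        p_value=permutation_p(null_values, observed),
        seed=seed,
        extra={"direction": direction, "sizes": sizes},
    )


def _standardized_counts(x, g_sizes, m, n_univ):
    frac = g_sizes / n_univ
    var = m * frac * (1 - frac) * (n_univ - m) / (n_univ - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(var > 0, (x - m * frac) / np.sqrt(var), 0.0)


def _enriched_ids(x, z, g_sizes, cat_ids, params) -> frozenset[str]:
    keep = np.ones(len(cat_ids), dtype=bool)
    z_min = params.get("z_min")
    p_max = params.get("p_max")
    if z_min is None and p_max is None:
        raise ConservationError("enrich_params needs z_min and/or p_max")
    if z_min is not None:
        keep &= z >= z_min
    if p_max is not None:
        keep &= stats.norm.sf(z) <= p_max
    keep &= g_sizes >= params.get("min_size", 1)
    keep &= x >= params.get("min_count", 0)
    return frozenset(np.asarray(cat_ids)[keep])


def go_perm_test(
    lists: TriadLists,
    annotation: GeneSetCollection,
    direction: str,
    enrich_params: dict,
    B: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Category-level permutation test with gene-level agreement held fixed.

    The observed statistic is the mean-overlap of the three per-genus
    enriched-category id lists (standardized-count enrichment under
    ``enrich_params``: z_min and/or p_max, min_size, min_count).  Each
    replicate applies one random bijection of the universe's anchors to
    the annotation's memberships — the gene lists are untouched, category
    sizes are preserved, and the same bijection serves all genera since the
    annotation is anchor-based.  If any genus yields an empty enriched list
    at the observed stage the result is flagged and p is NaN; in null
    replicates an empty source list contributes 0 to its pair fractions.
    """
    if B < 1:
        raise ConservationError("B must be >= 1")
    directional = lists.direction(direction)
    anchors = sorted(lists.universe.anchors)
    index = {a: i for i, a in enumerate(anchors)}
    n_univ = len(anchors)

    restricted = annotation.restrict(set(anchors), min_size=1)
    cat_ids = sorted(restricted.categories)
    if not cat_ids:
        raise ConservationError("annotation has no categories on the universe")
    member_idx = np.concatenate(
        [np.fromiter((index[g] for g in restricted.members(c)), dtype=np.int64)
         for c in cat_ids]
    )
    g_sizes = np.array([len(restricted.members(c)) for c in cat_ids])
    offsets = np.concatenate([[0], np.cumsum(g_sizes)[:-1]])

    masks = {}
    for genus in GENERA:
        mask = np.zeros(n_univ, dtype=bool)
        mask[[index[a] for a in directional[genus]]] = True
        masks[genus] = mask
    m_sizes = {g: int(masks[g].sum()) for g in GENERA}

    def enriched_lists(perm: np.ndarray) -> list[frozenset[str]]:
        mapped = perm[member_idx]
        out = []
        for genus in GENERA:
            x = np.add.reduceat(masks[genus][mapped], offsets)
            z = _standardized_counts(x, g_sizes, m_sizes[genus], n_univ)
            out.append(_enriched_ids(x, z, g_sizes, cat_ids, enrich_params))
        return out

    identity = np.arange(n_univ)
    observed_lists = enriched_lists(identity)
    empties = [g for g, s in zip(GENERA, observed_lists) if not s]
    observed = _mean_overlap_zero_on_empty(observed_lists)

    rng = np.random.default_rng(seed)
    null_values = np.empty(B)
    for b in range(B):
        null_values[b] = _mean_overlap_zero_on_empty(
            enriched_lists(rng.permutation(n_univ))
        )
    if empties:
        return PermutationResult(
            observed=observed,
            B=B,
            null_values=null_values,
            p_value=float("nan"),
            seed=seed,
            flag=f"empty enriched list(s) at the observed stage: {empties}",
            extra={"direction": direction, "enriched_sizes": [len(s) for s in observed_lists]},
        )
    return PermutationResult(
        observed=observed,
        B=B,
        null_values=null_values,
        p_value=permutation_p(null_values, observed),
        seed=seed,
        extra={
            "direction": direction,
            "enriched_sizes": [len(s) for s in observed_lists],
            "enriched_ids": {g: sorted(s) for g, s in zip(GENERA, observed_lists)},
        },
    )


@dataclass
class VennCounts:
    """Three-set exclusive region counts per direction, plus triple counts."""

    regions: dict[str, dict[str, int]]
    triple_consistent_up: int
    triple_consistent_down: int


def venn_counts(lists: TriadLists) -> VennCounts:
    """Exclusive Venn region counts for the up and down triads."""
    regions: dict[str, dict[str, int]] = {}
    triples = {}
    for direction in ("up", "down"):
        sets = lists.direction(direction)
        m, r, h = (sets[g] for g in GENERA)
        regions[direction] = {
            "mouse_only": len(m - r - h),
            "rat_only": len(r - m - h),
            "human_only": len(h - m - r),
            "mouse_rat": len((m & r) - h),
            "mouse_human": len((m & h) - r),
            "rat_human": len((r & h) - m),
            "all_three": len(m & r & h),
        }
        triples[direction] = len(m & r & h)
    return VennCounts(
        regions=regions,
        triple_consistent_up=triples["up"],
        triple_consistent_down=triples["down"],
    )
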
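"""Standardized-hypergeometric gene-set enrichment and greedy covering.

For a gene list of size m on a universe of N genes and a category with G
universe members, the observed in-category count X is standardized against
its hypergeometric moments:

    z = (X - m G / N) / sqrt( m (G/N)(1 - G/N)(N - m)/(N - 1) )

with a one-sided upper-tail normal p (the exact hypergeometric tail is
available for small-universe cross-checks).  Enriched-term gates follow the
convention used for the conserved-gene tables: z above a threshold (or a p
ceiling), a minimum category size, and a minimum number of list genes in
the category.  ``set.mean`` = X / G reports what fraction of the category
belongs to the focal list.

Greedy covering orders enriched categories by decreasing numbers of list
genes not contained in a prior category — the "dominant category" summary
that reads a long enrichment table as a short, low-redundancy one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import TriadLists
from .dataio import GENERA, GeneSetCollection
from .orthomap import LinkedUniverse

#: gates used for the triply-conserved gene tables
S2_GATES = {"z_min": 5.0, "min_size": 10, "min_count": 3}
#: gates used for the union ("any genus") dominant-category figures
FIG3_GATES = {"p_max": 1e-5, "min_size": 10, "min_count": 3}

GATE_PRESETS = {"s2_gates": S2_GATES, "fig3_p": FIG3_GATES}


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentRow:
    category_id: str
    name: str
    G: int
    m: int
    X: int
    expected: float
    z: float
    p: float
    set_mean: float


@dataclass
class CoverOrdering:
    """Greedy dominant-category ordering with per-step coverage gains."""

    category_ids: list[str]
    newly_covered: list[int]
    cumulative_covered: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category_id": self.category_ids,
                "newly_covered": self.newly_covered,
                "cumulative_covered": self.cumulative_covered,
            }
        )


def enrich_score(
    gene_list: frozenset | set,
    category: frozenset | set,
    universe_size: int,
    name: str = "",
    category_id: str = "",
    exact: bool = False,
) -> EnrichmentRow:
    """Standardized hypergeometric enrichment of one category.

    With ``exact`` the p-value is the exact hypergeometric upper tail
    P(X >= x) instead of the normal approximation of z.
    """
    g = len(category)
    m = len(gene_list)
    n = universe_size
    if m == 0:
        raise EnrichmentError("empty gene list")
    if g == 0 or g == n:
        raise EnrichmentError(
            f"category size {g} of universe {n}: zero-variance configuration"
        )
    if m > n:
        raise EnrichmentError("gene list larger than the universe")
    x = len(set(gene_list) & set(category))
    expected = m * g / n
    var = m * (g / n) * (1 - g / n) * (n - m) / (n - 1)
    z = (x - expected) / np.sqrt(var) if var > 0 else 0.0
    if exact:
        p = float(stats.hypergeom.sf(x - 1, n, g, m))
    else:
        p = float(stats.norm.sf(z))
    return EnrichmentRow(
        category_id=category_id,
        name=name,
        G=g,
        m=m,
        X=x,
        expected=expected,
        z=float(z),
        p=p,
        set_mean=x / g,
    )


def enrich_all(
    gene_list: frozenset | set,
    collection: GeneSetCollection,
    universe: LinkedUniverse,
    min_size: int = 1,
    max_size: int | None = None,
    exact: bool = False,
) -> pd.DataFrame:
    """Score every category of acceptable size; sort by z descending.

    Categories are intersected with the linked universe before G is
    computed, so N, G, m and X all live on one gene space.  Ties in z are
    broken lexicographically by category id.
    """
    if min_size < 1:
        raise EnrichmentError("min_size must be >= 1")
    restricted = collection.restrict(set(universe.anchors), min_size=1)
    gene_list = set(gene_list) & set(universe.anchors)
    if not gene_list:
        raise EnrichmentError("gene list has no members in the universe")
    rows = []
    for cid in sorted(restricted.categories):
        members = restricted.members(cid)
        g = len(members)
        if g < min_size or (max_size is not None and g > max_size) or g == universe.N:
            continue
        rows.append(
            enrich_score(
                gene_list,
                members,
                universe.N,
                name=restricted.name(cid),
                category_id=cid,
                exact=exact,
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return pd.DataFrame(
            columns=["category_id", "name", "G", "m", "X", "expected", "z", "p", "set_mean"]
        )
    return df.sort_values(
        ["z", "category_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def enriched_terms(
    rows: pd.DataFrame,
    z_min: float | None = None,
    p_max: float | None = None,
    min_size: int = 10,
    min_count: int = 3,
) -> list[str]:
    """Apply the enrichment gates; returns category ids in table order."""
    if z_min is None and p_max is None:
        raise EnrichmentError("configure at least one of z_min / p_max")
    if rows.empty:
        return []
    keep = pd.Series(True, index=rows.index)
    if z_min is not None:
        keep &= rows["z"] >= z_min
    if p_max is not None:
        keep &= rows["p"] <= p_max
    keep &= rows["G"] >= min_size
    keep &= rows["X"] >= min_count
    return rows.loc[keep, "category_id"].tolist()


def greedy_cover(
    gene_list: frozenset | set, selected: dict[str, frozenset | set]
) -> CoverOrdering:
    """Order categories by decreasing numbers of list genes not yet covered.

    Iteratively picks the category maximizing |list ∩ category \\ covered|;
    stops when the best increment is zero.  Ties break by larger total
    |list ∩ category|, then lexicographically smaller id.
    """
    if not selected:
        raise EnrichmentError("no categories selected")
    gene_list = set(gene_list)
    if not gene_list:
        return CoverOrdering([], [], [])
    in_list = {cid: set(members) & gene_list for cid, members in selected.items()}
    covered: set = set()
    remaining = dict(in_list)
    ordering: list[str] = []
    gains: list[int] = []
    cumulative: list[int] = []
    while remaining:
        # scan ids in lexicographic order so ties resolve to the smaller id
        best, best_key = None, (-1, -1)
        for cid in sorted(remaining):
            key = (len(remaining[cid] - covered), len(remaining[cid]))
            if key > best_key:
                best, best_key = cid, key
        gain = best_key[0]
        if gain == 0:
            break
        covered |= remaining.pop(best)
        ordering.append(best)
        gains.append(gain)
        cumulative.append(len(covered))
    return CoverOrdering(ordering, gains, cumulative)


def union_enrichment(
    lists: TriadLists,
    direction: str,
    collection: GeneSetCollection,
    universe: LinkedUniverse,
    gates: dict | str = "fig3_p",
) -> tuple[pd.DataFrame, CoverOrdering, pd.DataFrame]:
    """Enrichment + dominant-category cover of the any-genus union list.

    Runs the enrichment table, the gates, and the greedy cover on the union
    across genera of the directional lists.  Also returns a gene x genus
    membership flag table (the coloring of the dominant-category figures:
    which genus each union gene came from).
    """
    if isinstance(gates, str):
        gates = GATE_PRESETS[gates]
    directional = lists.direction(direction)
    union = frozenset().union(*directional.values())
    if not union:
        raise EnrichmentError(f"empty {direction} union across genera")
    rows = enrich_all(
        union, collection, universe, min_size=1
    )
    term_ids = enriched_terms(rows, **gates)
    restricted = collection.restrict(set(universe.anchors))
    selected = {cid: restricted.members(cid) for cid in term_ids if cid in restricted}
    cover = (
        greedy_cover(union, selected) if selected else CoverOrdering([], [], [])
    )
    genes = sorted(union)
    membership = pd.DataFrame(
        {genus: [g in directional[genus] for g in genes] for genus in GENERA},
        index=pd.Index(genes, name="anchor"),
    )
    return rows, cover, membership
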
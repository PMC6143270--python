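"""Three-genus linked universe and gene-list projection.

All cross-genus comparisons run on the linked universe: the ortholog
triples whose mouse, rat and human members were all measured in the
respective studies.  Genus gene lists are projected onto mouse-anchored ids
before any overlap or enrichment statistic is computed, so every count sits
on one common gene space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .dataio import GENERA, OrthologyMap

logger = logging.getLogger(__name__)


class OrthoMapError(ValueError):
    pass


@dataclass
class LinkedUniverse:
    """Anchors measured in all three genera plus per-genus translations."""

    anchors: frozenset[str]
    to_anchor: dict[str, dict[str, str]]  # genus -> genus id -> anchor
    from_anchor: dict[str, dict[str, str]]  # genus -> anchor -> genus id

    @property
    def N(self) -> int:
        return len(self.anchors)

    def genus_id(self, genus: str, anchor: str) -> str:
        return self.from_anchor[genus][anchor]

    def to_frame(self) -> pd.DataFrame:
        anchors = sorted(self.anchors)
        return pd.DataFrame(
            {
                "mouse_id": anchors,
                "rat_id": [self.from_anchor["rat"][a] for a in anchors],
                "human_id": [self.from_anchor["human"][a] for a in anchors],
            }
        )


def link_universe(
    omap: OrthologyMap, measured: dict[str, set[str]]
) -> LinkedUniverse:
    """Restrict ortholog triples to those measured in all three genera."""
    missing = [g for g in GENERA if not measured.get(g)]
    if missing:
        raise OrthoMapError(f"measured sets empty or missing for: {missing}")
    keep = omap.triples
    for genus in GENERA:
        keep = keep[keep[f"{genus}_id"].isin(measured[genus])]
    if keep.empty:
        raise OrthoMapError("no ortholog triple is measured in all three genera")
    dropped = len(omap.triples) - len(keep)
    if dropped:
        logger.info("link_universe: dropped %d unmeasured triples", dropped)
    to_anchor = {
        genus: dict(zip(keep[f"{genus}_id"], keep["mouse_id"])) for genus in GENERA
    }
    from_anchor = {
        genus: dict(zip(keep["mouse_id"], keep[f"{genus}_id"])) for genus in GENERA
    }
    return LinkedUniverse(
        anchors=frozenset(keep["mouse_id"]),
        to_anchor=to_anchor,
        from_anchor=from_anchor,
    )


def project_list(
    universe: LinkedUniverse, genus: str, genes: set[str]
) -> frozenset[str]:
    """Translate a genus gene list to the anchors present in the universe.

    Genes without a linked ortholog are dropped; the count is logged.
    Projection is idempotent when fed anchor ids for the mouse.
    """
    if genus not in universe.to_anchor:
        raise OrthoMapError(f"unknown genus {genus!r}")
    table = universe.to_anchor[genus]
    projected = frozenset(table[g] for g in genes if g in table)
    unmapped = len(genes) - len([g for g in genes if g in table])
    if unmapped:
        logger.info(
            "project_list(%s): %d of %d genes not in the linked universe",
            genus,
            unmapped,
            len(genes),
        )
    return projected
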
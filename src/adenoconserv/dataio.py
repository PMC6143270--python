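"""Domain types and plain-text readers/writers.

Expression studies are genes x samples matrices of log2 intensities with a
sample-metadata sidecar; gene sets travel as GMT; orthology as a three-column
TSV (mouse_id, rat_id, human_id) anchored on the mouse identifier; gene lists
as one-id-per-line text.  All identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TISSUES = ("tumor", "normal")
COLON_STATUSES = ("tumor_bearing", "tumor_free", "unknown")

GENERA = ("mouse", "rat", "human")
ORTHOLOGY_COLUMNS = ("mouse_id", "rat_id", "human_id")


class DataIOError(ValueError):
    """Raised for malformed input files or invalid domain objects."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one array sample: which animal, which tissue.

    ``colon_status`` distinguishes normal epithelium from tumor-bearing vs
    tumor-free colons (used by the empirical-Bayes two-group comparison);
    ``unknown`` is the default for studies where it was not recorded.
    """

    sample_id: str
    animal_id: str
    tissue: str
    colon_status: str = "unknown"

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise DataIOError(
                f"sample {self.sample_id!r}: tissue must be one of {TISSUES}, "
                f"got {self.tissue!r}"
            )
        if self.colon_status not in COLON_STATUSES:
            raise DataIOError(
                f"sample {self.sample_id!r}: colon_status must be one of "
                f"{COLON_STATUSES}, got {self.colon_status!r}"
            )


@dataclass
class ExpressionStudy:
    """One genus's log2 expression matrix (genes x samples) plus metadata.

    ``values[i, j]`` is the log2 intensity of ``gene_ids[i]`` in
    ``samples[j]``; sample order matches the matrix columns.
    """

    genus: str
    gene_ids: list[str]
    values: np.ndarray
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataIOError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise DataIOError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataIOError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.samples[bad[1]].sample_id!r}"
            )
        dupes = _duplicates(self.gene_ids)
        if dupes:
            raise DataIOError(f"duplicate gene ids: {sorted(dupes)[:5]}")
        dupes = _duplicates([s.sample_id for s in self.samples])
        if dupes:
            raise DataIOError(f"duplicate sample ids: {sorted(dupes)[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_genes(self, keep: np.ndarray) -> "ExpressionStudy":
        """Return a copy restricted to a boolean or index array of genes."""
        idx = np.asarray(keep)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionStudy(
            genus=self.genus,
            gene_ids=[self.gene_ids[i] for i in idx],
            values=self.values[idx],
            samples=list(self.samples),
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionStudy":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise DataIOError(f"unknown sample ids: {missing}")
        cols = [pos[s] for s in sample_ids]
        return ExpressionStudy(
            genus=self.genus,
            gene_ids=list(self.gene_ids),
            values=self.values[:, cols],
            samples=[self.samples[j] for j in cols],
        )


@dataclass
class GeneSetCollection:
    """Mapping category_id -> (name, member set) over anchor gene ids."""

    categories: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, (name, members) in self.categories.items():
            if not members:
                raise DataIOError(f"category {cid!r} is empty")
            self.categories[cid] = (name, frozenset(members))

    def __len__(self) -> int:
        return len(self.categories)

    def __contains__(self, cid: str) -> bool:
        return cid in self.categories

    def members(self, cid: str) -> frozenset[str]:
        return self.categories[cid][1]

    def name(self, cid: str) -> str:
        return self.categories[cid][0]

    def restrict(self, universe: set[str], min_size: int = 1) -> "GeneSetCollection":
        """Intersect every category with ``universe``; drop those below min_size."""
        kept = {}
        for cid, (name, members) in self.categories.items():
            inter = members & universe
            if len(inter) >= min_size:
                kept[cid] = (name, frozenset(inter))
        dropped = len(self.categories) - len(kept)
        if dropped:
            logger.info("restrict: dropped %d categories below size %d", dropped, min_size)
        return GeneSetCollection(kept)


@dataclass
class OrthologyMap:
    """1:1:1 ortholog triples (mouse_id, rat_id, human_id), mouse-anchored."""

    triples: pd.DataFrame

    def __post_init__(self) -> None:
        if tuple(self.triples.columns) != ORTHOLOGY_COLUMNS:
            raise DataIOError(
                f"orthology columns must be {ORTHOLOGY_COLUMNS}, "
                f"got {tuple(self.triples.columns)}"
            )
        anchors = self.triples["mouse_id"]
        if anchors.duplicated().any():
            dupes = anchors[anchors.duplicated()].tolist()[:5]
            raise DataIOError(f"duplicated anchors after collapse: {dupes}")
        if self.triples.isna().any().any() or (self.triples == "").any().any():
            raise DataIOError("retained orthology triples must have no empty fields")
        self.triples = self.triples.reset_index(drop=True)

    @property
    def anchors(self) -> list[str]:
        return self.triples["mouse_id"].tolist()

    def __len__(self) -> int:
        return len(self.triples)

    def genus_ids(self, genus: str) -> list[str]:
        return self.triples[f"{genus}_id"].tolist()


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(matrix_path, meta_path, genus: str = "unknown") -> ExpressionStudy:
    """Read a genes x samples log2 TSV plus its sample-metadata sidecar.

    The matrix's first column holds gene ids; the header holds sample ids.
    Every matrix sample must appear in the metadata; sample order follows
    the matrix header.
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    dupes = _duplicates(df.index.tolist())
    if dupes:
        raise DataIOError(f"{matrix_path}: duplicate gene id(s) {sorted(dupes)[:5]}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.argmax()]
            raise DataIOError(
                f"{matrix_path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        if numeric.isna().any():
            gene = df.index[numeric.isna().argmax()]
            raise DataIOError(
                f"{matrix_path}: missing value at gene {gene!r}, sample {col!r}"
            )
        values[:, j] = numeric.to_numpy()

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "animal_id", "tissue"}
    if not required.issubset(meta.columns):
        raise DataIOError(
            f"{meta_path}: metadata needs columns {sorted(required)}"
        )
    if "colon_status" not in meta.columns:
        meta["colon_status"] = "unknown"
    by_id = {row.sample_id: row for row in meta.itertuples()}
    samples = []
    for sid in df.columns:
        if sid not in by_id:
            raise DataIOError(f"{meta_path}: sample {sid!r} missing from metadata")
        row = by_id[sid]
        samples.append(
            SampleMeta(
                sample_id=sid,
                animal_id=row.animal_id,
                tissue=row.tissue,
                colon_status=row.colon_status,
            )
        )
    return ExpressionStudy(
        genus=genus, gene_ids=df.index.tolist(), values=values, samples=samples
    )


def write_expression(study: ExpressionStudy, matrix_path, meta_path) -> None:
    study.to_frame().to_csv(matrix_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in study.samples],
            "animal_id": [s.animal_id for s in study.samples],
            "tissue": [s.tissue for s in study.samples],
            "colon_status": [s.colon_status for s in study.samples],
        }
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> GeneSetCollection:
    """Parse a standard GMT file: id TAB name TAB member TAB member ..."""
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIOError(
                    f"{path}: line {lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            cid, name = fields[0], fields[1]
            if cid in categories:
                raise DataIOError(f"{path}: line {lineno}: duplicate category {cid!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise DataIOError(f"{path}: line {lineno}: category {cid!r} empty")
            categories[cid] = (name, members)
    return GeneSetCollection(categories)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for cid, (name, members) in collection.categories.items():
            fh.write("\t".join([cid, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# orthology


def read_orthology(path, collapse: str = "drop_all") -> OrthologyMap:
    """Read mouse/rat/human ortholog triples; resolve duplicated anchors.

    Rows with any empty field are dropped (count logged).  ``collapse``
    governs anchors appearing more than once: ``error`` fails naming the
    anchor, ``first`` keeps the first occurrence, ``drop_all`` (default)
    removes every ambiguous anchor — ambiguous many-to-many links cannot
    support a one-to-one cross-genus comparison.
    """
    if collapse not in ("error", "first", "drop_all"):
        raise DataIOError(f"unknown collapse policy {collapse!r}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ORTHOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise DataIOError(f"{path}: missing orthology columns {missing}")
    df = df[list(ORTHOLOGY_COLUMNS)]
    incomplete = df.isna().any(axis=1) | (df == "").any(axis=1)
    if incomplete.any():
        logger.info(
            "read_orthology: dropped %d incomplete triples", int(incomplete.sum())
        )
        df = df[~incomplete]
    dup_mask = df["mouse_id"].duplicated(keep=False)
    if dup_mask.any():
        dup_anchors = sorted(df.loc[dup_mask, "mouse_id"].unique())
        if collapse == "error":
            raise DataIOError(f"{path}: duplicated anchor(s) {dup_anchors[:5]}")
        if collapse == "first":
            df = df.drop_duplicates(subset="mouse_id", keep="first")
        else:  # drop_all
            df = df[~dup_mask]
        logger.info(
            "read_orthology: collapse=%s over %d duplicated anchors",
            collapse,
            len(dup_anchors),
        )
    return OrthologyMap(df.reset_index(drop=True))


def write_orthology(omap: OrthologyMap, path) -> None:
    omap.triples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plain gene lists


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
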
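"""Synthetic three-genus adenoma/normal expression studies with known truth.

The generator emulates the structure of the real design: paired tumor and
normal colonic-epithelium samples from 4 mice, 5 rats and 32 humans, a
mouse-anchored 1:1:1 ortholog universe, planted differential-expression (DE)
effects that are conserved across genera either gene-by-gene
(``gene_level``) or only through shared functional categories
(``category_level``), genus-private DE, a per-animal random offset shared by
the tumor/normal pair (what makes the paired design informative), and
Gaussian log2 noise.  Humans may receive a larger animal offset to mimic
their genetic heterogeneity.

Ground truth (which genes are DE where, which categories were planted) is
returned alongside the data so every downstream stage can be tested for
recovery without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    GENERA,
    ExpressionStudy,
    GeneSetCollection,
    OrthologyMap,
    SampleMeta,
    write_expression,
    write_gmt,
    write_orthology,
)
from .phenostats import CountTable, SurvivalData

# fixed stage tags so adding a stage never perturbs another stage's stream
_STAGE_ANNOTATION = 2
_STAGE_TRUTH = 3
_STAGE_STUDY = {"mouse": 10, "rat": 11, "human": 12}


class SynthConfigError(ValueError):
    pass


@dataclass
class SynthConfig:
    """Parameters of the synthetic three-genus study.

    Defaults mirror the real design: a ~19k-gene linked universe, 4/5/32
    animals, 75 conserved-up and 14 conserved-down genes, a strong
    (|log2| = 1.5) tumor-vs-normal shift on DE genes, and moderate
    animal-to-animal and residual variation on the log2 scale.
    """

    n_genes: int = 19169
    animals_per_genus: dict[str, int] = field(
        default_factory=lambda: {"mouse": 4, "rat": 5, "human": 32}
    )
    n_conserved_up: int = 75
    n_conserved_down: int = 14
    n_private_up: int = 300
    n_private_down: int = 300
    effect_log2: float = 1.5
    noise_sd: float = 0.25
    animal_sd: float = 0.3
    human_animal_sd: float | None = 0.6
    conservation_mode: str = "gene_level"
    n_categories: int = 100
    n_planted_categories: int = 10
    category_size_range: tuple[int, int] = (10, 30)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SynthConfigError("n_genes must be >= 1")
        if set(self.animals_per_genus) != set(GENERA):
            raise SynthConfigError(f"animals_per_genus must cover {GENERA}")
        if any(n < 2 for n in self.animals_per_genus.values()):
            raise SynthConfigError("need >= 2 animals per genus for paired tests")
        if self.conservation_mode not in ("gene_level", "category_level"):
            raise SynthConfigError(
                f"unknown conservation_mode {self.conservation_mode!r}"
            )
        if self.effect_log2 <= 0:
            raise SynthConfigError("effect_log2 must be positive")
        if self.noise_sd <= 0 or self.animal_sd < 0:
            raise SynthConfigError("noise_sd must be > 0 and animal_sd >= 0")
        lo, hi = self.category_size_range
        if not (1 <= lo <= hi):
            raise SynthConfigError("invalid category_size_range")

    # annotation- and study-specific feasibility is checked where those
    # pieces are generated, so e.g. a tiny universe without categories is
    # fine for universe-only use
    def validate_annotation(self) -> None:
        self.validate()
        if self.category_size_range[1] > self.n_genes:
            raise SynthConfigError("category sizes exceed the gene universe")
        if (
            self.conservation_mode == "category_level"
            and self.n_planted_categories > self.n_categories
        ):
            raise SynthConfigError("n_planted_categories exceeds n_categories")

    def validate_studies(self) -> None:
        self.validate()
        planted = (
            self.n_conserved_up
            + self.n_conserved_down
            + 3 * (self.n_private_up + self.n_private_down)
        )
        if self.conservation_mode == "gene_level" and planted > self.n_genes:
            raise SynthConfigError(
                f"planted DE counts ({planted}) exceed n_genes ({self.n_genes})"
            )


@dataclass
class SynthTruth:
    """Ground truth: per-genus DE anchor sets and planted categories."""

    up: dict[str, frozenset[str]]
    down: dict[str, frozenset[str]]
    planted_categories: frozenset[str]
    de_proportion: float

    def to_json(self, path) -> None:
        payload = {
            "up": {g: sorted(s) for g, s in self.up.items()},
            "down": {g: sorted(s) for g, s in self.down.items()},
            "planted_categories": sorted(self.planted_categories),
            "de_proportion": self.de_proportion,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SynthTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            up={g: frozenset(s) for g, s in payload["up"].items()},
            down={g: frozenset(s) for g, s in payload["down"].items()},
            planted_categories=frozenset(payload["planted_categories"]),
            de_proportion=payload["de_proportion"],
        )


def scaled_config(
    n_genes: int, conservation_mode: str = "gene_level", seed: int = 0, **overrides
) -> SynthConfig:
    """A SynthConfig with planted counts scaled proportionally to ``n_genes``.

    The full-size defaults mirror the real ~19k-gene universe; this keeps
    the planted-DE density roughly constant when simulating smaller
    universes for quick runs.
    """
    base = SynthConfig()
    f = n_genes / base.n_genes
    cfg = SynthConfig(
        n_genes=n_genes,
        n_conserved_up=max(2, round(base.n_conserved_up * f)),
        n_conserved_down=max(2, round(base.n_conserved_down * f)),
        n_private_up=max(2, round(base.n_private_up * f)),
        n_private_down=max(2, round(base.n_private_down * f)),
        n_categories=max(5, round(base.n_categories * min(1.0, 4 * f))),
        n_planted_categories=max(
            2, round(base.n_planted_categories * min(1.0, 4 * f))
        ),
        category_size_range=(
            max(3, round(base.category_size_range[0] * min(1.0, 10 * f))),
            max(6, round(base.category_size_range[1] * min(1.0, 10 * f))),
        ),
        conservation_mode=conservation_mode,
        seed=seed,
    )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def _rng(config: SynthConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, *tags]))


def generate_universe(config: SynthConfig) -> OrthologyMap:
    """Deterministic 1:1:1 synthetic ortholog table (m0001/r0001/h0001...)."""
    config.validate()
    width = max(5, len(str(config.n_genes)))
    idx = np.arange(1, config.n_genes + 1)
    return OrthologyMap(
        pd.DataFrame(
            {
                "mouse_id": [f"m{i:0{width}d}" for i in idx],
                "rat_id": [f"r{i:0{width}d}" for i in idx],
                "human_id": [f"h{i:0{width}d}" for i in idx],
            }
        )
    )


def generate_annotation(config: SynthConfig, omap: OrthologyMap) -> GeneSetCollection:
    """Random categories over the anchor universe.

    Sizes are uniform over ``category_size_range``.  The first
    ``n_planted_categories`` (ids ``C0001``...) are the plantable ones; in
    ``category_level`` mode their members are drawn mutually disjoint so that
    later DE assignment within one category never conflicts with another.
    """
    config.validate_annotation()
    rng = _rng(config, _STAGE_ANNOTATION)
    anchors = np.array(omap.anchors)
    lo, hi = config.category_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_categories)
    width = max(4, len(str(config.n_categories)))
    ids = [f"C{i:0{width}d}" for i in range(1, config.n_categories + 1)]

    categories: dict[str, tuple[str, frozenset[str]]] = {}
    n_planted = (
        config.n_planted_categories
        if config.conservation_mode == "category_level"
        else 0
    )
    if n_planted:
        need = int(sizes[:n_planted].sum())
        if need > len(anchors):
            raise SynthConfigError("planted categories exceed the gene universe")
        pool = rng.choice(anchors, size=need, replace=False)
        offset = 0
        for i in range(n_planted):
            members = pool[offset : offset + sizes[i]]
            offset += sizes[i]
            categories[ids[i]] = (f"planted category {ids[i]}", frozenset(members))
    for i in range(n_planted, config.n_categories):
        members = rng.choice(anchors, size=sizes[i], replace=False)
        categories[ids[i]] = (f"synthetic category {ids[i]}", frozenset(members))
    return GeneSetCollection(categories)


def _assign_de(
    config: SynthConfig,
    omap: OrthologyMap,
    annotation: GeneSetCollection | None,
) -> SynthTruth:
    rng = _rng(config, _STAGE_TRUTH)
    anchors = np.array(omap.anchors)
    up: dict[str, set[str]] = {g: set() for g in GENERA}
    down: dict[str, set[str]] = {g: set() for g in GENERA}

    if config.conservation_mode == "gene_level":
        pool = list(rng.permutation(anchors))
        conserved_up = set(pool[: config.n_conserved_up])
        del pool[: config.n_conserved_up]
        conserved_down = set(pool[: config.n_conserved_down])
        del pool[: config.n_conserved_down]
        for g in GENERA:
            up[g] |= conserved_up
            down[g] |= conserved_down
        planted_categories: frozenset[str] = frozenset()
    else:
        if annotation is None:
            raise SynthConfigError("category_level mode needs an annotation")
        planted_ids = sorted(annotation.categories)[: config.n_planted_categories]
        planted_members: set[str] = set()
        for cid in planted_ids:
            members = list(rng.permutation(sorted(annotation.members(cid))))
            # round-robin split: different member genes are DE in different genera
            for k, gene in enumerate(members):
                up[GENERA[k % 3]].add(gene)
            planted_members |= set(members)
        pool = [a for a in rng.permutation(anchors) if a not in planted_members]
        planted_categories = frozenset(planted_ids)

    # genus-private DE, mutually disjoint across genera and directions
    need = 3 * (config.n_private_up + config.n_private_down)
    if need > len(pool):
        raise SynthConfigError("not enough genes left for genus-private DE")
    for g in GENERA:
        up[g] |= set(pool[: config.n_private_up])
        del pool[: config.n_private_up]
        down[g] |= set(pool[: config.n_private_down])
        del pool[: config.n_private_down]

    all_de = set().union(*up.values(), *down.values())
    return SynthTruth(
        up={g: frozenset(s) for g, s in up.items()},
        down={g: frozenset(s) for g, s in down.items()},
        planted_categories=planted_categories,
        de_proportion=len(all_de) / config.n_genes,
    )


def generate_studies(
    config: SynthConfig,
    omap: OrthologyMap,
    annotation: GeneSetCollection | None = None,
) -> tuple[dict[str, ExpressionStudy], SynthTruth]:
    """Paired tumor/normal studies for all three genera plus ground truth.

    value = gene baseline + animal offset + tissue effect (+/- effect_log2
    on the genus's DE genes, tumor samples only) + N(0, noise_sd) noise.
    Per-genus RNG streams are derived independently from the seed, so adding
    a genus never perturbs the others.
    """
    config.validate_studies()
    truth = _assign_de(config, omap, annotation)
    anchor_arr = np.array(omap.anchors)
    studies: dict[str, ExpressionStudy] = {}
    for genus in GENERA:
        rng = _rng(config, _STAGE_STUDY[genus])
        n_animals = config.animals_per_genus[genus]
        n_genes = config.n_genes
        gene_ids = omap.genus_ids(genus)

        effect = np.zeros(n_genes)
        up_mask = np.isin(anchor_arr, sorted(truth.up[genus]))
        down_mask = np.isin(anchor_arr, sorted(truth.down[genus]))
        effect[up_mask] = config.effect_log2
        effect[down_mask] = -config.effect_log2

        animal_sd = config.animal_sd
        if genus == "human" and config.human_animal_sd is not None:
            animal_sd = config.human_animal_sd

        baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n_genes)
        offsets = rng.normal(0.0, animal_sd, size=n_animals) if animal_sd > 0 else np.zeros(n_animals)

        values = np.empty((n_genes, 2 * n_animals))
        samples: list[SampleMeta] = []
        for a in range(n_animals):
            animal = f"{genus}_{a + 1:03d}"
            base = baseline + offsets[a]
            values[:, 2 * a] = base + rng.normal(0, config.noise_sd, n_genes)
            values[:, 2 * a + 1] = (
                base + effect + rng.normal(0, config.noise_sd, n_genes)
            )
            samples.append(
                SampleMeta(f"{animal}_N", animal, "normal", "tumor_bearing")
            )
            samples.append(
                SampleMeta(f"{animal}_T", animal, "tumor", "tumor_bearing")
            )
        studies[genus] = ExpressionStudy(
            genus=genus, gene_ids=gene_ids, values=values, samples=samples
        )
    return studies, truth


def generate_nce_study(
    omap: OrthologyMap,
    n_per_group: int = 6,
    n_de: int = 50,
    effect_log2: float = 1.5,
    noise_sd: float = 0.4,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[ExpressionStudy, frozenset[str], frozenset[str]]:
    """Normal-epithelium-only mouse study: tumor-bearing vs tumor-free colons.

    Emulates the two-group design behind the empirical-Bayes comparison:
    one normal sample per animal, the first group from tumor-bearing colons
    with ``n_de`` genes shifted (half up, half down).  Returns the study and
    the true up/down anchor sets.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20]))
    anchors = np.array(omap.anchors)
    gene_ids = omap.genus_ids("mouse")
    n_genes = len(anchors)
    de = rng.choice(n_genes, size=n_de, replace=False)
    up_idx, down_idx = de[: n_de // 2], de[n_de // 2 :]
    effect = np.zeros(n_genes)
    effect[up_idx] = effect_log2
    effect[down_idx] = -effect_log2

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    values = np.empty((n_genes, 2 * n_per_group))
    samples: list[SampleMeta] = []
    for a in range(n_per_group):
        values[:, a] = baseline + effect + rng.normal(0, noise_sd, n_genes)
        samples.append(
            SampleMeta(f"nce_tb_{a + 1:02d}", f"tb_{a + 1:02d}", "normal", "tumor_bearing")
        )
    for a in range(n_per_group):
        values[:, n_per_group + a] = baseline + rng.normal(0, noise_sd, n_genes)
        samples.append(
            SampleMeta(f"nce_tf_{a + 1:02d}", f"tf_{a + 1:02d}", "normal", "tumor_free")
        )
    study = ExpressionStudy(
        genus="mouse", gene_ids=gene_ids, values=values, samples=samples
    )
    return (
        study,
        frozenset(anchors[up_idx]),
        frozenset(anchors[down_idx]),
    )


def generate_lnnmv_dataset(
    n_genes: int,
    n_a: int,
    n_b: int,
    p_de: float,
    mu0: float = 7.0,
    tau0_sq: float = 1.0,
    sigma_shape: float = 3.0,
    sigma_scale: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-group matrices drawn exactly from the log-normal/normal mixture.

    Per gene: variance sigma^2 ~ InvGamma(sigma_shape, sigma_scale); with
    probability ``p_de`` the two groups get independent latent means from
    N(mu0, tau0_sq), otherwise one shared latent mean.  Returns
    (group_a, group_b, is_de).
    """
    rng = np.random.default_rng(seed)
    sigma_sq = sigma_scale / rng.gamma(sigma_shape, 1.0, size=n_genes)
    is_de = rng.random(n_genes) < p_de
    mu_a = rng.normal(mu0, np.sqrt(tau0_sq), size=n_genes)
    mu_b = np.where(is_de, rng.normal(mu0, np.sqrt(tau0_sq), size=n_genes), mu_a)
    sd = np.sqrt(sigma_sq)[:, None]
    a = mu_a[:, None] + rng.normal(0, 1, size=(n_genes, n_a)) * sd
    b = mu_b[:, None] + rng.normal(0, 1, size=(n_genes, n_b)) * sd
    return a, b, is_de


def generate_counts(
    group_specs: dict[str, tuple[int, float, float]], seed: int = 0
) -> CountTable:
    """Negative-binomial tumor multiplicities per group.

    ``group_specs`` maps label -> (n animals, mean, dispersion k); variance
    is mean + mean^2 / k, matching the overdispersed, non-normal counts seen
    in tumor-multiplicity data.  mean = 0 yields all-zero counts.
    """
    rng = np.random.default_rng(seed)
    groups = {}
    for label, (n, mean, k) in group_specs.items():
        if mean < 0 or k <= 0 or n < 1:
            raise SynthConfigError(f"group {label!r}: need n>=1, mean>=0, k>0")
        if mean == 0:
            counts = np.zeros(n, dtype=int)
        else:
            counts = rng.negative_binomial(k, k / (k + mean), size=n)
        groups[label] = counts
    return CountTable(groups)


def generate_survival(
    group_specs: dict[str, tuple[int, float]],
    horizon_days: int = 100,
    seed: int = 0,
) -> SurvivalData:
    """Exponential times-to-morbidity, censored at the study horizon.

    hazard = 0 means no morbidity: everything is censored at the horizon,
    like animals sacrificed at the end of the study.
    """
    if horizon_days <= 0:
        raise SynthConfigError("horizon_days must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for label, (n, hazard) in group_specs.items():
        if hazard < 0 or n < 1:
            raise SynthConfigError(f"group {label!r}: need n>=1, hazard>=0")
        if hazard == 0:
            times = np.full(n, float(horizon_days))
        else:
            times = np.minimum(rng.exponential(1.0 / hazard, size=n), horizon_days)
        for t in times:
            rows.append((label, float(t) if t < horizon_days else float(horizon_days),
                         bool(t < horizon_days)))
    return SurvivalData(
        pd.DataFrame(rows, columns=["group", "time", "event"])
    )


def write_dataset(config: SynthConfig, outdir, overwrite: bool = False) -> dict[str, Path]:
    """Generate and write a full dataset in the plain-text exchange formats.

    Produces one expression + metadata TSV pair per genus, the orthology
    TSV, the GMT annotation, a normal-epithelium two-group study, and a
    JSON ground-truth file.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"{outdir} exists and is not empty (use overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)

    omap = generate_universe(config)
    annotation = generate_annotation(config, omap)
    studies, truth = generate_studies(config, omap, annotation)
    nce, nce_up, nce_down = generate_nce_study(omap, seed=config.seed)

    paths: dict[str, Path] = {}
    for genus, study in studies.items():
        m = outdir / f"expression_{genus}.tsv"
        s = outdir / f"meta_{genus}.tsv"
        write_expression(study, m, s)
        paths[f"expression_{genus}"] = m
        paths[f"meta_{genus}"] = s
    write_expression(nce, outdir / "expression_nce.tsv", outdir / "meta_nce.tsv")
    paths["expression_nce"] = outdir / "expression_nce.tsv"
    paths["meta_nce"] = outdir / "meta_nce.tsv"
    write_orthology(omap, outdir / "orthology.tsv")
    paths["orthology"] = outdir / "orthology.tsv"
    write_gmt(annotation, outdir / "annotation.gmt")
    paths["annotation"] = outdir / "annotation.gmt"
    truth.to_json(outdir / "truth.json")
    paths["truth"] = outdir / "truth.json"
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=1))
    paths["config"] = outdir / "config.json"
    return paths
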
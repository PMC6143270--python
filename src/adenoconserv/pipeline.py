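"""End-to-end orchestration: load -> DE -> link -> conserve -> enrich -> report.

A run consumes the plain-text dataset formats (three expression studies, an
orthology table, a GMT annotation, optionally a normal-epithelium two-group
study), executes every analysis stage with deterministic sub-seeds, and
writes TSV/JSON outputs plus a manifest recording the configuration, all
gate values, per-stage seeds and a checksum for every file produced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .conservation import (
    TriadLists,
    gene_perm_test,
    go_perm_test,
    venn_counts,
)
from .dataio import (
    GENERA,
    ExpressionStudy,
    read_expression,
    read_gmt,
    read_orthology,
    write_gene_list,
)
from .diffexpr import (
    call_directional,
    filter_low_expression,
    lnnmv_call,
    lnnmv_fit,
    paired_de,
)
from .enrichment import GATE_PRESETS, union_enrichment
from .orthomap import link_universe, project_list
from .phenostats import center_by_gene

logger = logging.getLogger(__name__)

_STAGE_SEED_TAGS = {
    "gene_perm_up": 101,
    "gene_perm_down": 102,
    "go_perm_up": 103,
    "go_perm_down": 104,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and tunables of one analysis run."""

    studies: dict[str, dict[str, str]]  # genus -> {matrix, meta}
    orthology: str
    annotation: str
    nce_matrix: str | None = None
    nce_meta: str | None = None
    fold_factor: float = 2.0
    de_fdr: float = 0.05
    lnnmv_fdr: float = 0.20
    gates: str = "s2_gates"  # or "fig3_p"
    min_size: int = 10
    min_count: int = 3
    B: int = 1000
    filter_quantile: float = 0.0
    orthology_collapse: str = "drop_all"
    go_enrich_params: dict = field(
        default_factory=lambda: {"z_min": 3.0, "min_size": 10, "min_count": 3}
    )
    seed: int = 0

    def validate(self) -> None:
        if set(self.studies) != set(GENERA):
            raise ValueError(f"studies must cover exactly {GENERA}")
        if self.fold_factor < 1:
            raise ValueError("fold_factor must be >= 1")
        if not 0 < self.de_fdr <= 1 or not 0 < self.lnnmv_fdr < 1:
            raise ValueError("FDR levels out of range")
        if self.gates not in GATE_PRESETS:
            raise ValueError(f"gates must be one of {sorted(GATE_PRESETS)}")
        if not 0 <= self.filter_quantile < 1:
            raise ValueError("filter_quantile must lie in [0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _stage_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _anchor_study(study: ExpressionStudy, universe) -> ExpressionStudy:
    """Restrict a study to the linked universe and relabel genes by anchor."""
    table = universe.to_anchor[study.genus]
    keep = [i for i, g in enumerate(study.gene_ids) if g in table]
    sub = study.subset_genes(np.array(keep))
    sub.gene_ids = [table[g] for g in sub.gene_ids]
    return sub


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns the manifest dictionary.

    Any stage failure aborts with the stage name and removes the partial
    outputs already written to ``outdir``.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "gates": GATE_PRESETS[config.gates],
        "stage_seeds": {
            name: _stage_seed(config.seed, tag)
            for name, tag in _STAGE_SEED_TAGS.items()
        },
        "counts": {},
        "results": {},
    }

    def emit(name: str, path: Path) -> None:
        written.append(path)
        manifest.setdefault("files", {})[name] = {
            "path": path.name,
            "sha256": _sha256(path),
        }

    stage = "load"
    try:
        studies = {
            genus: read_expression(
                config.studies[genus]["matrix"], config.studies[genus]["meta"], genus
            )
            for genus in GENERA
        }
        omap = read_orthology(config.orthology, collapse=config.orthology_collapse)
        annotation = read_gmt(config.annotation)

        stage = "filter"
        pre_counts = {g: s.n_genes for g, s in studies.items()}
        studies = {
            g: filter_low_expression(s, config.filter_quantile)
            for g, s in studies.items()
        }
        manifest["counts"]["genes_before_filter"] = pre_counts
        manifest["counts"]["genes_after_filter"] = {
            g: s.n_genes for g, s in studies.items()
        }

        stage = "de"
        calls = {}
        for genus, study in studies.items():
            table = paired_de(study)
            path = outdir / f"de_{genus}.tsv"
            table.to_csv(path, sep="\t")
            emit(f"de_{genus}", path)
            calls[genus] = call_directional(
                table, fold_factor=config.fold_factor, fdr=config.de_fdr
            )
            for direction in ("up", "down"):
                lst = sorted(getattr(calls[genus], direction))
                path = outdir / f"calls_{genus}_{direction}.txt"
                write_gene_list(lst, path)
                emit(f"calls_{genus}_{direction}", path)
        manifest["counts"]["de_calls"] = {
            g: {"up": len(c.up), "down": len(c.down)} for g, c in calls.items()
        }

        stage = "link"
        measured = {g: set(s.gene_ids) for g, s in studies.items()}
        universe = link_universe(omap, measured)
        path = outdir / "linked_universe.tsv"
        universe.to_frame().to_csv(path, sep="\t", index=False)
        emit("linked_universe", path)
        manifest["counts"]["linked_universe_N"] = universe.N

        stage = "project"
        lists = TriadLists(
            up={
                g: project_list(universe, g, set(calls[g].up)) for g in GENERA
            },
            down={
                g: project_list(universe, g, set(calls[g].down)) for g in GENERA
            },
            universe=universe,
        )
        manifest["counts"]["projected"] = {
            g: {"up": len(lists.up[g]), "down": len(lists.down[g])} for g in GENERA
        }

        stage = "venn"
        venn = venn_counts(lists)
        path = outdir / "venn_counts.json"
        path.write_text(
            json.dumps(
                {
                    "regions": venn.regions,
                    "triple_consistent_up": venn.triple_consistent_up,
                    "triple_consistent_down": venn.triple_consistent_down,
                },
                indent=1,
                sort_keys=True,
            )
        )
        emit("venn_counts", path)
        manifest["results"]["triple_consistent"] = {
            "up": venn.triple_consistent_up,
            "down": venn.triple_consistent_down,
        }

        stage = "conserve"
        for direction in ("up", "down"):
            if all(lists.direction(direction)[g] for g in GENERA):
                res = gene_perm_test(
                    lists,
                    direction,
                    B=config.B,
                    seed=manifest["stage_seeds"][f"gene_perm_{direction}"],
                )
                manifest["results"][f"gene_perm_{direction}"] = {
                    "observed": res.observed,
                    "p": res.p_value,
                    "B": res.B,
                }
                path = outdir / f"gene_perm_{direction}.json"
                path.write_text(
                    json.dumps(
                        {
                            "observed": res.observed,
                            "p_value": res.p_value,
                            "B": res.B,
                            "seed": res.seed,
                            "null_quantiles": {
                                q: float(np.quantile(res.null_values, float(q)))
                                for q in ("0.05", "0.25", "0.5", "0.75", "0.95")
                            },
                        },
                        indent=1,
                        sort_keys=True,
                    )
                )
                emit(f"gene_perm_{direction}", path)
            else:
                manifest["results"][f"gene_perm_{direction}"] = "skipped: empty list"
            res = go_perm_test(
                lists,
                annotation,
                direction,
                enrich_params=config.go_enrich_params,
                B=config.B,
                seed=manifest["stage_seeds"][f"go_perm_{direction}"],
            )
            manifest["results"][f"go_perm_{direction}"] = {
                "observed": res.observed,
                "p": res.p_value,
                "B": res.B,
                "flag": res.flag,
            }

        stage = "enrich"
        for direction in ("up", "down"):
            rows, cover, membership = union_enrichment(
                lists, direction, annotation, universe, gates=config.gates
            )
            for name, frame in (
                (f"enrichment_{direction}", rows),
                (f"cover_{direction}", cover.to_frame()),
                (f"membership_{direction}", membership),
            ):
                path = outdir / f"{name}.tsv"
                frame.to_csv(path, sep="\t", index=name.startswith("membership"))
                emit(name, path)

        stage = "heatmap"
        consistent = frozenset.intersection(*(lists.up[g] for g in GENERA)) | (
            frozenset.intersection(*(lists.down[g] for g in GENERA))
        )
        if consistent:
            anchor_studies = [
                _anchor_study(studies[g], universe) for g in GENERA
            ]
            matrix = center_by_gene(anchor_studies, consistent)
            path = outdir / "heatmap_triple_consistent.tsv"
            matrix.to_csv(path, sep="\t", index_label="anchor")
            emit("heatmap_triple_consistent", path)
        manifest["counts"]["triple_consistent_total"] = len(consistent)

        if config.nce_matrix and config.nce_meta:
            stage = "lnnmv"
            nce = read_expression(config.nce_matrix, config.nce_meta, "mouse")
            bearing = [
                s.sample_id for s in nce.samples if s.colon_status == "tumor_bearing"
            ]
            free = [
                s.sample_id for s in nce.samples if s.colon_status == "tumor_free"
            ]
            a = nce.subset_samples(bearing).values
            b = nce.subset_samples(free).values
            fit = lnnmv_fit(a, b)
            d = a.mean(axis=1) - b.mean(axis=1)
            nce_calls = lnnmv_call(
                fit,
                d,
                nce.gene_ids,
                fold_factor=config.fold_factor,
                posterior_fdr=config.lnnmv_fdr,
            )
            manifest["results"]["lnnmv"] = {
                "p_hat": fit.p_hat,
                "up": len(nce_calls.up),
                "down": len(nce_calls.down),
                "converged": fit.converged,
            }
            called = sorted(nce_calls.up | nce_calls.down)
            if called:
                centered = center_by_gene([nce], called)
                path = outdir / "heatmap_nce.tsv"
                centered.to_csv(path, sep="\t", index_label="gene_id")
                emit("heatmap_nce", path)

        stage = "manifest"
        path = outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        written.append(path)
    except Exception as exc:  # noqa: BLE001 - abort cleanly naming the stage
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return manifest
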
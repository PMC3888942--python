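"""End-to-end orchestration: expression → consensus targets → enrichment.

A single YAML config drives all stages; every stage parameter defaults to the
study's stated value (detection limit 40 cycles, 1000 permutations, pfp > 0.5
retention, alpha 0.05). A manifest records parameters, seeds and per-stage
record counts so a run is fully reproducible from its output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from riscmir import consensus as cns
from riscmir import enrichment as enr
from riscmir import io_formats as iof
from riscmir import qpcr

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline config is malformed."""


@dataclass
class SourceSpec:
    path: str
    name: str
    direction: str = "higher_is_better"
    orthologs: bool = False  # project through the ortholog map first


@dataclass
class PipelineConfig:
    """Fully-defaulted pipeline parameters (defaults match the study)."""

    # stage toggles
    run_expression: bool = True
    run_consensus: bool = True
    run_enrichment: bool = True
    # expression stage
    ct_table: str | None = None
    detection_limit: float = 40.0
    normalizer: str = "global"  # global | reference:<assay> | housekeeping:<assay>
    m_tests: int | None = None
    # consensus stage
    sources: list[SourceSpec] = field(default_factory=list)
    ortholog_map: str | None = None
    mirnas: list[str] = field(default_factory=list)
    n_perm: int = 1000
    impute: str = "mean"
    retain: str = "gt:0.5"
    retain_statistic: str = "pfp"
    # enrichment stage
    gmt: str | None = None
    universe: str | None = None
    targets: str | None = None  # explicit target list overrides consensus union
    alpha: float = 0.05
    # global
    seed: int = 0
    out_dir: str = "riscmir_out"


_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def validate_config(path: str | Path | None = None, data: dict | None = None) -> PipelineConfig:
    """Load and type-check a YAML config; unknown keys are rejected and every
    missing key takes its study default."""
    if data is None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - set(_FIELDS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "sources" in data:
        specs = []
        for i, entry in enumerate(data["sources"]):
            if not isinstance(entry, dict) or "path" not in entry:
                raise ConfigError(f"sources[{i}]: need a mapping with a 'path'")
            extra = set(entry) - {"path", "name", "direction", "orthologs"}
            if extra:
                raise ConfigError(f"sources[{i}]: unknown key(s) {sorted(extra)}")
            entry.setdefault("name", Path(entry["path"]).stem)
            specs.append(SourceSpec(**entry))
        data = {**data, "sources": specs}
    cfg = PipelineConfig(**data)
    if cfg.n_perm < 1:
        raise ConfigError(f"n_perm must be >= 1, got {cfg.n_perm}")
    if cfg.detection_limit <= 0:
        raise ConfigError("detection_limit must be positive")
    if not 0 < cfg.alpha <= 1:
        raise ConfigError("alpha must be in (0, 1]")
    cns.RetentionRule.parse(cfg.retain)  # raises on bad rule syntax
    cns.ImputeRule(cfg.impute)
    for spec in cfg.sources:
        iof.ScoreDirection(spec.direction)
    return cfg


def _substream_seeds(seed: int, n: int) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from the single config seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_all(config: PipelineConfig) -> dict:
    """Run the enabled stages and return the manifest (also written to
    ``out_dir/manifest.json`` along with per-stage TSV outputs)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": {
            k: (v if not isinstance(v, list) else [dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s for s in v])
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }
    union_targets: set[str] | None = None

    if config.run_expression:
        if config.ct_table is None:
            raise ConfigError("expression stage enabled but no ct_table given")
        table = iof.read_ct_table(config.ct_table)
        filtered, excluded = qpcr.apply_detection_filter(table, config.detection_limit)
        norm_kind, _, ref = config.normalizer.partition(":")
        if norm_kind == "global":
            norm = qpcr.global_normalize(filtered)
        elif norm_kind in ("reference", "housekeeping"):
            if not ref:
                raise ConfigError(f"normalizer {config.normalizer!r} needs an assay id")
            norm = qpcr.reference_normalize(
                filtered, ref, qpcr.NormalizerKind(norm_kind)
            )
        else:
            raise ConfigError(f"unknown normalizer {config.normalizer!r}")
        fc = qpcr.fold_change_analysis(norm, m_tests=config.m_tests)
        iof.write_results(fc, out / "expression.tsv")
        stage = {
            "records_read": len(table),
            "assays_excluded": excluded,
            "results": len(fc),
        }
        fractions = set(filtered.records["fraction"])
        if {"input", "ago2_ip"} <= fractions:
            ratios = qpcr.ago2_input_ratio_analysis(norm)
            iof.write_results(ratios, out / "ago2_input_ratios.tsv")
            stage["ratio_results"] = len(ratios)
        manifest["stages"]["expression"] = stage

    if config.run_consensus:
        if len(config.sources) < 2:
            raise ConfigError("consensus stage needs >=2 prediction sources")
        ortho = (
            iof.read_ortholog_map(config.ortholog_map)
            if config.ortholog_map
            else None
        )
        tables = []
        for spec in config.sources:
            t = iof.read_prediction_table(spec.path, spec.name, spec.direction)
            n_before = len(t)
            if spec.orthologs:
                if ortho is None:
                    raise ConfigError(
                        f"source {spec.name!r} requests ortholog projection but "
                        "no ortholog_map is configured"
                    )
                t = cns.project_orthologs(t, ortho)
            tables.append((spec, t, n_before))
        mirnas = config.mirnas or sorted(
            set.union(*(set(t.mirnas) for _, t, _ in tables))
        )
        rule = cns.RetentionRule.parse(config.retain, config.retain_statistic)
        impute = cns.ImputeRule(config.impute)
        seeds = _substream_seeds(config.seed, len(mirnas))
        per_mirna_lists: dict[str, list[str]] = {}
        per_mirna_counts: dict[str, dict] = {}
        for mirna, sub_seed in zip(mirnas, seeds):
            ranked = {}
            for spec, t, _ in tables:
                if mirna in set(t.records["mirna_id"]):
                    ranked[spec.name] = cns.rank_by_score(t, mirna)
            if len(ranked) < 2:
                logger.warning("miRNA %s predicted by <2 sources; skipped", mirna)
                continue
            matrix = cns.assemble_rank_matrix(ranked, impute=impute)
            results = cns.rank_product_analysis(
                matrix, n_perm=config.n_perm, seed=sub_seed, impute=impute, rule=rule
            )
            kept = cns.filter_targets(results, rule)
            per_mirna_lists[mirna] = kept
            per_mirna_counts[mirna] = {
                "genes_ranked": len(matrix.genes),
                "discarded_missing_sources": matrix.n_discarded,
                "retained": len(kept),
            }
            iof.write_results(
                cns.results_frame(results), out / f"rp_{mirna.replace('/', '_')}.tsv"
            )
        if not per_mirna_lists:
            raise ValueError("no miRNA had >=2 predicting sources")
        union = cns.union_sets(per_mirna_lists)
        union_targets = union["union"]
        (out / "union_targets.txt").write_text(
            "\n".join(sorted(union_targets)) + "\n"
        )
        manifest["stages"]["consensus"] = {
            "sources": {
                spec.name: {"predictions_read": n_before, "after_projection": len(t)}
                for spec, t, n_before in tables
            },
            "per_mirna": per_mirna_counts,
            "union_size": union["union_size"],
            "list_sizes": union["sizes"],
        }

    if config.run_enrichment:
        if config.gmt is None:
            raise ConfigError("enrichment stage enabled but no gmt given")
        db = iof.read_gmt(config.gmt, config.universe)
        if config.targets:
            targets = {
                g.strip()
                for g in Path(config.targets).read_text().splitlines()
                if g.strip()
            }
        elif union_targets is not None:
            targets = set(union_targets)
        else:
            raise ConfigError(
                "enrichment stage needs a targets file or the consensus stage"
            )
        rows = enr.enrich_pathways(targets, db, alpha=config.alpha)
        iof.write_results(enr.enrichment_frame(rows), out / "enrichment.tsv")
        manifest["stages"]["enrichment"] = {
            "targets": len(targets),
            "pathways_tested": len(db.pathways),
            "pathways_reported": len(rows),
            "significant": sum(r.significant for r in rows),
        }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
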
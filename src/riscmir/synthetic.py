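"""Seeded generators for synthetic study inputs with planted ground truth.

Three generators emulate the statistical structure the analysis stages
assume:

* :func:`gen_prediction_sources` — several prediction sources with partially
  overlapping gene coverage (per-source dropout) and noisy agreement on a
  planted true-target set placed in each source's top score quantile.
* :func:`gen_ct_experiment` — paired treated/contralateral Ct measurements
  across treatment groups and fractions with planted log2 fold changes under
  the 2^-ddCt model, additive Gaussian noise on the cycle scale, and one
  designated stable (effect-free) reference assay.
* :func:`gen_pathway_db` — a pathway database plus a target gene list whose
  overlap with one chosen pathway is planted at a stated fold enrichment.

Every generator is bit-reproducible under a fixed seed and returns a
:class:`SyntheticTruth` carrying the planted signal for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from riscmir.io_formats import (
    CT_COLUMNS,
    CtTable,
    Fraction,
    Group,
    Pathway,
    PathwayDB,
    PredictionTable,
    ScoreDirection,
)

DEFAULT_GROUPS = [g.value for g in Group]
DEFAULT_FRACTIONS = [f.value for f in Fraction]


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    seed: int
    planted_targets: dict[str, set[str]] = field(default_factory=dict)
    planted_log2fc: dict[tuple[str, str, str], float] = field(default_factory=dict)
    stable_assay: str | None = None
    enriched_pathway: str | None = None
    planted_fold: float | None = None
    planted_overlap: int | None = None


# ---------------------------------------------------------------------------
# prediction sources


def gen_prediction_sources(
    g_genes: int = 2000,
    n_sources: int = 4,
    planted: int = 50,
    top_fraction: float = 0.05,
    dropout: float = 0.1,
    seed: int = 0,
    mirna: str = "miR-sim-1",
) -> tuple[dict[str, PredictionTable], SyntheticTruth]:
    """Generate per-source prediction tables with a planted target set.

    Non-planted genes score as exchangeable noise; planted genes, where not
    dropped by the per-source dropout, are placed by quantile assignment at
    uniformly random rank positions within the top ``top_fraction`` of that
    source's list (exact placement, not an additive score shift). Sources
    alternate score orientation to exercise both directions downstream.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if planted >= g_genes:
        raise ValueError("planted must be < g_genes")
    if top_fraction == 1.0:
        import logging

        logging.getLogger(__name__).warning(
            "top_fraction=1 makes planted genes indistinguishable from noise"
        )
    rng = np.random.default_rng(seed)
    width = len(str(g_genes))
    genes = np.array([f"G{i:0{width}d}" for i in range(1, g_genes + 1)])
    planted_idx = rng.choice(g_genes, size=planted, replace=False)
    planted_set = set(genes[planted_idx])
    is_planted = np.zeros(g_genes, bool)
    is_planted[planted_idx] = True

    tables: dict[str, PredictionTable] = {}
    for j in range(n_sources):
        direction = (
            ScoreDirection.LOWER_IS_BETTER
            if j % 3 == 2
            else ScoreDirection.HIGHER_IS_BETTER
        )
        present = rng.random(g_genes) >= dropout
        idx_present = np.flatnonzero(present)
        n_s = idx_present.size
        pl_local = np.flatnonzero(is_planted[idx_present])
        top_k = max(int(math.ceil(top_fraction * n_s)), pl_local.size)
        # rank positions: planted genes uniformly within the top block
        positions = np.empty(n_s, dtype=int)
        top_positions = rng.choice(top_k, size=pl_local.size, replace=False)
        positions[pl_local] = top_positions
        rest = np.setdiff1d(np.arange(n_s), top_positions, assume_unique=False)
        others = np.setdiff1d(np.arange(n_s), pl_local, assume_unique=True)
        positions[others] = rng.permutation(rest)
        scores_sorted = np.sort(rng.uniform(size=n_s))[::-1]  # best first
        scores = scores_sorted[positions]
        if direction is ScoreDirection.LOWER_IS_BETTER:
            scores = 1.0 - scores
        name = f"src{j + 1}"
        tables[name] = PredictionTable(
            name,
            direction,
            pd.DataFrame(
                {
                    "mirna_id": mirna,
                    "gene_id": genes[idx_present],
                    "score": scores,
                }
            ),
        )
    truth = SyntheticTruth(seed=seed, planted_targets={mirna: planted_set})
    return tables, truth


# ---------------------------------------------------------------------------
# Ct experiment


def plant_effects(
    assays: Sequence[str],
    log2fc: float,
    fractions: Sequence[str] = DEFAULT_FRACTIONS,
    groups: Sequence[str] = ("HFS",),
) -> dict[tuple[str, str, str], float]:
    """Convenience builder: the same planted log2 fold change for each listed
    assay in the given fractions and groups (AP5 groups default to no effect)."""
    return {
        (a, f, g): log2fc for a in assays for f in fractions for g in groups
    }


def gen_ct_experiment(
    n_animals: int = 6,
    groups: Sequence[str] = DEFAULT_GROUPS,
    fractions: Sequence[str] = DEFAULT_FRACTIONS,
    n_assays: int = 48,
    planted_log2fc: Mapping[tuple[str, str, str], float] | None = None,
    sigma_ct: float = 0.2,
    seed: int = 0,
    timepoint: float = 30.0,
    sigma_animal: float = 0.5,
) -> tuple[CtTable, SyntheticTruth]:
    """Generate paired treated/contralateral Ct data under the 2^-ddCt model.

    Assay ids are ``miR-sim-01`` ... plus a designated stable reference
    ``miR-ref`` with zero planted effect everywhere. Per animal and assay, the
    control-side Ct is the assay baseline (uniform in [18, 35]) plus an
    animal-level offset (sd ``sigma_animal``, shared between sides, so it
    cancels in the within-animal contrast); the treated-side Ct is the
    control-side Ct minus the planted log2 fold change plus Gaussian noise of
    sd ``sigma_ct``. ``planted_log2fc`` maps (assay_id, fraction, group) to
    the planted effect; unlisted combinations (including AP5 groups by
    default) have no effect.
    """
    if sigma_ct < 0:
        raise ValueError("sigma_ct must be >= 0")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_assays)))
    assays = [f"miR-sim-{i:0{width}d}" for i in range(1, n_assays)] + ["miR-ref"]
    effects = dict(planted_log2fc or {})
    for key in effects:
        if key[0] == "miR-ref":
            raise ValueError("the stable reference assay cannot carry an effect")
    baseline = {a: rng.uniform(18.0, 35.0) for a in assays}
    rows = []
    for group in groups:
        for i in range(1, n_animals + 1):
            animal = f"{group}_rat{i}"
            for fraction in fractions:
                offsets = {a: rng.normal(0.0, sigma_animal) for a in assays}
                for side in ("control", "treated"):
                    sample = f"{animal}_{fraction}_{side}"
                    for a in assays:
                        ct = baseline[a] + offsets[a]
                        if side == "treated":
                            lfc = effects.get((a, fraction, group), 0.0)
                            ct = ct - lfc + rng.normal(0.0, sigma_ct)
                        rows.append(
                            (sample, animal, group, fraction, side, timepoint, a, ct)
                        )
    table = CtTable(pd.DataFrame(rows, columns=CT_COLUMNS))
    truth = SyntheticTruth(
        seed=seed, planted_log2fc=effects, stable_assay="miR-ref"
    )
    return table, truth


# ---------------------------------------------------------------------------
# pathway database


def gen_pathway_db(
    n_pathways: int = 100,
    genes_per_pathway: tuple[int, int] = (40, 80),
    universe_size: int = 3000,
    planted_pathway_fold: float = 4.0,
    target_list_size: int = 200,
    seed: int = 0,
) -> tuple[PathwayDB, list[str], SyntheticTruth]:
    """Generate a pathway database and a target list with one planted
    over-represented pathway.

    The planted pathway's overlap with the target list is fixed at
    ``round(fold * expected)`` where expected = n*K/M; the remaining targets
    are drawn outside the planted pathway so the overlap is exact. With
    ``planted_pathway_fold == 1`` the whole target list is uniform (null
    construction) and no pathway is marked as planted.
    """
    rng = np.random.default_rng(seed)
    width = len(str(universe_size))
    universe = np.array([f"U{i:0{width}d}" for i in range(1, universe_size + 1)])
    lo, hi = genes_per_pathway
    pathways = []
    for i in range(1, n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        pid = f"pw{i:03d}"
        pathways.append(Pathway(pid, f"synthetic pathway {i}", frozenset(members)))
    db = PathwayDB(pathways, frozenset(universe))

    n = target_list_size
    M = universe_size
    if planted_pathway_fold == 1.0:
        targets = sorted(rng.choice(universe, size=n, replace=False))
        return db, list(targets), SyntheticTruth(seed=seed)

    planted_i = int(rng.integers(n_pathways))
    planted = pathways[planted_i]
    K = len(planted.genes)
    expected = n * K / M
    k_star = int(round(planted_pathway_fold * expected))
    if k_star > min(K, n):
        max_fold = min(K, n) / expected
        raise ValueError(
            f"planted fold {planted_pathway_fold} infeasible; max achievable "
            f"fold is {max_fold:.2f}"
        )
    inside = rng.choice(sorted(planted.genes), size=k_star, replace=False)
    outside_pool = np.array(sorted(set(universe) - planted.genes))
    outside = rng.choice(outside_pool, size=n - k_star, replace=False)
    targets = sorted(np.concatenate([inside, outside]))
    truth = SyntheticTruth(
        seed=seed,
        enriched_pathway=planted.pathway_id,
        planted_fold=planted_pathway_fold,
        planted_overlap=k_star,
    )
    return db, list(targets), truth


# ---------------------------------------------------------------------------
# file emitters (the exact dialects the io_formats readers accept)


def emit_prediction_table(table: PredictionTable, path: str | Path) -> None:
    table.records.to_csv(path, sep="\t", index=False)


def emit_ct_table(table: CtTable, path: str | Path) -> None:
    table.records.to_csv(path, index=False)


def emit_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in db.pathways:
            fh.write("\t".join([pw.pathway_id, pw.name, *sorted(pw.genes)]) + "\n")


def emit_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(genes) + "\n")
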
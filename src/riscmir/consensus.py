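"""Consensus miRNA target prediction by rank-product aggregation.

Each prediction source orders its candidate targets by quality score; the
rank product of a gene is the geometric mean of its ranks across sources.
Genes missing exactly one source have that rank imputed (arithmetic mean of
the observed ranks by default); genes missing two or more sources are
discarded. A within-source permutation null — shuffle each source's observed
rank column, re-apply imputation, recompute rank products — yields a per-gene
permutation p-value and the pfp (percentage of false prediction, an FDR-like
quantity: expected number of null genes at least as extreme, divided by the
gene's rank position).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from riscmir.io_formats import OrthologMap, PredictionTable, ScoreDirection

logger = logging.getLogger(__name__)


class ImputeRule(str, enum.Enum):
    """How to fill the single missing rank of a gene.

    mean/median are neutral with respect to the gene's own evidence;
    worst_plus_one penalizes absence with the source's worst rank + 1.
    """

    MEAN = "mean"
    MEDIAN = "median"
    WORST_PLUS_ONE = "worst_plus_one"


class Comparator(str, enum.Enum):
    GREATER_THAN = "greater_than"
    AT_MOST = "at_most"


@dataclass
class RetentionRule:
    """Which genes to keep after the permutation analysis.

    The default (pfp > 0.5) keeps all but the least consistently ranked genes,
    deliberately permissive so true targets are not eliminated before pathway
    analysis; (at_most, 0.05) is the conventional significance-style rule.
    """

    comparator: Comparator = Comparator.GREATER_THAN
    threshold: float = 0.5
    statistic: str = "pfp"  # "pfp" or "p_perm"

    @classmethod
    def parse(cls, text: str, statistic: str = "pfp") -> "RetentionRule":
        """Parse 'gt:0.5' / 'le:0.05' style rule strings."""
        op, _, value = text.partition(":")
        comparator = {"gt": Comparator.GREATER_THAN, "le": Comparator.AT_MOST}.get(op)
        if comparator is None or not value:
            raise ValueError(f"unparseable retention rule {text!r} (want gt:X or le:X)")
        return cls(comparator, float(value), statistic)

    def applies(self, value: float) -> bool:
        if self.comparator is Comparator.GREATER_THAN:
            return value > self.threshold
        return value <= self.threshold


@dataclass
class RankMatrix:
    """Genes × sources matrix of within-source ranks (1 = best, ties averaged).

    ``observed_mask`` marks ranks coming from a source's own ordering;
    ``imputed_mask`` marks single-missing entries filled by the imputation
    rule. After assembly no gene is missing more than one source.
    """

    genes: list[str]
    sources: list[str]
    ranks: np.ndarray  # (G, S) float
    observed_mask: np.ndarray  # (G, S) bool
    imputed_mask: np.ndarray  # (G, S) bool
    n_discarded: int = 0

    def __post_init__(self) -> None:
        if self.ranks.shape != (len(self.genes), len(self.sources)):
            raise ValueError("rank matrix shape mismatch")
        if np.any(self.observed_mask & self.imputed_mask):
            raise ValueError("entry cannot be both observed and imputed")
        if np.any((~self.observed_mask).sum(axis=1) > 1):
            raise ValueError("gene missing more than one source after assembly")


@dataclass
class RankProductResult:
    gene: str
    rp: float
    n_observed: int
    p_perm: float
    pfp: float
    retained: bool = False


# ---------------------------------------------------------------------------
# ortholog projection and per-source ranking


def project_orthologs(table: PredictionTable, ortho: OrthologMap) -> PredictionTable:
    """Translate gene ids through a one-to-one ortholog map; unmapped genes
    are dropped (and counted in the log)."""
    mapping = ortho.as_dict()
    records = table.records
    mapped = records["gene_id"].map(mapping)
    n_dropped = int(mapped.isna().sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d predictions without a direct ortholog",
            table.source_name,
            n_dropped,
            len(records),
        )
    out = records.loc[mapped.notna()].assign(gene_id=mapped.dropna())
    if out.empty:
        logger.warning("%s: no predictions survive ortholog projection", table.source_name)
    return PredictionTable(table.source_name, table.score_direction, out.reset_index(drop=True))


def rank_by_score(table: PredictionTable, mirna: str) -> pd.Series:
    """Rank a source's predicted genes for one miRNA, best score = rank 1.

    Tied scores receive the average of the ranks they span.
    """
    sub = table.records[table.records["mirna_id"] == mirna]
    if sub.empty:
        raise ValueError(f"miRNA {mirna!r} absent from source {table.source_name!r}")
    scores = sub["score"].to_numpy(float)
    if table.score_direction is ScoreDirection.HIGHER_IS_BETTER:
        scores = -scores
    ranks = st.rankdata(scores, method="average")
    return pd.Series(ranks, index=sub["gene_id"].to_numpy(), name=table.source_name)


# ---------------------------------------------------------------------------
# assembly and rank product


def _impute_rows(
    ranks: np.ndarray, observed: np.ndarray, rule: ImputeRule, worst: np.ndarray
) -> np.ndarray:
    """Fill single-missing entries in (.., G, S) rank arrays.

    ``observed`` is (G, S); arrays may carry a leading permutation axis.
    ``worst`` is the per-source worst observed rank (for WORST_PLUS_ONE).
    """
    out = ranks.copy()
    miss_g, miss_s = np.nonzero(~observed)
    if miss_g.size == 0:
        return out
    obs = np.where(observed, ranks, np.nan)
    if rule is ImputeRule.MEAN:
        fill = np.nanmean(obs[..., miss_g, :], axis=-1)
    elif rule is ImputeRule.MEDIAN:
        fill = np.nanmedian(obs[..., miss_g, :], axis=-1)
    else:
        fill = np.broadcast_to(worst[miss_s] + 1.0, ranks.shape[:-2] + miss_g.shape)
    out[..., miss_g, miss_s] = fill
    return out


def assemble_rank_matrix(
    ranked_lists: dict[str, pd.Series],
    impute: ImputeRule = ImputeRule.MEAN,
) -> RankMatrix:
    """Combine per-source rank lists into a genes × sources matrix.

    Genes present in all sources keep their ranks; genes missing exactly one
    source get that entry imputed; genes missing two or more are discarded.
    """
    if len(ranked_lists) < 2:
        raise ValueError("need >=2 prediction sources")
    sources = list(ranked_lists)
    all_genes = sorted(set().union(*(set(s.index) for s in ranked_lists.values())))
    G, S = len(all_genes), len(sources)
    ranks = np.full((G, S), np.nan)
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    for j, name in enumerate(sources):
        series = ranked_lists[name]
        idx = [gene_pos[g] for g in series.index]
        ranks[idx, j] = series.to_numpy(float)
    observed = ~np.isnan(ranks)
    n_missing = (~observed).sum(axis=1)
    keep = n_missing <= 1
    n_discarded = int((~keep).sum())
    if not keep.any():
        raise ValueError("no consensus support: every gene misses >=2 sources")
    if n_discarded:
        logger.info("discarded %d genes missing >=2 sources", n_discarded)
    genes = [g for g, k in zip(all_genes, keep) if k]
    ranks = ranks[keep]
    observed = observed[keep]
    worst = np.nanmax(np.where(observed, ranks, np.nan), axis=0)
    filled = _impute_rows(np.nan_to_num(ranks), observed, impute, worst)
    return RankMatrix(
        genes=genes,
        sources=sources,
        ranks=filled,
        observed_mask=observed,
        imputed_mask=~observed,
        n_discarded=n_discarded,
    )


def rank_product(matrix: RankMatrix) -> np.ndarray:
    """Geometric mean of each gene's ranks over all sources (imputed included),
    computed in the log domain."""
    return np.exp(np.mean(np.log(matrix.ranks), axis=1))


# ---------------------------------------------------------------------------
# permutation null


def _null_rank_products(
    matrix: RankMatrix,
    n_perm: int,
    rng: np.random.Generator,
    impute: ImputeRule,
) -> np.ndarray:
    """(n_perm, G) null rank products from within-source shuffles.

    Each source's observed rank column is shuffled over the positions that
    source predicts; imputation is re-applied per permutation so imputed genes
    are compared against their own null.
    """
    G, S = matrix.ranks.shape
    null = np.zeros((n_perm, G, S))
    for j in range(S):
        obs_idx = np.flatnonzero(matrix.observed_mask[:, j])
        values = matrix.ranks[obs_idx, j]
        # one independent permutation of the column per iteration
        order = np.argsort(rng.random((n_perm, obs_idx.size)), axis=1)
        null[:, obs_idx, j] = values[order]
    worst = np.max(
        np.where(matrix.observed_mask, matrix.ranks, -np.inf), axis=0
    )
    null = _impute_rows(null, matrix.observed_mask, impute, worst)
    return np.exp(np.mean(np.log(null), axis=2))


def permutation_pvalues(
    matrix: RankMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    impute: ImputeRule = ImputeRule.MEAN,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values and pfp for each gene's rank product.

    p(g) = (1 + #{permutations with the gene's own null rp <= rp(g)}) /
    (n_perm + 1); the pseudo-count keeps p away from 0. pfp(g) is the expected
    number of null rank products (pooled over all genes) at least as small as
    rp(g), divided by the gene's ascending-rp rank position, then monotonized
    from the largest rp downward.

    Returns (p_perm, pfp), deterministic for a given seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        logger.warning("n_perm=%d gives unstable p estimates", n_perm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rp_obs = rank_product(matrix)
    null_rp = _null_rank_products(matrix, n_perm, rng, impute)
    eps = 1e-9  # tolerate log-domain float jitter in rp ties
    counts = (null_rp <= rp_obs[None, :] * (1 + eps)).sum(axis=0)
    p_perm = (1.0 + counts) / (n_perm + 1.0)

    pooled = np.sort(null_rp.ravel())
    exp_false = np.searchsorted(pooled, rp_obs * (1 + eps), side="right") / n_perm
    order = np.argsort(rp_obs, kind="stable")
    position = np.empty_like(order)
    position[order] = np.arange(1, len(rp_obs) + 1)
    pfp = exp_false / position
    # enforce monotonicity in rp (a better-ranked gene never has larger pfp)
    pfp_sorted = np.minimum.accumulate(pfp[order][::-1])[::-1]
    pfp = np.empty_like(pfp_sorted)
    pfp[order] = pfp_sorted
    return p_perm, pfp


# ---------------------------------------------------------------------------
# filtering and set algebra


def rank_product_analysis(
    matrix: RankMatrix,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    impute: ImputeRule = ImputeRule.MEAN,
    rule: RetentionRule | None = None,
) -> list[RankProductResult]:
    """Full per-gene rank-product analysis: statistic, permutation p, pfp,
    retention flag. Results are sorted by ascending rank product."""
    rule = rule or RetentionRule()
    rp = rank_product(matrix)
    p_perm, pfp = permutation_pvalues(matrix, n_perm=n_perm, seed=seed, impute=impute)
    n_obs = matrix.observed_mask.sum(axis=1)
    results = [
        RankProductResult(g, float(r), int(n), float(p), float(q))
        for g, r, n, p, q in zip(matrix.genes, rp, n_obs, p_perm, pfp)
    ]
    results.sort(key=lambda r: (r.rp, r.gene))
    for res in results:
        value = res.pfp if rule.statistic == "pfp" else res.p_perm
        res.retained = rule.applies(value)
    return results


def filter_targets(
    results: list[RankProductResult], rule: RetentionRule | None = None
) -> list[str]:
    """Apply a retention rule and return the kept genes sorted by ascending
    rank product.

    The default rule (pfp > 0.5) deliberately retains everything but the least
    consistently ranked genes; pass ``RetentionRule(Comparator.AT_MOST, 0.05)``
    for conventional significance filtering.
    """
    rule = rule or RetentionRule()
    if rule.comparator is Comparator.GREATER_THAN:
        logger.info(
            "retention rule keeps %s > %g: this keeps the LEAST consistent "
            "genes under the conventional orientation — intended as a "
            "permissive pre-filter",
            rule.statistic,
            rule.threshold,
        )
    kept = []
    for res in sorted(results, key=lambda r: (r.rp, r.gene)):
        value = res.pfp if rule.statistic == "pfp" else res.p_perm
        res.retained = rule.applies(value)
        if res.retained:
            kept.append(res.gene)
    if not kept:
        logger.warning("retention rule kept no genes")
    return kept


def union_sets(named_lists: dict[str, list[str]]) -> dict:
    """Union of per-miRNA target lists with per-list sizes and pairwise
    overlap counts."""
    if not named_lists:
        raise ValueError("need >=1 gene list")
    sets = {name: set(genes) for name, genes in named_lists.items()}
    names = list(sets)
    overlaps = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(names)
        for b in names[i + 1 :]
    }
    union: set[str] = set().union(*sets.values())
    return {
        "sizes": {name: len(s) for name, s in sets.items()},
        "union": union,
        "union_size": len(union),
        "overlaps": overlaps,
    }


def results_frame(results: list[RankProductResult]) -> pd.DataFrame:
    """Tabulate rank-product results for writing."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "rp": r.rp,
                "n_observed": r.n_observed,
                "p_perm": r.p_perm,
                "pfp": r.pfp,
                "retained": r.retained,
            }
            for r in results
        ]
    )
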
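"""Hypergeometric over-representation of gene lists in pathway sets.

For a target list of size n drawn from a universe of M genes, the overlap k
with a pathway of size K is tested against the one-sided hypergeometric tail
P(X >= k); fold enrichment is the observed overlap divided by its expected
value n*K/M. Output rows follow the conventional over-representation report
schema (pathway, N, K, FC, p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from riscmir.io_formats import PathwayDB

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    pathway_id: str
    name: str
    n_overlap: int
    pathway_size: int
    fold_enrichment: float
    p: float
    significant: bool = False


def hypergeometric_tail(k: int, K: int, n: int, M: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeometric(M, K, n).

    k = overlap, K = pathway size, n = list size, M = universe size.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if K > M or n > M:
        raise ValueError("pathway and list sizes cannot exceed the universe")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, M, K, n))


def enrichment_fold(k: int, K: int, n: int, M: int) -> float:
    """Observed/expected overlap ratio; 0 when the overlap is empty."""
    if min(K, n, M) <= 0:
        raise ValueError("K, n, M must be positive")
    return k / (n * K / M)


def enrich_pathways(
    targets: set[str], db: PathwayDB, alpha: float = 0.05
) -> list[EnrichmentRow]:
    """Test each pathway for over-representation of the target list.

    Target genes outside the universe are excluded from n (logged); pathways
    with zero overlap are omitted. Rows are sorted by ascending p, ties broken
    by descending fold enrichment; rows with p <= alpha are flagged
    significant.
    """
    in_universe = set(targets) & set(db.universe)
    n_outside = len(set(targets)) - len(in_universe)
    if n_outside:
        logger.info("dropped %d target genes outside the universe", n_outside)
    if not in_universe:
        raise ValueError("no target genes in the pathway universe")
    M = len(db.universe)
    n = len(in_universe)
    rows = []
    for pw in db.pathways:
        k = len(in_universe & pw.genes)
        if k == 0:
            continue
        K = len(pw.genes)
        p = hypergeometric_tail(k, K, n, M)
        rows.append(
            EnrichmentRow(
                pw.pathway_id,
                pw.name,
                k,
                K,
                enrichment_fold(k, K, n, M),
                p,
                significant=p <= alpha,
            )
        )
    rows.sort(key=lambda r: (r.p, -r.fold_enrichment, r.pathway_id))
    return rows


def enrichment_frame(rows: list[EnrichmentRow], bh: bool = False) -> pd.DataFrame:
    """Tabulate enrichment rows (pathway_id, name, N, K, FC, p, significant);
    ``bh=True`` appends a Benjamini–Hochberg adjusted column."""
    df = pd.DataFrame(
        [
            {
                "pathway_id": r.pathway_id,
                "name": r.name,
                "N": r.n_overlap,
                "K": r.pathway_size,
                "FC": r.fold_enrichment,
                "p": r.p,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
    if bh and not df.empty:
        from statsmodels.stats.multitest import multipletests

        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
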
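import numpy as np
import pandas as pd
import pytest

from riscmir.consensus import RankMatrix
from riscmir.io_formats import CT_COLUMNS, CtTable


def make_rank_matrix(ranks, genes=None, sources=None, observed=None) -> RankMatrix:
    """Build a RankMatrix from a plain nested list of ranks (all observed
    unless an ``observed`` boolean mask is given; unobserved entries are
    treated as already imputed)."""
    ranks = np.asarray(ranks, float)
    G, S = ranks.shape
    genes = genes or [f"g{i}" for i in range(G)]
    sources = sources or [f"s{j}" for j in range(S)]
    observed = (
        np.ones_like(ranks, bool) if observed is None else np.asarray(observed, bool)
    )
    return RankMatrix(genes, sources, ranks, observed, ~observed)


def make_ct_table(rows) -> CtTable:
    """rows: (sample, animal, group, fraction, side, timepoint, assay, ct)."""
    return CtTable(pd.DataFrame(rows, columns=CT_COLUMNS))


@pytest.fixture
def paired_ct_table() -> CtTable:
    """Two animals, one group/fraction, three assays, fully paired."""
    rows = []
    cts = {"mA": 20.0, "mB": 22.0, "mC": 24.0}
    for animal in ("rat1", "rat2"):
        for side in ("treated", "control"):
            sample = f"{animal}_{side}"
            for assay, ct in cts.items():
                shift = -1.0 if (side == "treated" and assay == "mA") else 0.0
                rows.append(
                    (sample, animal, "HFS", "input", side, 30.0, assay, ct + shift)
                )
    return make_ct_table(rows)
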
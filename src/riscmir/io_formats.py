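"""Readers, writers and validated in-memory containers for all external tables.

Every downstream module operates on the domain types defined here
(:class:`PredictionTable`, :class:`OrthologMap`, :class:`PathwayDB`,
:class:`CtTable`); file-format concerns (TSV/CSV/GMT dialects, missing-value
spellings, duplicate rows) stop at this boundary.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Case-insensitive spellings that parse to an undetermined Ct (no amplification
#: before the cycle cutoff). They carry "Ct = +inf" semantics for the detection
#: filter and are stored as NaN.
UNDETERMINED_CT = frozenset({"undet", "undetermined", "na"})


class FormatError(ValueError):
    """A file violates the expected schema (missing column, bad enum, ...)."""


class ParseError(ValueError):
    """A field could not be converted to its expected type."""


class ScoreDirection(str, enum.Enum):
    """Orientation of a prediction source's quality score."""

    HIGHER_IS_BETTER = "higher_is_better"
    LOWER_IS_BETTER = "lower_is_better"


class Group(str, enum.Enum):
    """Treatment arms: high-frequency stimulation (HFS) induces LTP,
    low-frequency test stimulation (LFT) does not, and AP5 blocks NMDA
    receptors in either condition."""

    HFS = "HFS"
    AP5_HFS = "AP5_HFS"
    LFT = "LFT"
    AP5_LFT = "AP5_LFT"


class Fraction(str, enum.Enum):
    """Input = total lysate; ago2_ip = Argonaute-2 immunoprecipitate."""

    INPUT = "input"
    AGO2_IP = "ago2_ip"


class Side(str, enum.Enum):
    """Treated dentate gyrus vs the contralateral (within-animal) control."""

    TREATED = "treated"
    CONTROL = "control"


CT_COLUMNS = [
    "sample_id",
    "animal_id",
    "group",
    "fraction",
    "side",
    "timepoint",
    "assay_id",
    "ct",
]


@dataclass
class PredictionTable:
    """Per-source miRNA→gene prediction scores.

    ``records`` has columns ``mirna_id``, ``gene_id``, ``score``;
    (mirna_id, gene_id) pairs are unique and scores finite.
    """

    source_name: str
    score_direction: ScoreDirection
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"mirna_id", "gene_id", "score"} - set(self.records.columns)
        if missing:
            raise FormatError(f"prediction table missing columns: {sorted(missing)}")
        if not np.all(np.isfinite(self.records["score"].to_numpy(float))):
            raise FormatError(f"non-finite score in source {self.source_name!r}")
        if self.records.duplicated(["mirna_id", "gene_id"]).any():
            raise FormatError(
                f"duplicate (mirna_id, gene_id) pairs in source {self.source_name!r}"
            )

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.records["mirna_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class OrthologMap:
    """One-to-one source-species → target-species gene pairs."""

    pairs: pd.DataFrame  # columns: source_gene, target_gene

    def __post_init__(self) -> None:
        missing = {"source_gene", "target_gene"} - set(self.pairs.columns)
        if missing:
            raise FormatError(f"ortholog map missing columns: {sorted(missing)}")
        if (
            self.pairs["source_gene"].duplicated().any()
            or self.pairs["target_gene"].duplicated().any()
        ):
            raise FormatError("ortholog map is not one-to-one")

    def as_dict(self) -> dict[str, str]:
        return dict(
            zip(self.pairs["source_gene"], self.pairs["target_gene"], strict=True)
        )

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class Pathway:
    pathway_id: str
    name: str
    genes: frozenset[str]


@dataclass
class PathwayDB:
    """A pathway collection plus the gene universe enrichment is tested against.

    The universe defaults to the union of all pathway genes; an explicit
    universe must contain every annotated gene.
    """

    pathways: list[Pathway]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for pw in self.pathways:
            if not pw.genes:
                raise FormatError(f"pathway {pw.pathway_id!r} has no genes")
            union |= pw.genes
        if not self.universe:
            self.universe = frozenset(union)
        elif not union <= self.universe:
            missing = sorted(union - self.universe)[:5]
            raise FormatError(
                f"universe does not cover pathway genes (e.g. {missing})"
            )

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class CtTable:
    """Long-format threshold-cycle records with sample metadata.

    One row per well: sample/animal identifiers, treatment group, fraction,
    side, timepoint (minutes), assay and Ct. Undetermined Ct values are NaN.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.records.columns)
        if missing:
            raise FormatError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.records["ct"]
        if (ct.dropna() <= 0).any():
            raise FormatError("Ct values must be positive")
        if self.records.duplicated(["sample_id", "assay_id"]).any():
            raise FormatError("duplicate (sample_id, assay_id) records")

    def unpaired_animals(self) -> list[str]:
        """Animals with a treated record lacking a same-animal control partner
        (within animal, fraction and timepoint)."""
        unpaired = []
        keys = ["animal_id", "fraction", "timepoint"]
        for key, sub in self.records.groupby(keys):
            sides = set(sub["side"])
            if Side.TREATED.value in sides and Side.CONTROL.value not in sides:
                unpaired.append(str(key[0]))
        return sorted(set(unpaired))

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# readers


def read_prediction_table(
    path: str | Path, source_name: str, score_direction: ScoreDirection | str
) -> PredictionTable:
    """Read a tab-separated prediction export (mirna_id, gene_id, score).

    Duplicate (mirna, gene) rows — typically transcript-level duplicates — are
    collapsed to the best score for the stated direction.
    """
    direction = ScoreDirection(score_direction)
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str})
    missing = {"mirna_id", "gene_id", "score"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    scores = pd.to_numeric(df["score"], errors="coerce")
    bad = scores.isna() & df["score"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(f"{path}: non-numeric score at data row {row + 1}")
    if scores.isna().any():
        raise ParseError(f"{path}: empty score field")
    df = df.assign(score=scores.astype(float))
    keep_max = direction is ScoreDirection.HIGHER_IS_BETTER
    agg = "max" if keep_max else "min"
    n_dup = int(df.duplicated(["mirna_id", "gene_id"]).sum())
    if n_dup:
        logger.info("%s: collapsed %d duplicate prediction rows", path, n_dup)
        df = (
            df.groupby(["mirna_id", "gene_id"], as_index=False)["score"]
            .agg(agg)
        )
    return PredictionTable(source_name, direction, df.reset_index(drop=True))


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column TSV of ortholog pairs and keep only one-to-one pairs.

    Any pair participating in a one-to-many or many-to-one relation is removed
    entirely (direct orthologs only); the number removed is logged.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["source_gene", "target_gene"], dtype=str
    )
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly 2 columns")
    df = df.drop_duplicates()
    one_to_one = ~(
        df["source_gene"].duplicated(keep=False)
        | df["target_gene"].duplicated(keep=False)
    )
    n_removed = int((~one_to_one).sum())
    if n_removed:
        logger.info("%s: removed %d non one-to-one ortholog pairs", path, n_removed)
    kept = df.loc[one_to_one].reset_index(drop=True)
    if kept.empty:
        logger.warning("%s: ortholog map empty after one-to-one filtering", path)
    return OrthologMap(kept)


def read_gmt(path: str | Path, universe_path: str | Path | None = None) -> PathwayDB:
    """Read a GMT file (set id TAB description TAB gene TAB gene ...).

    If ``universe_path`` (one gene per line) is given it overrides the default
    universe (union of all pathway genes) and must cover it.
    """
    pathways: list[Pathway] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway with 0 genes")
            pathways.append(Pathway(fields[0], fields[1], genes))
    universe: frozenset[str] = frozenset()
    if universe_path is not None:
        with open(universe_path) as fh:
            universe = frozenset(g.strip() for g in fh if g.strip())
    return PathwayDB(pathways, universe)


def _parse_ct(value: object) -> float:
    if isinstance(value, str):
        if value.strip().lower() in UNDETERMINED_CT or not value.strip():
            return math.nan
        try:
            return float(value)
        except ValueError as exc:
            raise ParseError(f"unparseable Ct value {value!r}") from exc
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    return float(value)


def read_ct_table(path: str | Path) -> CtTable:
    """Read a long-format CSV of Ct records.

    ``timepoint`` is optional (defaults to 0 minutes). "undet"/"undetermined"/
    "NA" Ct values parse as missing for the detection filter. Treated records
    without a same-animal control partner are reported via a warning.
    """
    df = pd.read_csv(path, dtype=str)
    if "timepoint" not in df.columns:
        df["timepoint"] = "0"
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col, enum_cls in [("group", Group), ("fraction", Fraction), ("side", Side)]:
        valid = {e.value for e in enum_cls}
        bad = set(df[col].unique()) - valid
        if bad:
            raise FormatError(
                f"{path}: unknown {col} value(s) {sorted(bad)}; expected {sorted(valid)}"
            )
    df["ct"] = [_parse_ct(v) for v in df["ct"]]
    df["timepoint"] = pd.to_numeric(df["timepoint"]).astype(float)
    table = CtTable(df[CT_COLUMNS].reset_index(drop=True))
    unpaired = table.unpaired_animals()
    if unpaired:
        logger.warning(
            "%s: treated records without same-animal control for animals %s",
            path,
            unpaired,
        )
    return table


# ---------------------------------------------------------------------------
# writer


def write_results(
    table: pd.DataFrame | Sequence, path: str | Path, sig_digits: int = 6
) -> None:
    """Write a results table as TSV with a header.

    Floats are rendered with ``sig_digits`` significant digits so a re-read
    reproduces the rendered values exactly. Accepts a DataFrame or a sequence
    of dataclass-like row objects.
    """
    if not isinstance(table, pd.DataFrame):
        rows = list(table)
        if not rows:
            raise ValueError("refusing to write an empty results table")
        table = pd.DataFrame([vars(r) if hasattr(r, "__dict__") else r for r in rows])
    if table.empty:
        raise ValueError("refusing to write an empty results table")
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{sig_digits}g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a TSV produced by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
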
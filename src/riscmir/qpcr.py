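"""Ct-level quantification for RIP (Ago2-IP) vs input qPCR experiments.

The workflow mirrors standard relative-quantification practice: exclude
undetected assays (Ct above a cycle limit), normalize Ct values (global mean
over all assays on a card, or a single reference/housekeeping assay), form
per-animal 2^-ddCt fold changes of the treated side relative to the
contralateral control, summarize per group, and test with a paired t-test
under Bonferroni correction or one-way ANOVA with Fisher's LSD. The Ago2-IP /
input fold-change ratio quantifies differential RISC association.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from riscmir.io_formats import CtTable, Fraction, Side

logger = logging.getLogger(__name__)


class NormalizerKind(str, enum.Enum):
    GLOBAL_MEAN = "global_mean"
    REFERENCE = "reference"
    HOUSEKEEPING = "housekeeping"


@dataclass
class NormalizedMatrix:
    """Assay × sample matrix of normalizer-relative dCt values (PCR cycles).

    ``meta`` carries one row of sample metadata per matrix column.
    """

    values: pd.DataFrame  # index: assay_id, columns: sample_id
    normalizer: NormalizerKind
    reference_assay: str | None = None
    meta: pd.DataFrame | None = None  # per-sample metadata, indexed by sample_id


@dataclass
class StandardCurve:
    """Linear fit of Ct on log10 quantity for a dilution series.

    Amplification efficiency follows from the slope: a perfectly doubling
    reaction has slope -1/log10(2) = -3.3219 and efficiency 1.0.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float = field(init=False)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("non-amplifying curve (slope must be negative)")
        self.efficiency = 10.0 ** (-1.0 / self.slope) - 1.0
        if not 0.0 < self.efficiency <= 1.1:
            logger.warning(
                "amplification efficiency %.3f outside plausible (0, 1.1]",
                self.efficiency,
            )
        if self.r_squared < 0.98:
            logger.warning("standard curve r^2 = %.4f < 0.98", self.r_squared)


@dataclass
class FoldChangeResult:
    assay_id: str
    fraction: str
    group: str
    fold_change: float
    sem: float
    p_raw: float
    p_adj: float
    n: int


@dataclass
class RatioResult:
    assay_id: str
    group: str
    ratio: float
    sem: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# detection filter


def apply_detection_filter(
    table: CtTable, limit: float = 40.0
) -> tuple[CtTable, list[str]]:
    """Exclude assays undetected in any sample of the given table.

    An assay is excluded when any of its Ct values is missing or strictly
    greater than ``limit`` (a Ct of exactly ``limit`` is retained). Pass a
    per-contrast subset to make exclusion contrast-local.
    """
    if limit <= 0:
        raise ValueError("detection limit must be positive")
    df = table.records
    undetected = df["ct"].isna() | (df["ct"] > limit)
    excluded = sorted(df.loc[undetected, "assay_id"].unique())
    kept = df[~df["assay_id"].isin(excluded)].reset_index(drop=True)
    if kept.empty:
        raise ValueError("no quantifiable assays after detection filtering")
    return CtTable(kept), excluded


# ---------------------------------------------------------------------------
# normalization


def _ct_matrix(table: CtTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot to assay × sample, with per-sample metadata."""
    df = table.records
    mat = df.pivot(index="assay_id", columns="sample_id", values="ct")
    meta = (
        df.drop_duplicates("sample_id")
        .set_index("sample_id")[["animal_id", "group", "fraction", "side", "timepoint"]]
    )
    return mat, meta.loc[mat.columns]


def global_normalize(table: CtTable, min_assays: int = 100) -> NormalizedMatrix:
    """Normalize each Ct to the per-sample mean Ct over all detected assays.

    Appropriate for large panels where most assays are unregulated; a warning
    is emitted below ``min_assays`` detected assays per sample.
    """
    mat, meta = _ct_matrix(table)
    detected = mat.notna().sum(axis=0)
    if (detected == 0).any():
        bad = list(detected.index[detected == 0])
        raise ValueError(f"sample(s) with zero detected assays: {bad}")
    if (detected < min_assays).any():
        logger.warning(
            "global-mean normalization with <%d detected assays in some samples "
            "(min observed: %d)",
            min_assays,
            int(detected.min()),
        )
    values = mat - mat.mean(axis=0, skipna=True)
    return NormalizedMatrix(values, NormalizerKind.GLOBAL_MEAN, meta=meta)


def reference_normalize(
    table: CtTable,
    reference: str,
    kind: NormalizerKind = NormalizerKind.REFERENCE,
) -> NormalizedMatrix:
    """Normalize each Ct to a single reference assay's Ct in the same sample.

    The reference row is removed from the output. Housekeeping-gene
    normalization (e.g. Arc vs ubiquitin-B) is the same operation with
    ``kind=NormalizerKind.HOUSEKEEPING``.
    """
    mat, meta = _ct_matrix(table)
    if reference not in mat.index:
        raise ValueError(f"reference assay {reference!r} absent from table")
    ref_row = mat.loc[reference]
    if ref_row.isna().any():
        bad = list(ref_row.index[ref_row.isna()])
        raise ValueError(f"reference {reference!r} undetected in samples {bad}")
    values = mat.drop(index=reference) - ref_row
    return NormalizedMatrix(values, kind, reference_assay=reference, meta=meta)


def select_reference(
    table: CtTable, design_factors: list[str]
) -> list[tuple[str, float, float]]:
    """Rank candidate reference assays by expression stability.

    For each assay detected in every sample, a fixed-effects ANOVA of Ct on
    the design factors (main effects only) gives a model F-test p-value; a
    stable assay has a high p (no factor explains its Ct) and a low overall
    SD. Candidates are ordered by the rank-sum of descending-p rank and
    ascending-SD rank; ties break by smaller SD, then lexical assay id.
    An exactly constant assay is assigned p = 1, SD = 0 (maximally stable).
    """
    import statsmodels.formula.api as smf

    df = table.records
    complete = df.groupby("assay_id")["ct"].apply(lambda s: s.notna().all())
    candidates = sorted(complete.index[complete])
    if len(candidates) < 2:
        raise ValueError("need >=2 candidate assays detected in all samples")
    results = []
    for assay in candidates:
        sub = df[df["assay_id"] == assay]
        sd = float(sub["ct"].std(ddof=1))
        if sd == 0.0 or math.isnan(sd):
            results.append((assay, 1.0, 0.0))
            continue
        usable = [f for f in design_factors if sub[f].nunique() > 1]
        if not usable:
            results.append((assay, 1.0, sd))
            continue
        formula = "ct ~ " + " + ".join(f"C({f})" for f in usable)
        fit = smf.ols(formula, data=sub).fit()
        p = float(fit.f_pvalue)
        if math.isnan(p):  # zero residual variance with varying Ct
            p = 0.0
        results.append((assay, p, sd))
    p_rank = st.rankdata([-p for _, p, _ in results])  # small = high p
    sd_rank = st.rankdata([sd for _, _, sd in results])
    order = sorted(
        range(len(results)),
        key=lambda i: (p_rank[i] + sd_rank[i], results[i][2], results[i][0]),
    )
    return [results[i] for i in order]


# ---------------------------------------------------------------------------
# standard curve


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """Ordinary least squares of Ct on log10 quantity over a dilution series."""
    if len({x for x, _ in points}) < 3:
        raise ValueError("need >=3 distinct dilution points")
    x = np.array([p[0] for p in points], float)
    y = np.array([p[1] for p in points], float)
    fit = st.linregress(x, y)
    if fit.slope >= 0:
        raise ValueError("non-amplifying curve (slope must be negative)")
    return StandardCurve(float(fit.slope), float(fit.intercept), float(fit.rvalue**2))


def relative_quantity(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: quantity = 10^((intercept - ct) / (-slope))."""
    return 10.0 ** ((curve.intercept - ct) / (-curve.slope))


# ---------------------------------------------------------------------------
# fold changes and ratios


def fold_change(dct_treated: float, dct_control: float) -> float:
    """2^-ddCt fold change of treated relative to control."""
    if not (math.isfinite(dct_treated) and math.isfinite(dct_control)):
        raise ValueError("dCt values must be finite")
    return 2.0 ** (-(dct_treated - dct_control))


def ago2_input_ratio(fc_ago2: float, fc_input: float) -> float:
    """Ago2-IP fold change divided by input fold change (differential RISC
    association)."""
    if fc_input <= 0:
        raise ValueError("input fold change must be positive")
    if fc_ago2 <= 0:
        raise ValueError("Ago2-IP fold change must be positive")
    return fc_ago2 / fc_input


def per_animal_fold_changes(norm: NormalizedMatrix) -> pd.DataFrame:
    """Within-animal treated-vs-contralateral fold change per assay.

    Returns a long DataFrame (assay_id, fraction, group, timepoint, animal_id,
    fold_change, ddct). Animals lacking either side are skipped.
    """
    if norm.meta is None:
        raise ValueError("normalized matrix lacks sample metadata")
    long = norm.values.reset_index().melt(
        id_vars="assay_id", var_name="sample_id", value_name="dct"
    )
    long = long.join(norm.meta, on="sample_id")
    keys = ["assay_id", "fraction", "group", "timepoint", "animal_id"]
    wide = long.pivot_table(index=keys, columns="side", values="dct", aggfunc="mean")
    if "treated" not in wide.columns or "control" not in wide.columns:
        raise ValueError("need both treated and control sides")
    wide = wide.dropna(subset=["treated", "control"])
    out = wide.reset_index()
    out["ddct"] = out["treated"] - out["control"]
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out.drop(columns=["treated", "control"])


def fold_change_analysis(
    norm: NormalizedMatrix,
    m_tests: int | None = None,
    geometric: bool = False,
) -> list[FoldChangeResult]:
    """Group-level fold-change summaries with a paired t-test per assay.

    Per-animal folds are averaged arithmetically by default (geometric mean
    behind ``geometric``); the paired t-test is run on the per-animal ddCt
    differences and Bonferroni-adjusted over ``m_tests`` (default: number of
    assays tested).
    """
    per_animal = per_animal_fold_changes(norm)
    grouped = per_animal.groupby(["assay_id", "fraction", "group"])
    if m_tests is None:
        m_tests = per_animal["assay_id"].nunique()
    results = []
    for (assay, fraction, group), sub in grouped:
        folds = sub["fold_change"].to_numpy(float)
        if geometric:
            fc = float(np.exp(np.mean(np.log(folds))))
        else:
            fc = float(np.mean(folds))
        sem = float(st.sem(folds)) if len(folds) > 1 else math.nan
        _, p_raw, _ = _paired_t(sub["ddct"].to_numpy(float))
        p_adj = min(1.0, m_tests * p_raw)
        results.append(
            FoldChangeResult(
                assay, str(fraction), str(group), fc, sem, p_raw, p_adj, len(folds)
            )
        )
    return results


def ago2_input_ratio_analysis(
    norm: NormalizedMatrix, geometric: bool = False
) -> list[RatioResult]:
    """Per-assay Ago2-IP/input fold-change ratios, computed within animal and
    then averaged; one-sample t-test of log2 ratio against 0."""
    per_animal = per_animal_fold_changes(norm)
    wide = per_animal.pivot_table(
        index=["assay_id", "group", "animal_id"],
        columns="fraction",
        values="fold_change",
    )
    if Fraction.INPUT.value not in wide.columns or Fraction.AGO2_IP.value not in wide.columns:
        raise ValueError("need both input and ago2_ip fractions")
    wide = wide.dropna()
    if (wide[Fraction.INPUT.value] <= 0).any():
        raise ValueError("non-positive input fold change")
    wide["ratio"] = wide[Fraction.AGO2_IP.value] / wide[Fraction.INPUT.value]
    results = []
    for (assay, group), sub in wide.reset_index().groupby(["assay_id", "group"]):
        ratios = sub["ratio"].to_numpy(float)
        r = (
            float(np.exp(np.mean(np.log(ratios))))
            if geometric
            else float(np.mean(ratios))
        )
        sem = float(st.sem(ratios)) if len(ratios) > 1 else math.nan
        if len(ratios) > 1 and np.std(ratios) > 0:
            _, p = st.ttest_1samp(np.log2(ratios), 0.0)
            p = float(p)
        else:
            p = math.nan
        results.append(RatioResult(assay, str(group), r, sem, p, len(ratios)))
    return results


# ---------------------------------------------------------------------------
# significance tests


def _paired_t(differences: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided one-sample t on paired differences; returns (t, p, degenerate)."""
    d = np.asarray(differences, float)
    if len(d) < 2:
        raise ValueError("need >=2 paired differences")
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0, True
        return math.inf if d[0] > 0 else -math.inf, 0.0, True
    t, p = st.ttest_1samp(d, 0.0)
    return float(t), float(p), False


def ttest_dunn_bonferroni(
    differences_by_assay: dict[str, np.ndarray], m: int | None = None
) -> pd.DataFrame:
    """Paired two-sided t-test per assay with single-step Bonferroni correction.

    ``differences_by_assay`` maps assay id to per-animal treated-minus-control
    dCt differences; ``m`` defaults to the number of assays. Zero-variance
    differences with nonzero mean are reported with p = 0 and a degeneracy
    flag.
    """
    if m is None:
        m = len(differences_by_assay)
    rows = []
    for assay, diffs in differences_by_assay.items():
        t, p_raw, degenerate = _paired_t(np.asarray(diffs, float))
        rows.append(
            {
                "assay_id": assay,
                "t": t,
                "p_raw": p_raw,
                "p_adj": min(1.0, m * p_raw),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def anova_lsd(
    groups: list[np.ndarray], alpha: float = 0.05
) -> tuple[float, float, np.ndarray]:
    """One-way ANOVA with Fisher's LSD post-hoc pairwise comparisons.

    Returns (F, p_anova, pairwise p matrix). The LSD t statistic for groups i, j
    is (mean_i - mean_j) / sqrt(MSW * (1/n_i + 1/n_j)) on the within-group
    degrees of freedom; p-values are two-sided and unadjusted (Fisher's
    protected LSD convention: interpret only if the omnibus p <= alpha).
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with n >= 2 each")
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    df_within = int(ns.sum() - k)
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msw = ssw / df_within
    grand = float(np.concatenate(groups).mean())
    ssb = float((ns * (means - grand) ** 2).sum())
    msb = ssb / (k - 1)
    if msw == 0.0:
        logger.warning("degenerate ANOVA: zero within-group variance")
        f_stat = math.inf if msb > 0 else 0.0
        p_anova = 0.0 if msb > 0 else 1.0
    else:
        f_stat = msb / msw
        p_anova = float(st.f.sf(f_stat, k - 1, df_within))
    pmat = np.ones((k, k))
    for i, j in itertools.combinations(range(k), 2):
        if msw == 0.0:
            p = 1.0 if means[i] == means[j] else 0.0
        else:
            t = (means[i] - means[j]) / math.sqrt(msw * (1 / ns[i] + 1 / ns[j]))
            p = float(2 * st.t.sf(abs(t), df_within))
        pmat[i, j] = pmat[j, i] = p
    return float(f_stat), float(p_anova), pmat
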
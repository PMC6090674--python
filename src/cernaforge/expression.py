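"""Normalization, filtering and statistics for time-series expression matrices.

Implements the quantification conventions of the leaf-development ceRNA
analysis: FPKM for mRNA/lncRNA, RPM for miRNA and circRNA junction reads,
log2(x+1) transformation, a replicate-reproducibility Pearson filter, a
per-class abundance filter, and stage-wise Welch t-tests.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")
SCALES = ("raw_count", "FPKM", "RPM", "log2p1")

#: abundance thresholds, inclusive, applied on the class-appropriate scale
ABUNDANCE_RULES = {
    "circRNA": ("raw_count", 2.0),
    "mRNA": ("FPKM", 1.0),
    "lncRNA": ("FPKM", 1.0),
    "miRNA": ("RPM", 1.0),
}

_DAY_RE = re.compile(r"Day(\d+)")


def day_of(label: str) -> int:
    """Extract the day number from a sample label like ``Day12`` or ``Day12_r1``."""
    m = _DAY_RE.search(str(label))
    if m is None:
        raise ValueError(f"sample label {label!r} carries no day number")
    return int(m.group(1))


@dataclass
class ExpressionMatrix:
    """Transcripts x ordered samples, with RNA-class labels and a declared scale.

    Parameters
    ----------
    values
        DataFrame with transcript ids as index and ordered sample labels as
        columns. No missing cells.
    rna_class
        Series mapping transcript id -> one of ``mRNA/lncRNA/circRNA/miRNA``.
    scale
        One of ``raw_count``, ``FPKM``, ``RPM``, ``log2p1``. Scale transitions
        happen only through :func:`fpkm`, :func:`rpm` and :func:`log2p1`.
    """

    values: pd.DataFrame
    rna_class: pd.Series
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        self.rna_class = self.rna_class.reindex(self.values.index)
        if self.rna_class.isna().any():
            missing = self.rna_class[self.rna_class.isna()].index.tolist()[:5]
            raise ValueError(f"transcripts without rna_class: {missing}")
        bad = set(self.rna_class.unique()) - set(RNA_CLASSES)
        if bad:
            raise ValueError(f"unknown rna classes: {sorted(bad)}")
        days = [day_of(c) for c in self.values.columns]
        if days != sorted(days):
            raise ValueError("sample columns are not in day order")
        if self.scale != "log2p1" and (self.values.values < 0).any():
            raise ValueError("negative values in a nonneg-scale matrix")

    # -- convenience -------------------------------------------------------
    @property
    def transcripts(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, ids) -> "ExpressionMatrix":
        ids = [i for i in self.values.index if i in set(ids)]
        return ExpressionMatrix(self.values.loc[ids], self.rna_class.loc[ids], self.scale)

    def select_samples(self, labels) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(labels)], self.rna_class, self.scale)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


# ---------------------------------------------------------------------------
# normalization


def fpkm(counts: ExpressionMatrix, lengths: pd.Series, totals: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    value = count / (length/1e3) / (total/1e6), per cell.
    """
    if counts.scale != "raw_count":
        raise ValueError("fpkm expects raw counts")
    lengths = lengths.reindex(counts.transcripts)
    if lengths.isna().any():
        off = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"missing transcript lengths: {off}")
    if (lengths <= 0).any():
        off = lengths[lengths <= 0].index.tolist()[:5]
        raise ValueError(f"non-positive transcript lengths: {off}")
    totals = totals.reindex(counts.samples)
    if totals.isna().any() or (totals <= 0).any():
        off = totals[(totals.isna()) | (totals <= 0)].index.tolist()
        raise ValueError(f"non-positive library totals for samples: {off}")
    vals = counts.values.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)
    return ExpressionMatrix(vals, counts.rna_class, "FPKM")


def rpm(counts: ExpressionMatrix, totals: pd.Series) -> ExpressionMatrix:
    """Reads per million: count / (total/1e6)."""
    if counts.scale != "raw_count":
        raise ValueError("rpm expects raw counts")
    totals = totals.reindex(counts.samples)
    if totals.isna().any() or (totals <= 0).any():
        off = totals[(totals.isna()) | (totals <= 0)].index.tolist()
        raise ValueError(f"non-positive library totals for samples: {off}")
    vals = counts.values.div(totals / 1e6, axis=1)
    return ExpressionMatrix(vals, counts.rna_class, "RPM")


def log2p1(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(x + 1); input must be FPKM or RPM (or raw counts for circRNA use)."""
    if m.scale not in ("FPKM", "RPM", "raw_count"):
        raise ValueError(f"log2p1 not defined on scale {m.scale!r}")
    if (m.values.values < 0).any():
        raise ValueError("negative input to log2p1")
    return ExpressionMatrix(np.log2(m.values + 1.0), m.rna_class, "log2p1")


# ---------------------------------------------------------------------------
# correlation


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation with the two-sided t-based p-value.

    p is derived from t = r*sqrt((n-2)/(1-r^2)) on n-2 df (scipy's exact
    beta form, analytically identical).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length vectors")
    n = x.size
    if n < 3:
        raise ValueError("pearson needs n >= 3 for a defined p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-row Pearson r and two-sided p between two matrices."""
    n = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((ac**2).sum(axis=1))
    sb = np.sqrt((bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ac * bc).sum(axis=1) / (sa * sb)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    undefined = (sa == 0) | (sb == 0)
    return np.where(undefined, np.nan, r), np.where(undefined, np.nan, p)


def reproducibility_filter(
    replicate_a: ExpressionMatrix,
    replicate_b: ExpressionMatrix,
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> list[str]:
    """Transcripts whose two replicate time courses correlate (r > r_min, p < p_max).

    Strict inequalities; zero-variance rows are dropped with a warning.
    """
    if list(replicate_a.transcripts) != list(replicate_b.transcripts):
        raise ValueError("replicate matrices must share transcripts")
    if len(replicate_a.samples) != len(replicate_b.samples):
        raise ValueError("replicate matrices must share time points")
    if len(replicate_a.samples) < 3:
        raise ValueError("need >= 3 time points")
    r, p = _rowwise_pearson(replicate_a.values.to_numpy(float), replicate_b.values.to_numpy(float))
    undef = np.isnan(r)
    if undef.any():
        logger.warning(
            "reproducibility_filter: %d constant transcript(s) dropped (undefined correlation)",
            int(undef.sum()),
        )
    keep = (~undef) & (r > r_min) & (p < p_max)
    return [t for t, k in zip(replicate_a.transcripts, keep) if k]


# ---------------------------------------------------------------------------
# abundance filter


def abundance_filter(matrices: dict[str, ExpressionMatrix]) -> dict[str, list[str]]:
    """Per-class low-expression filter, retained iff threshold met in >= 1 sample.

    Thresholds (inclusive): circRNA junction counts >= 2; mRNA and lncRNA
    FPKM >= 1; miRNA RPM >= 1. Each class matrix must be on its class scale.
    """
    retained: dict[str, list[str]] = {}
    for cls, m in matrices.items():
        if cls not in ABUNDANCE_RULES:
            raise ValueError(f"unknown rna class {cls!r}")
        scale, thr = ABUNDANCE_RULES[cls]
        if m.scale != scale:
            raise ValueError(f"{cls} abundance filter expects scale {scale!r}, got {m.scale!r}")
        keep = (m.values >= thr).any(axis=1)
        retained[cls] = [t for t, k in zip(m.transcripts, keep) if k]
    return retained


# ---------------------------------------------------------------------------
# differential expression


def stage_de_ttest(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-transcript two-sample t-test between two stage sample sets.

    Pooled-variance Student's t by default, which is exactly calibrated
    under an equal-variance null; ``equal_var=False`` switches to Welch's
    unequal-variance test (slightly conservative at these group sizes).
    Significant iff p < alpha, strict. Degenerate rows (both groups
    constant): p=1 when the two group means are equal, p=0 otherwise.
    """
    for g in (group_a, group_b):
        if len(g) < 2:
            raise ValueError("each group needs >= 2 samples")
    if m.scale != "log2p1":
        raise ValueError("stage DE expects log-scale values")
    a = m.values[list(group_a)].to_numpy(float)
    b = m.values[list(group_b)].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    both_const = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    if both_const.any():
        logger.warning("stage_de_ttest: %d doubly-constant transcript(s), p set by convention",
                       int(both_const.sum()))
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        diff_sign = np.sign(a.mean(axis=1) - b.mean(axis=1))
        with np.errstate(invalid="ignore"):
            t_conv = np.where(equal_means, 0.0, np.inf * np.where(diff_sign == 0, 1.0, diff_sign))
        p = np.where(both_const, np.where(equal_means, 1.0, 0.0), p)
        t = np.where(both_const, t_conv, t)
    out = pd.DataFrame({"t": t, "p": p}, index=m.transcripts)
    out["significant"] = out["p"] < alpha
    return out


# ---------------------------------------------------------------------------
# parent co-expression


@dataclass
class ParentCoexpression:
    fraction: float
    table: pd.DataFrame = field(repr=False)


def parent_coexpression(
    ecirc,
    circ_expr: ExpressionMatrix,
    gene_expr: ExpressionMatrix,
    r_min: float = 0.5,
    p_max: float = 0.05,
) -> ParentCoexpression:
    """Fraction of exonic circRNAs significantly co-expressed with their parent gene.

    ``ecirc`` is an iterable of junction records with ``name`` and a single
    entry in ``parent_genes``. circRNAs whose parent is absent from
    ``gene_expr`` are skipped with a warning and excluded from the
    denominator.
    """
    rows = []
    for j in ecirc:
        parents = sorted(j.parent_genes)
        if len(parents) != 1:
            raise ValueError(f"ecircRNA {j.name} must have exactly one parent gene")
        parent = parents[0]
        if j.name not in circ_expr.values.index:
            logger.warning("parent_coexpression: no expression for %s, skipped", j.name)
            continue
        if parent not in gene_expr.values.index:
            logger.warning("parent_coexpression: parent %s of %s not expressed, skipped",
                           parent, j.name)
            continue
        x = circ_expr.values.loc[j.name].to_numpy(float)
        y = gene_expr.values.loc[parent].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("parent_coexpression: constant profile for %s/%s, skipped",
                           j.name, parent)
            continue
        res = pearson(x, y)
        rows.append((j.name, parent, res.r, res.p, res.r > r_min and res.p < p_max))
    table = pd.DataFrame(rows, columns=["circ_id", "parent_gene", "r", "p", "coexpressed"])
    frac = float(table["coexpressed"].mean()) if len(table) else float("nan")
    return ParentCoexpression(fraction=frac, table=table)
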
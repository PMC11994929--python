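"""Count-matrix preprocessing: filtering, log2, quantile normalization, QC.

The pipeline starts from a gene×sample raw count matrix and produces the
normalized log2 expression matrix the subtype classifier consumes.  The fixed
order of operations is: low-expression gene filter → log2(count + pseudocount)
→ quantile normalization → PCA-based outlier-sample removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class QCReport:
    """What preprocessing removed and why."""

    genes_removed: int = 0
    outlier_sample_ids: list[str] = field(default_factory=list)
    pc_scores: pd.DataFrame | None = None
    thresholds: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genes_removed": int(self.genes_removed),
            "outlier_sample_ids": list(self.outlier_sample_ids),
            "thresholds": dict(self.thresholds),
        }


def _check_matrix(df: pd.DataFrame, name: str = "matrix") -> None:
    if df.empty:
        raise ValueError(f"{name} is empty")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {name}: {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs in {name}: {dupes[:5]}")


def filter_low_expression_genes(
    counts: pd.DataFrame, min_count: int = 5, sample_fraction: float = 0.8
) -> tuple[pd.DataFrame, QCReport]:
    """Drop genes with fewer than ``min_count`` counts in at least
    ``sample_fraction`` of samples.

    A gene is removed iff the fraction of samples where its count is below
    ``min_count`` is >= ``sample_fraction``; retained genes keep their order.
    """
    _check_matrix(counts, "counts")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    low_frac = (counts.values < min_count).mean(axis=1)
    keep = low_frac < sample_fraction
    out = counts.loc[keep]
    report = QCReport(
        genes_removed=int((~keep).sum()),
        thresholds={"min_count": min_count, "sample_fraction": sample_fraction},
    )
    return out, report


def log2_transform(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(count + pseudocount)."""
    _check_matrix(counts, "counts")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if (counts.values < 0).any():
        raise ValueError("negative counts")
    return pd.DataFrame(
        np.log2(counts.values + pseudocount), index=counts.index, columns=counts.columns
    )


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common distribution of mean order
    statistics.

    Each column is replaced by the cross-sample mean of the sorted values at
    its ranks; tied values within a column receive the mean of the quantile
    means their ranks span, so after normalization every column holds the same
    multiset of values (up to that tie averaging).
    """
    _check_matrix(expr, "expression")
    if expr.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(expr.values).all():
        raise ValueError("expression contains non-finite values")
    values = expr.values.astype(float)
    mean_quantiles = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = mean_quantiles
        # ties: average the quantile means across each tied run
        sorted_col = col[order]
        boundaries = np.r_[0, np.flatnonzero(np.diff(sorted_col) != 0) + 1, n]
        for a, b in zip(boundaries[:-1], boundaries[1:]):
            if b - a > 1:
                assigned[order[a:b]] = mean_quantiles[a:b].mean()
        out[:, j] = assigned
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def detect_outlier_samples(
    expr: pd.DataFrame, n_components: int = 2, z_threshold: float = 6.0
) -> QCReport:
    """Flag outlier samples by robust z-scores on principal components.

    Samples are the observations (genes the features); a sample is flagged
    when its median/MAD robust z-score on any of the first ``n_components``
    components exceeds ``z_threshold`` in absolute value.  Deterministic up to
    component sign, which the robust z is insensitive to in magnitude.
    """
    _check_matrix(expr, "expression")
    n_samples = expr.shape[1]
    if n_samples < n_components + 2:
        raise ValueError(
            f"need at least {n_components + 2} samples for {n_components} components"
        )
    X = expr.values.T  # samples × genes
    X = X - X.mean(axis=0)
    if not np.any(np.abs(X) > 1e-12):
        return QCReport(thresholds={"n_components": 0, "z_threshold": z_threshold})
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(X)
    flagged: set[str] = set()
    z = np.zeros_like(scores)
    for k in range(scores.shape[1]):
        s = scores[:, k]
        med = np.median(s)
        mad = np.median(np.abs(s - med))
        scale = 1.4826 * mad if mad > 0 else (s.std() or 1.0)
        z[:, k] = (s - med) / scale
    mask = (np.abs(z) > z_threshold).any(axis=1)
    flagged = [expr.columns[i] for i in np.flatnonzero(mask)]
    pc_scores = pd.DataFrame(
        scores, index=expr.columns, columns=[f"PC{k+1}" for k in range(scores.shape[1])]
    )
    return QCReport(
        outlier_sample_ids=sorted(flagged),
        pc_scores=pc_scores,
        thresholds={"n_components": n_components, "z_threshold": z_threshold},
    )


def preprocess_counts(
    counts: pd.DataFrame,
    min_count: int = 5,
    sample_fraction: float = 0.8,
    pseudocount: float = 1.0,
    n_components: int = 2,
    z_threshold: float = 6.0,
) -> tuple[pd.DataFrame, QCReport]:
    """Full preprocessing chain: filter → log2 → quantile-normalize → drop
    PCA outliers.  Returns the cleaned expression matrix and a merged QC
    report."""
    filtered, gene_report = filter_low_expression_genes(counts, min_count, sample_fraction)
    expr = quantile_normalize(log2_transform(filtered, pseudocount))
    outlier_report = detect_outlier_samples(expr, n_components, z_threshold)
    expr = expr.drop(columns=outlier_report.outlier_sample_ids)
    report = QCReport(
        genes_removed=gene_report.genes_removed,
        outlier_sample_ids=outlier_report.outlier_sample_ids,
        pc_scores=outlier_report.pc_scores,
        thresholds={**gene_report.thresholds, **outlier_report.thresholds},
    )
    return expr, report
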
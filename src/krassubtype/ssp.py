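"""Nearest-centroid single-sample predictor (SSP) for KL/KP/K subtyping.

Each tumor is correlated (Pearson) against per-subtype centroid expression
vectors over a fixed gene panel and assigned to the nearest centroid; samples
whose best correlation falls below a threshold (default 0.15, the convention
of centroid-based consensus classifiers) remain unclassified and are handed to
the random-forest rescue step.  A gene-wise permutation null quantifies how
large a maximum correlation arises by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBTYPES = ("KL", "KP", "K")


@dataclass
class ClassifierConfig:
    correlation_threshold: float = 0.15
    n_permutations: int = 1000
    min_gene_overlap_fraction: float = 0.5
    standardize_genes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 <= self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in [-1, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.min_gene_overlap_fraction <= 1:
            raise ValueError("min_gene_overlap_fraction must be in (0, 1]")


@dataclass
class SubtypeCall:
    """One sample's classification: correlations, label, provenance."""

    sample_id: str
    correlations: dict[str, float]
    best_subtype: str
    delta: float
    classified: bool
    method: str  # "SSP" or "RF"
    tie: bool = False
    permutation_p: float | None = None

    def as_row(self) -> dict:
        row = {"sample_id": self.sample_id}
        row.update({f"corr_{s}": self.correlations.get(s, np.nan) for s in SUBTYPES})
        row.update(
            {
                "delta": self.delta,
                "label": self.best_subtype,
                "classified": self.classified,
                "method": self.method,
                "tie": self.tie,
                "perm_p": self.permutation_p,
            }
        )
        return row


def calls_to_frame(calls: list[SubtypeCall]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in calls])


def _validate_centroids(centroids: pd.DataFrame) -> None:
    if centroids.shape[1] < 2:
        raise ValueError("need at least 2 subtype centroids")
    if centroids.index.duplicated().any():
        raise ValueError("duplicate gene IDs in centroid table")
    if not np.isfinite(centroids.values).all():
        raise ValueError("centroid table contains non-finite values")


def _standardize(expr: pd.DataFrame, centroids: pd.DataFrame):
    """Gene-wise z-scoring using cohort mean/sd, applied identically to the
    sample columns and the centroid columns so correlations are computed in
    one standardized space."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1).replace(0.0, 1.0)
    expr_z = expr.sub(mu, axis=0).div(sd, axis=0)
    cent_z = centroids.sub(mu, axis=0).div(sd, axis=0)
    return expr_z, cent_z


def _pearson_matrix(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of X against every column of C
    (both gene-indexed the same way).  Returns samples × subtypes."""
    Xc = X - X.mean(axis=0)
    Cc = C - C.mean(axis=0)
    xs = np.sqrt((Xc**2).sum(axis=0))
    cs = np.sqrt((Cc**2).sum(axis=0))
    if (xs == 0).any() or (cs == 0).any():
        raise ValueError("zero-variance profile: Pearson correlation undefined")
    return (Xc.T @ Cc) / np.outer(xs, cs)


def correlate_to_centroids(
    sample_profile: pd.Series,
    centroids: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> dict[str, float]:
    """Pearson correlation of one sample against each subtype centroid over
    the gene intersection."""
    config = config or ClassifierConfig()
    _validate_centroids(centroids)
    common = centroids.index.intersection(sample_profile.index)
    needed = config.min_gene_overlap_fraction * len(centroids)
    if len(common) < max(needed, 3):
        raise ValueError(
            f"only {len(common)}/{len(centroids)} centroid genes present in sample "
            f"(need >= {needed:.0f} and >= 3)"
        )
    x = sample_profile.loc[common].to_numpy(float)[:, None]
    C = centroids.loc[common].to_numpy(float)
    corr = _pearson_matrix(x, C)[0]
    return dict(zip(centroids.columns, corr.astype(float)))


def classify_by_centroid(
    correlations: dict[str, float], config: ClassifierConfig | None = None
) -> SubtypeCall:
    """Assign the nearest-centroid label from a correlation dict.

    best = argmax correlation; classified iff the max meets the threshold;
    delta = top1 - top2.  Exact ties resolve by the fixed subtype order of the
    correlation dict and raise the ``tie`` flag.
    """
    config = config or ClassifierConfig()
    if len(correlations) < 2:
        raise ValueError("need correlations for at least 2 subtypes")
    names = list(correlations)
    values = np.array([correlations[s] for s in names], float)
    order = np.argsort(-values, kind="stable")
    best, second = order[0], order[1]
    tie = bool(values[best] == values[second])
    classified = bool(values[best] >= config.correlation_threshold)
    return SubtypeCall(
        sample_id="",
        correlations=dict(correlations),
        best_subtype=names[best] if classified else "unclassified",
        delta=float(values[best] - values[second]),
        classified=classified,
        method="SSP",
        tie=tie,
    )


def permutation_null(
    expr: pd.DataFrame,
    centroids: pd.DataFrame,
    config: ClassifierConfig | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Gene-wise permutation null of the maximum centroid correlation.

    For each replicate every gene's values are independently permuted across
    samples, producing "virtual tumors" with the cohort's gene-wise marginals
    but no coordinated subtype signal; the max-over-subtypes correlation of
    every virtual sample is pooled into the null.  The empirical p for a real
    sample is the add-one-smoothed fraction of null maxima at least as large
    as its observed maximum.
    """
    config = config or ClassifierConfig()
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples for the permutation null")
    common = centroids.index.intersection(expr.index)
    expr = expr.loc[common]
    centroids = centroids.loc[common]
    if config.standardize_genes:
        expr, centroids = _standardize(expr, centroids)
    X = expr.to_numpy(float)
    C = centroids.to_numpy(float)
    observed = _pearson_matrix(X, C).max(axis=1)

    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = X.shape
    null_max = np.empty((config.n_permutations, n_samples))
    for b in range(config.n_permutations):
        perm = np.argsort(rng.random((n_genes, n_samples)), axis=1)
        Xp = np.take_along_axis(X, perm, axis=1)
        null_max[b] = _pearson_matrix(Xp, C).max(axis=1)
    null = null_max.ravel()
    p = (1.0 + (null[None, :] >= observed[:, None]).sum(axis=1)) / (1.0 + null.size)
    return null, pd.Series(p, index=expr.columns, name="perm_p")


def classify_cohort(
    expr: pd.DataFrame,
    centroids: pd.DataFrame,
    config: ClassifierConfig | None = None,
    compute_permutation_p: bool = True,
) -> list[SubtypeCall]:
    """Run the SSP over a whole (preprocessed, log-scale) cohort.

    Applies optional cohort gene standardization, correlates every sample to
    every centroid, assigns nearest-centroid labels with the correlation
    threshold, and attaches permutation p-values.
    """
    config = config or ClassifierConfig()
    _validate_centroids(centroids)
    common = centroids.index.intersection(expr.index)
    needed = config.min_gene_overlap_fraction * len(centroids)
    if len(common) < max(needed, 3):
        raise ValueError(
            f"only {len(common)}/{len(centroids)} centroid genes present in cohort"
        )
    sub_expr = expr.loc[common]
    sub_cent = centroids.loc[common]
    if config.standardize_genes:
        sub_expr, sub_cent = _standardize(sub_expr, sub_cent)
    corr = _pearson_matrix(sub_expr.to_numpy(float), sub_cent.to_numpy(float))
    perm_p = None
    if compute_permutation_p:
        # permutation operates on the raw (pre-standardized) sub-matrix so the
        # null includes the standardization step itself
        _, perm_p = permutation_null(expr.loc[common], centroids.loc[common], config)
    calls = []
    for j, sample_id in enumerate(expr.columns):
        correlations = dict(zip(sub_cent.columns, corr[j].astype(float)))
        call = classify_by_centroid(correlations, config)
        call.sample_id = sample_id
        if perm_p is not None:
            call.permutation_p = float(perm_p.iloc[j])
        calls.append(call)
    return calls
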
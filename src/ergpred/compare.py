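"""Cluster-bootstrap model comparison and paired-eye diagnostics.

Because both eyes of one participant can enter the cohort, observations
are clustered within individuals. Model comparisons therefore resample
at the individual level (all of a drawn individual's eyes enter each
bootstrap replicate together), and the degree of between-eye dependence
is summarized by a one-way ANOVA intraclass correlation for cluster
samples, with the matching design-effect effective sample size.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import BootstrapInstabilityError, UndefinedICCError
from .mars import (
    LinearModel,
    MARSModel,
    _refit_terms,
    cv_linear,
    cv_tune,
    fit_linear,
    r_squared,
)

logger = logging.getLogger(__name__)

#: Named ERG feature sets used throughout the analysis.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "phnr_only": ("phnr2_uV",),
    "all_markers": ("a_uV", "b_uV", "i_uV", "phnr1_uV", "phnr2_uV"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A model to be fit on a cohort table: family plus feature columns.

    ``features`` may be a named set ("phnr_only"/"all_markers") or an
    explicit tuple of column names.
    """

    family: Literal["linear", "mars"]
    features: tuple[str, ...] | str
    k_folds: int = 10
    max_terms: int = 40
    grouped_cv: bool = True

    def feature_columns(self) -> tuple[str, ...]:
        if isinstance(self.features, str):
            return FEATURE_SETS[self.features]
        return tuple(self.features)


def fit_spec(
    spec: ModelSpec,
    data: pd.DataFrame,
    outcome: str = "ergc",
    group_col: str = "individual_id",
    seed: int = 0,
):
    """Fit a model spec on a cohort table with its full tuning procedure."""
    cols = list(spec.feature_columns())
    X = data[cols]
    y = data[outcome].to_numpy(dtype=float)
    groups = data[group_col].to_numpy() if spec.grouped_cv else None
    if spec.family == "linear":
        return cv_linear(X, y, groups=groups, k=spec.k_folds, seed=seed)
    return cv_tune(
        X, y, groups=groups, k=spec.k_folds, max_terms=spec.max_terms, seed=seed
    )


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a one-sided cluster-bootstrap R² comparison.

    ``p_value`` is the fraction of resamples with delta = R²_b − R²_a
    less than or equal to zero, testing the alternative "model b
    predicts better than model a"; ties count toward the null.
    """

    r2_a: float
    r2_b: float
    delta: float
    p_value: float
    n_resamples: int
    seed: int
    n_redrawn: int = 0


def _resample_rows(
    rng: np.random.Generator, data: pd.DataFrame, row_blocks: list[np.ndarray]
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw individuals with replacement; returns stacked rows plus a
    draw-index group label (each draw is its own cluster)."""
    draws = rng.integers(0, len(row_blocks), size=len(row_blocks))
    parts = [row_blocks[j] for j in draws]
    draw_idx = np.repeat(np.arange(len(draws)), [len(p) for p in parts])
    return data.iloc[np.concatenate(parts)].reset_index(drop=True), draw_idx


def _score_spec(
    spec: ModelSpec,
    rows: pd.DataFrame,
    draw_idx: np.ndarray,
    fitted,
    outcome: str,
    score: str,
    retune: bool,
    seed: int,
) -> float:
    """R² of one spec on one bootstrap replicate."""
    cols = list(spec.feature_columns())
    X = rows[cols]
    y = rows[outcome].to_numpy(dtype=float)
    if score == "cv":
        groups = draw_idx if spec.grouped_cv else None
        k = min(spec.k_folds, len(np.unique(draw_idx)))
        if spec.family == "linear":
            return cv_linear(X, y, groups=groups, k=k, seed=seed).cv_r2
        return cv_tune(X, y, groups=groups, k=k, max_terms=spec.max_terms, seed=seed).cv_r2
    if retune:
        groups = draw_idx if spec.grouped_cv else None
        k = min(spec.k_folds, len(np.unique(draw_idx)))
        if spec.family == "linear":
            m = fit_linear(X, y)
        else:
            m = cv_tune(X, y, groups=groups, k=k, max_terms=spec.max_terms, seed=seed)
        return m.score(X, y)
    # apparent R^2: re-estimate coefficients of the tuned structure on the replicate
    if spec.family == "linear":
        m = fit_linear(X, y)
        return m.score(X, y)
    m = _refit_terms(list(fitted.terms), X, y, cols, spec.max_terms)
    return m.score(X, y)


def cluster_bootstrap_compare(
    spec_a: ModelSpec,
    spec_b: ModelSpec,
    data: pd.DataFrame,
    n_resamples: int = 1000,
    seed: int = 0,
    outcome: str = "ergc",
    group_col: str = "individual_id",
    score: Literal["apparent", "cv"] = "apparent",
    retune: bool = False,
    max_redraw_fraction: float = 0.10,
    fitted: tuple | None = None,
) -> ComparisonResult:
    """Compare two model specs by individual-level cluster bootstrap.

    Both specs are first fit with their full tuning procedure on the
    original cohort. For each of ``n_resamples`` replicates,
    individuals are drawn with replacement (all their eyes enter), both
    models are re-estimated on the replicate — by default re-fitting
    the coefficients of the tuned structures and scoring apparent R²;
    ``retune=True`` repeats the full tuning per replicate and
    ``score="cv"`` scores by within-replicate cross-validation — and
    the difference in R² is recorded. The one-sided p-value is the
    fraction of replicates with delta <= 0 (alternative: b better
    than a).

    Degenerate replicates (constant outcome, or too few rows to fit)
    are redrawn and logged; more than ``max_redraw_fraction`` redraws
    raises :class:`BootstrapInstabilityError`. ``fitted`` may supply
    the two already-tuned models to skip the initial fits.

    Note: apparent R² of nested feature sets is biased upward for the
    larger set; for nested comparisons under a near-null, prefer
    ``score="cv"``.
    """
    ids = pd.unique(data[group_col])
    if len(ids) < 2:
        raise ValueError("cluster bootstrap needs at least 2 individuals")
    row_blocks = [np.flatnonzero((data[group_col] == i).to_numpy()) for i in ids]
    if fitted is not None:
        fitted_a, fitted_b = fitted
    else:
        fitted_a = fit_spec(spec_a, data, outcome, group_col, seed)
        fitted_b = fit_spec(spec_b, data, outcome, group_col, seed)
    cols_a = list(spec_a.feature_columns())
    r2_a = fitted_a.score(data[cols_a], data[outcome].to_numpy(dtype=float))
    cols_b = list(spec_b.feature_columns())
    r2_b = fitted_b.score(data[cols_b], data[outcome].to_numpy(dtype=float))

    rng = np.random.default_rng(seed)
    min_rows = max(len(cols_a), len(cols_b)) + 2
    deltas = np.empty(n_resamples)
    n_redrawn = 0
    max_redraws = max(1, int(np.ceil(max_redraw_fraction * n_resamples)))
    for i in range(n_resamples):
        while True:
            rows, draw_idx = _resample_rows(rng, data, row_blocks)
            y = rows[outcome].to_numpy(dtype=float)
            if len(rows) >= min_rows and np.ptp(y) > 0 and len(np.unique(draw_idx)) >= 2:
                break
            n_redrawn += 1
            logger.debug("degenerate bootstrap replicate redrawn (%d so far)", n_redrawn)
            if n_redrawn > max_redraws:
                raise BootstrapInstabilityError(
                    f"more than {max_redraws} degenerate replicates redrawn"
                )
        ra = _score_spec(spec_a, rows, draw_idx, fitted_a, outcome, score, retune, seed)
        rb = _score_spec(spec_b, rows, draw_idx, fitted_b, outcome, score, retune, seed)
        deltas[i] = rb - ra

    p = float(np.mean(deltas <= 0.0))
    return ComparisonResult(
        r2_a=float(r2_a),
        r2_b=float(r2_b),
        delta=float(r2_b - r2_a),
        p_value=p,
        n_resamples=n_resamples,
        seed=seed,
        n_redrawn=n_redrawn,
    )


@dataclass(frozen=True)
class ICCResult:
    """One-way cluster-sampling intraclass correlation."""

    icc: float
    n_clusters: int
    cluster_sizes: tuple[int, ...]


def icc_lohr(values: Sequence[float], clusters: Sequence) -> ICCResult:
    """ANOVA-form intraclass correlation for cluster samples.

    ICC = 1 − M/(M−1) · SSW/SSTO, where M is the mean cluster size
    (observations per cluster), SSW the within-cluster sum of squares
    and SSTO the total sum of squares about the grand mean. Size-1
    clusters contribute nothing to SSW but count toward M and SSTO.

    Raises
    ------
    UndefinedICCError
        If fewer than 2 clusters have 2 or more members.
    """
    values = np.asarray(values, dtype=float)
    clusters = np.asarray(clusters)
    ids = pd.unique(clusters)
    sizes = []
    ssw = 0.0
    n_multi = 0
    for cid in ids:
        v = values[clusters == cid]
        sizes.append(len(v))
        if len(v) >= 2:
            n_multi += 1
            ssw += float(np.sum((v - v.mean()) ** 2))
    if n_multi < 2:
        raise UndefinedICCError("need at least 2 clusters of size >= 2")
    M = len(values) / len(ids)
    ssto = float(np.sum((values - values.mean()) ** 2))
    if ssto == 0.0:
        raise UndefinedICCError("all values identical; ICC undefined")
    icc = 1.0 - (M / (M - 1.0)) * ssw / ssto
    return ICCResult(icc=float(icc), n_clusters=len(ids), cluster_sizes=tuple(sizes))


def effective_sample_size(n_eyes: int, n_individuals: int, icc: float) -> float:
    """Design-effect effective sample size:
    n_eff = n_eyes / (1 + (m̄ − 1) icc) with m̄ = n_eyes / n_individuals."""
    m_bar = n_eyes / n_individuals
    return n_eyes / (1.0 + (m_bar - 1.0) * icc)
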
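"""Linear and degree-1 multivariate adaptive regression spline (MARS) models.

MARS represents the outcome as an intercept plus a sum of hinge
functions max(0, x - t) / max(0, t - x), which lets each ERG feature's
contribution bend or saturate without interaction terms. The fit is the
classic two-stage procedure: a greedy forward pass that adds reflected
hinge pairs at observed-data knots to minimize residual sum of squares,
and a backward pruning pass driven by generalized cross-validation
(GCV). Final model size is tuned by (optionally group-aware) k-fold
cross-validation, mirroring how such models are tuned in practice with
degree fixed at 1 and the forward pass capped at ``max_terms`` basis
functions.

No third-party MARS implementation is used; the forward/backward passes
here are the package's own.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CollinearityError,
    FoldError,
    InsufficientDataError,
)

Direction = Literal["+", "-"]


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Proportion of variance explained, 1 - SS_res/SS_tot.

    Defined as 0 when y is constant (SS_tot = 0), so that model
    comparisons on degenerate outcomes stay well defined.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass(frozen=True)
class HingeTerm:
    """One truncated-linear basis function: coefficient * max(0, +/-(x - knot)).

    ``direction`` "+" is max(0, x - knot) (active above the knot), "-"
    is max(0, knot - x) (active below it).
    """

    variable: str
    knot: float
    direction: Direction
    coefficient: float = 0.0

    def basis(self, x: np.ndarray) -> np.ndarray:
        if self.direction == "+":
            return np.maximum(0.0, x - self.knot)
        return np.maximum(0.0, self.knot - x)


@dataclass
class MARSModel:
    """A fitted degree-1 MARS model: intercept plus hinge terms."""

    intercept: float
    terms: list[HingeTerm]
    feature_names: list[str]
    max_terms: int = 40
    degree: int = 1
    gcv: float = float("nan")
    cv_rmse: float | None = None
    cv_r2: float | None = None

    @property
    def n_knots(self) -> int:
        return len({(t.variable, t.knot) for t in self.terms})

    def basis_matrix(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(X))]
        for t in self.terms:
            cols.append(t.basis(X[t.variable].to_numpy(dtype=float)))
        return np.column_stack(cols)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        coef = np.concatenate([[self.intercept], [t.coefficient for t in self.terms]])
        return self.basis_matrix(X) @ coef

    def score(self, X: pd.DataFrame, y: np.ndarray) -> float:
        return r_squared(y, self.predict(X))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "terms": [
                {
                    "variable": t.variable,
                    "knot": t.knot,
                    "direction": t.direction,
                    "coefficient": t.coefficient,
                }
                for t in self.terms
            ],
            "feature_names": list(self.feature_names),
            "max_terms": self.max_terms,
            "degree": self.degree,
            "gcv": self.gcv,
            "cv_rmse": self.cv_rmse,
            "cv_r2": self.cv_r2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MARSModel":
        return cls(
            intercept=d["intercept"],
            terms=[
                HingeTerm(t["variable"], t["knot"], t["direction"], t["coefficient"])
                for t in d["terms"]
            ],
            feature_names=list(d["feature_names"]),
            max_terms=d.get("max_terms", 40),
            degree=d.get("degree", 1),
            gcv=d.get("gcv", float("nan")),
            cv_rmse=d.get("cv_rmse"),
            cv_r2=d.get("cv_r2"),
        )


@dataclass
class LinearModel:
    """Ordinary least-squares linear model over named features."""

    intercept: float
    coefficients: dict[str, float]
    feature_names: list[str]
    cv_rmse: float | None = None
    cv_r2: float | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.intercept)
        for name, c in self.coefficients.items():
            out = out + c * X[name].to_numpy(dtype=float)
        return out

    def score(self, X: pd.DataFrame, y: np.ndarray) -> float:
        return r_squared(y, self.predict(X))

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "feature_names": list(self.feature_names),
            "cv_rmse": self.cv_rmse,
            "cv_r2": self.cv_r2,
        }


def fit_linear(X: pd.DataFrame, y: np.ndarray) -> LinearModel:
    """OLS fit of y on the columns of X plus an intercept.

    Raises
    ------
    InsufficientDataError
        Fewer rows than features + 2.
    CollinearityError
        Rank-deficient design (after excluding the degenerate
        constant-y case, which yields a zero-slope model).
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise InsufficientDataError(f"{n} rows cannot identify {p} slopes plus intercept")
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.ptp(y) == 0.0:
        return LinearModel(float(y[0]), {c: 0.0 for c in X.columns}, list(X.columns))
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise CollinearityError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(float(coef[0]), dict(zip(X.columns, coef[1:])), list(X.columns))


def _ols_refit(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients and RSS for a basis matrix."""
    coef, res, rank, _ = np.linalg.lstsq(B, y, rcond=None)
    rss = float(np.sum((y - B @ coef) ** 2))
    return coef, rss


def _best_pair_for_variable(
    x: np.ndarray, knots: np.ndarray, Q: np.ndarray, r: np.ndarray
) -> tuple[float, float]:
    """RSS reduction of the best reflected hinge pair on one variable.

    Candidate columns are residualized against the current basis (via
    its orthonormal Q), then the 2x2 normal equations for each pair are
    solved in closed form. Returns (best_reduction, best_knot); ties in
    reduction break toward the smaller knot because knots are scanned
    in increasing order with strict improvement.
    """
    Hp = np.maximum(0.0, x[:, None] - knots[None, :])
    Hm = np.maximum(0.0, knots[None, :] - x[:, None])
    # residualize against current basis
    Hp = Hp - Q @ (Q.T @ Hp)
    Hm = Hm - Q @ (Q.T @ Hm)
    g11 = np.einsum("ij,ij->j", Hp, Hp)
    g22 = np.einsum("ij,ij->j", Hm, Hm)
    g12 = np.einsum("ij,ij->j", Hp, Hm)
    b1 = Hp.T @ r
    b2 = Hm.T @ r
    det = g11 * g22 - g12 * g12
    scale = np.maximum(g11, g22)
    best_red, best_knot = -np.inf, float("nan")
    for j in range(len(knots)):
        if det[j] > 1e-10 * max(scale[j] ** 2, 1e-300):
            # both columns informative: solve the 2x2 system
            red = (g22[j] * b1[j] ** 2 - 2 * g12[j] * b1[j] * b2[j] + g11[j] * b2[j] ** 2) / det[j]
        elif g11[j] > 1e-12:
            red = b1[j] ** 2 / g11[j]
        elif g22[j] > 1e-12:
            red = b2[j] ** 2 / g22[j]
        else:
            continue
        if red > best_red:
            best_red, best_knot = red, float(knots[j])
    return best_red, best_knot


def mars_forward(
    X: pd.DataFrame,
    y: np.ndarray,
    max_terms: int = 40,
    rss_tol_factor: float = 1e-10,
) -> MARSModel:
    """Greedy forward pass: add the reflected hinge pair that most
    reduces the residual sum of squares, at candidate knots taken from
    the observed data values of each variable.

    Stops when ``max_terms`` hinge terms are reached, when no pair
    improves RSS by more than ``rss_tol_factor * var(y)``, or when the
    fit is exact. ``max_terms`` caps hinge basis functions (the
    intercept is not counted), so ``max_terms=2`` allows exactly one
    reflected pair — a single-knot segmented regression.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 observations.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise InsufficientDataError("MARS forward pass needs at least 4 observations")
    if max_terms < 2:
        raise ValueError("max_terms must be at least 2 (one reflected pair)")
    feature_names = list(X.columns)
    Xv = {c: X[c].to_numpy(dtype=float) for c in feature_names}

    terms: list[HingeTerm] = []
    B = np.ones((n, 1))
    coef, rss = _ols_refit(B, y)
    var_y = float(np.var(y))
    tol = rss_tol_factor * var_y if var_y > 0 else 0.0

    while len(terms) + 2 <= max_terms:
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        best = None  # (reduction, variable, knot)
        for name in feature_names:
            x = Xv[name]
            knots = np.unique(x)
            red, knot = _best_pair_for_variable(x, knots, Q, r)
            if np.isfinite(red) and (best is None or red > best[0] * (1 + 1e-12)):
                # strict scan order => ties keep the earlier variable/smaller knot
                if best is None or red > best[0]:
                    best = (red, name, knot)
        if best is None or best[0] <= max(tol, 0.0) or rss <= 1e-12 * max(var_y * n, 1.0):
            break
        _, name, knot = best
        x = Xv[name]
        n_before = B.shape[1]
        # drop pair members that add nothing to the span (knot at a data extreme)
        for t in (HingeTerm(name, knot, "+"), HingeTerm(name, knot, "-")):
            B_try = np.column_stack([B, t.basis(x)])
            if np.linalg.matrix_rank(B_try) > B.shape[1]:
                B = B_try
                terms.append(t)
        if B.shape[1] == n_before:
            break
        new_coef, new_rss = _ols_refit(B, y)
        if rss - new_rss <= max(tol, 0.0):
            B = B[:, :n_before]
            del terms[n_before - 1 :]
            coef, _ = _ols_refit(B, y)
            break
        coef, rss = new_coef, new_rss
        if rss <= tol:
            break

    model = MARSModel(
        intercept=float(coef[0]),
        terms=[replace(t, coefficient=float(c)) for t, c in zip(terms, coef[1:])],
        feature_names=feature_names,
        max_terms=max_terms,
    )
    model.gcv = gcv_score(model, X, y)
    return model


def gcv_score(
    model: MARSModel, X: pd.DataFrame, y: np.ndarray, penalty: float = 2.0
) -> float:
    """Generalized cross-validation score of a MARS model.

    GCV = (RSS/n) / (1 - C/n)^2 with effective complexity
    C = (number of basis functions including the intercept)
        + penalty * (number of distinct knots); penalty defaults to 2
    for degree-1 models. Returns inf when C >= n.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    C = (len(model.terms) + 1) + penalty * model.n_knots
    if C >= n:
        return float("inf")
    rss = float(np.sum((y - model.predict(X)) ** 2))
    return (rss / n) / (1.0 - C / n) ** 2


def _refit_terms(
    terms: list[HingeTerm], X: pd.DataFrame, y: np.ndarray, feature_names: list[str],
    max_terms: int,
) -> MARSModel:
    """Refit OLS coefficients for a fixed set of hinge terms."""
    n = len(y)
    B = np.ones((n, 1))
    for t in terms:
        B = np.column_stack([B, t.basis(X[t.variable].to_numpy(dtype=float))])
    coef, _ = _ols_refit(B, y)
    model = MARSModel(
        intercept=float(coef[0]),
        terms=[replace(t, coefficient=float(c)) for t, c in zip(terms, coef[1:])],
        feature_names=feature_names,
        max_terms=max_terms,
    )
    return model


def prune_path(
    model: MARSModel, X: pd.DataFrame, y: np.ndarray, penalty: float = 2.0
) -> list[MARSModel]:
    """Backward-elimination path: refitted submodels of every size.

    Starting from the full forward-pass model, repeatedly delete the
    hinge term whose removal gives the lowest GCV, down to the
    intercept-only model. Returns the path indexed by number of hinge
    terms (element k has k terms), each with its GCV populated.
    """
    y = np.asarray(y, dtype=float)
    current = list(model.terms)
    path: dict[int, MARSModel] = {}
    m = _refit_terms(current, X, y, model.feature_names, model.max_terms)
    m.gcv = gcv_score(m, X, y, penalty)
    path[len(current)] = m
    while current:
        best = None  # (gcv, rss, sub, model); rss breaks ties when gcv is inf
        for j in range(len(current)):
            sub = current[:j] + current[j + 1 :]
            cand = _refit_terms(sub, X, y, model.feature_names, model.max_terms)
            g = gcv_score(cand, X, y, penalty)
            rss = float(np.sum((y - cand.predict(X)) ** 2))
            if best is None or (g, rss) < (best[0], best[1]):
                best = (g, rss, sub, cand)
        current = best[2]
        best[3].gcv = best[0]
        path[len(current)] = best[3]
    return [path[k] for k in sorted(path)]


def mars_prune(
    model: MARSModel, X: pd.DataFrame, y: np.ndarray, penalty: float = 2.0
) -> MARSModel:
    """Backward pruning: return the submodel on the elimination path
    with the best (lowest) GCV. Pruning an intercept-only model is a
    no-op; the returned GCV never exceeds the unpruned model's."""
    path = prune_path(model, X, y, penalty)
    return min(path, key=lambda m: m.gcv)


def make_folds(
    n: int,
    k: int,
    rng: np.random.Generator,
    groups: Sequence | None = None,
) -> list[np.ndarray]:
    """Index arrays for k-fold CV; with ``groups``, whole groups (e.g.
    both eyes of one individual) are assigned to the same fold."""
    if groups is None:
        idx = rng.permutation(n)
        return [idx[i::k] for i in range(k)]
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if k > len(uniq):
        raise FoldError(f"{k} folds requested but only {len(uniq)} groups present")
    order = rng.permutation(len(uniq))
    fold_of_group = {uniq[g]: i % k for i, g in enumerate(order)}
    assign = np.array([fold_of_group[g] for g in groups])
    return [np.flatnonzero(assign == i) for i in range(k)]


def cv_tune(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: Sequence | None = None,
    k: int = 10,
    max_terms: int = 40,
    penalty: float = 2.0,
    seed: int = 0,
    selection: Literal["1se", "best"] = "1se",
) -> MARSModel:
    """Tune MARS model size by k-fold cross-validation and refit.

    For each fold, a forward pass and pruning path are computed on the
    training split and out-of-fold squared error is recorded for every
    model size (number of retained hinge terms). With
    ``selection="1se"`` (default) the smallest size whose mean CV RMSE
    is within one standard error of the minimum is chosen — the usual
    parsimony rule for flat tuning curves; ``"best"`` takes the strict
    minimizer (ties toward the smaller model). The forward/pruning path
    is then recomputed on the full data and the submodel of the chosen
    size refit, with ``cv_rmse``/``cv_r2`` diagnostics attached.

    ``groups`` (individual IDs) keeps paired eyes in the same fold;
    pass ``None`` for plain (ungrouped) tenfold CV.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise FoldError("k must be at least 2")
    if n < k:
        raise FoldError(f"{n} observations cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    folds = make_folds(n, k, rng, groups)

    max_size = max_terms
    sse = np.zeros(max_size + 1)
    counts = np.zeros(max_size + 1, dtype=int)
    fold_mse: list[np.ndarray] = []
    oof_pred = {s: np.full(n, np.nan) for s in range(max_size + 1)}
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        X_tr, y_tr = X.iloc[mask.nonzero()[0]], y[mask]
        X_te, y_te = X.iloc[test_idx], y[test_idx]
        if np.ptp(y_tr) == 0:
            path = [_refit_terms([], X_tr, y_tr, list(X.columns), max_terms)]
        else:
            full = mars_forward(X_tr, y_tr, max_terms)
            path = prune_path(full, X_tr, y_tr, penalty)
        by_size = {len(m.terms): m for m in path}
        largest = max(by_size)
        this_fold = np.empty(max_size + 1)
        for s in range(max_size + 1):
            m = by_size[min(s, largest)]
            pred = m.predict(X_te)
            fold_sse = float(np.sum((y_te - pred) ** 2))
            sse[s] += fold_sse
            counts[s] += len(test_idx)
            this_fold[s] = fold_sse / len(test_idx)
            oof_pred[s][test_idx] = pred
        fold_mse.append(np.sqrt(this_fold))

    rmse = np.sqrt(sse / np.maximum(counts, 1))
    argmin = int(np.argmin(np.round(rmse, 12)))  # ties -> smaller size
    if selection == "1se" and fold_mse:
        per_fold = np.vstack(fold_mse)  # folds x sizes, fold-level RMSE
        se = float(np.std(per_fold[:, argmin], ddof=1) / np.sqrt(len(per_fold)))
        best_size = int(np.argmax(rmse <= rmse[argmin] + se))  # smallest within 1 SE
    else:
        best_size = argmin

    if np.ptp(y) == 0:
        final = _refit_terms([], X, y, list(X.columns), max_terms)
    else:
        full = mars_forward(X, y, max_terms)
        path = prune_path(full, X, y, penalty)
        by_size = {len(m.terms): m for m in path}
        final = by_size[min(best_size, max(by_size))]
    final.gcv = gcv_score(final, X, y, penalty)
    final.cv_rmse = float(rmse[best_size])
    final.cv_r2 = r_squared(y, oof_pred[best_size]) if counts[best_size] == n else None
    return final


def cv_linear(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: Sequence | None = None,
    k: int = 10,
    seed: int = 0,
) -> LinearModel:
    """OLS fit with k-fold cross-validated RMSE/R² diagnostics attached."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    folds = make_folds(n, k, rng, groups)
    oof = np.full(n, np.nan)
    for test_idx in folds:
        if len(test_idx) == 0:
            continue
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        m = fit_linear(X.iloc[mask.nonzero()[0]], y[mask])
        oof[test_idx] = m.predict(X.iloc[test_idx])
    model = fit_linear(X, y)
    model.cv_rmse = float(np.sqrt(np.nanmean((y - oof) ** 2)))
    model.cv_r2 = r_squared(y, oof)
    return model
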
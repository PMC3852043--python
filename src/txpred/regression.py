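"""Jackknifed greedy-selection regression.

The inference scheme: the gene universe is partitioned into three
near-equal terciles — train, test, validation — independently 100 times.
Within each replicate a regressor is grown by greedy forward selection:
every candidate feature is tried in turn, the one giving the highest
training correlation joins the model, and growth stops as soon as the
test-tercile correlation fails to improve.  The finished model is scored
once on the validation tercile.  Across the replicate family the reported
performance is the median validation correlation and every feature gets a
prevalence score: the number of replicates (0-100) whose predictor includes
it.

Features whose computation itself depends on expression (scheme B) are
recomputed inside each replicate from that replicate's train tercile only;
the leakage guard asserts held-out genes never reach that computation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mars import MarsModel, fit_mars

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TercileSplit:
    replicate: int
    train: tuple[str, ...]
    test: tuple[str, ...]
    validation: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.test), set(self.validation)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("tercile sets must be disjoint")


def make_splits(gene_ids: Sequence[str], n_replicates: int = 100,
                seed: int = 0) -> list[TercileSplit]:
    """Independent uniform random tercile partitions, reproducible by seed.

    Sizes are balanced to within one gene; when n is not divisible by 3 the
    remainder goes to train first, then test.
    """
    ids = list(gene_ids)
    n = len(ids)
    if n < 9:
        raise ValueError(f"need at least 9 genes for terciles, got {n}")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if r < rem else 0) for r in range(3)]
    rng = np.random.default_rng(seed)
    splits = []
    for rep in range(n_replicates):
        perm = rng.permutation(n)
        a, b = sizes[0], sizes[0] + sizes[1]
        splits.append(TercileSplit(
            replicate=rep,
            train=tuple(ids[i] for i in perm[:a]),
            test=tuple(ids[i] for i in perm[a:b]),
            validation=tuple(ids[i] for i in perm[b:]),
        ))
    return splits


# ---------------------------------------------------------------------------
# Models and scoring
# ---------------------------------------------------------------------------


@dataclass
class LinearModel:
    coef: np.ndarray
    intercept: float
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError("feature-count mismatch")
        return X @ self.coef + self.intercept


def fit_linear(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Ordinary least squares with intercept, minimum-norm on singular designs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values passed to fit_linear")
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        log.warning("singular design (rank %d < %d); minimum-norm solution",
                    rank, p + 1)
    return LinearModel(coef=coef[1:], intercept=float(coef[0]), n_features=p)


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation, NaN (with a warning) when undefined."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        log.warning("fewer than 3 complete pairs; correlation undefined")
        return np.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        log.warning("constant vector; correlation undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def score(predictions: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Correlation between predictions and a target.

    ``log_pearson`` log-transforms the (positive) target first — the default
    treatment of expression measurements elsewhere in the package;
    ``pearson`` and ``spearman`` act on the values as given.
    """
    y = np.asarray(y, dtype=float)
    if method == "log_pearson":
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.where(y > 0, np.log(y), np.nan)
        method = "pearson"
    if method == "pearson":
        return pearson(predictions, y)
    if method == "spearman":
        ok = np.isfinite(predictions) & np.isfinite(y)
        if ok.sum() < 3:
            log.warning("fewer than 3 complete pairs; correlation undefined")
            return np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = stats.spearmanr(predictions[ok], y[ok]).statistic
        return float(rho) if np.isfinite(rho) else np.nan
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Greedy forward selection
# ---------------------------------------------------------------------------


@dataclass
class Predictor:
    features: list[str]
    model_kind: str
    model: LinearModel | MarsModel
    replicate: int
    train_corr: float
    test_corr: float
    validation_corr: float
    # train-tercile standardization applied before the model
    means: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)
    stds: np.ndarray = field(default_factory=lambda: np.ones(0), repr=False)

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        Z = (X[self.features].to_numpy(dtype=float) - self.means) / self.stds
        return self.model.predict(Z)

    def coefficients(self) -> dict[str, float]:
        if isinstance(self.model, LinearModel):
            return dict(zip(self.features, self.model.coef))
        agg: dict[str, float] = {f: 0.0 for f in self.features}
        for term, c in zip(self.model.terms, self.model.coef):
            for var, _, sign in term:
                agg[self.features[var]] += sign * c
        return agg


def _fit(model_kind: str, X: np.ndarray, y: np.ndarray,
         mars_params: dict | None) -> LinearModel | MarsModel:
    if model_kind == "linear":
        return fit_linear(X, y)
    if model_kind == "mars":
        return fit_mars(X, y, **(mars_params or {}))
    raise ValueError(f"unknown model kind {model_kind!r}")


def _linear_argmax(Q: np.ndarray | None, Xc: np.ndarray, yc: np.ndarray,
                   alive: np.ndarray) -> int:
    """Fastest-improving candidate under OLS.

    Adding the column with the largest squared partial correlation with the
    current residual maximizes the refit training correlation, because with
    an intercept that correlation is sqrt(R^2) and the R^2 increment is the
    squared partial correlation of the residualized pair.  Equivalent to
    refitting every candidate (asserted against the naive path in tests).
    """
    r = yc - Q @ (Q.T @ yc) if Q is not None else yc.copy()
    C = Xc - Q @ (Q.T @ Xc) if Q is not None else Xc
    num = (C * r[:, None]).sum(axis=0) ** 2
    den = (C * C).sum(axis=0)
    scores = np.where(alive & (den > 1e-12 * len(yc)), num / np.maximum(den, 1e-300),
                      -np.inf)
    j = int(np.argmax(scores))
    return j if np.isfinite(scores[j]) else -1


def greedy_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    candidate_names: Sequence[str],
    model_kind: str = "linear",
    max_features: int = 30,
    epsilon: float = 0.0,
    mars_params: dict | None = None,
    select_on: str = "train",
) -> tuple[list[str], LinearModel | MarsModel, float, float]:
    """Grow a regressor by greedy forward selection with test-set stopping.

    At each step every unselected candidate is scored by the training
    correlation of the refit model (``select_on="test"`` switches the
    selection criterion to the test correlation, for sensitivity analysis);
    the argmax joins the model, ties breaking toward the earlier catalogue
    position.  Growth stops when the grown model's test correlation fails to
    exceed the previous one by ``epsilon``, or at ``max_features``.  At
    least one feature is always retained.

    Returns (ordered selected names, fitted model, train corr, test corr).
    """
    names = list(candidate_names)
    p = len(names)
    alive = np.ones(p, dtype=bool)
    selected: list[int] = []
    yc = y_train - y_train.mean()
    Xc = X_train - X_train.mean(axis=0)
    Q: np.ndarray | None = None
    best_model: LinearModel | MarsModel | None = None
    prev_test = -np.inf
    prev_train = np.nan
    fast = model_kind == "linear" and select_on == "train"

    while alive.any() and len(selected) < max_features:
        if fast:
            j = _linear_argmax(Q, Xc, yc, alive)
            if j < 0:
                break
        else:
            best_j, best_s = -1, -np.inf
            for cand in np.flatnonzero(alive):
                cols = selected + [int(cand)]
                m = _fit(model_kind, X_train[:, cols], y_train, mars_params)
                crit = (X_test, y_test) if select_on == "test" else (X_train, y_train)
                s = pearson(m.predict(crit[0][:, cols]), crit[1])
                if np.isfinite(s) and s > best_s + 1e-12:
                    best_j, best_s = int(cand), s
            if best_j < 0:
                break
            j = best_j
        trial = selected + [j]
        model = _fit(model_kind, X_train[:, trial], y_train, mars_params)
        test_corr = pearson(model.predict(X_test[:, trial]), y_test)
        if not np.isfinite(test_corr):
            test_corr = -np.inf
        if len(selected) >= 1 and test_corr <= prev_test + epsilon:
            break  # revert the trial addition
        selected.append(j)
        alive[j] = False
        best_model = model
        prev_test = test_corr
        prev_train = pearson(model.predict(X_train[:, selected]), y_train)
        if fast:
            # extend the orthonormal basis with the new residualized column
            v = Xc[:, j].copy()
            if Q is not None:
                v -= Q @ (Q.T @ v)
            nv = np.linalg.norm(v)
            if nv > 1e-12:
                v = (v / nv)[:, None]
                Q = v if Q is None else np.hstack([Q, v])

    if best_model is None:
        # degenerate inputs: fall back to the single least-bad feature
        j = 0
        selected = [j]
        best_model = _fit(model_kind, X_train[:, selected], y_train, mars_params)
        prev_test = pearson(best_model.predict(X_test[:, selected]), y_test)
        prev_train = pearson(best_model.predict(X_train[:, selected]), y_train)
    return ([names[j] for j in selected], best_model, float(prev_train),
            float(prev_test) if np.isfinite(prev_test) else np.nan)


# ---------------------------------------------------------------------------
# Predictor families
# ---------------------------------------------------------------------------


@dataclass
class PredictorFamily:
    target: str
    scope: str
    scheme: str
    model_kind: str
    predictors: list[Predictor]
    median: Predictor
    prevalence: dict[str, int]

    @property
    def median_validation_corr(self) -> float:
        return self.median.validation_corr

    def validation_corrs(self) -> list[float]:
        return [p.validation_corr for p in self.predictors]

    def to_report(self) -> dict:
        return {
            "target": self.target,
            "scope": self.scope,
            "scheme": self.scheme,
            "model_kind": self.model_kind,
            "n_replicates": len(self.predictors),
            "median_validation_corr": self.median_validation_corr,
            "validation_corrs": self.validation_corrs(),
            "median_features": self.median.features,
            "median_coefficients": self.median.coefficients(),
            "mean_n_features": float(np.mean([len(p.features)
                                              for p in self.predictors])),
            "prevalence": {k: v for k, v in sorted(
                self.prevalence.items(), key=lambda kv: -kv[1]) if v > 0},
        }


SchemeBHook = Callable[[tuple[str, ...]], pd.DataFrame]


def build_family(
    features: pd.DataFrame,
    y: pd.Series,
    candidates: Sequence[str],
    target: str = "y",
    scope: str = "TRANSCRIPT",
    scheme: str = "A",
    model_kind: str = "linear",
    n_replicates: int = 100,
    seed: int = 0,
    max_features: int = 30,
    epsilon: float = 0.0,
    mars_params: dict | None = None,
    select_on: str = "train",
    scheme_b_hook: SchemeBHook | None = None,
) -> PredictorFamily:
    """Fit one jackknife family of predictors.

    ``features`` is the genes x features table (scheme-A values for any
    expression-dependent columns); ``y`` the already-transformed target.
    Genes with a missing target are dropped up front.  Under scheme B,
    ``scheme_b_hook(train_ids)`` must return recomputed expression-dependent
    feature columns (indexed by all genes) inferred from the given train ids
    only; they overwrite the corresponding columns for that replicate.
    """
    y = y.reindex(features.index)
    keep = y.notna()
    if keep.sum() < 9:
        raise ValueError("fewer than 9 genes with a measured target")
    X_all = features.loc[keep]
    y_all = y.loc[keep]
    ids = list(X_all.index)
    splits = make_splits(ids, n_replicates=n_replicates, seed=seed)

    candidates = [c for c in candidates if c in X_all.columns]
    predictors: list[Predictor] = []
    for split in splits:
        try:
            predictors.append(_fit_replicate(
                X_all, y_all, candidates, split, model_kind, max_features,
                epsilon, mars_params, select_on, scheme, scheme_b_hook,
            ))
        except Exception as exc:  # noqa: BLE001 - enrich and re-raise
            raise RuntimeError(
                f"replicate {split.replicate} failed for target={target} "
                f"scope={scope}: {exc}"
            ) from exc

    order = sorted(
        range(len(predictors)),
        key=lambda i: (np.nan_to_num(predictors[i].validation_corr, nan=-2.0), i),
    )
    median = predictors[order[(len(order) - 1) // 2]]
    prevalence: dict[str, int] = {c: 0 for c in candidates}
    for p in predictors:
        for f in p.features:
            prevalence[f] += 1
    return PredictorFamily(
        target=target, scope=scope, scheme=scheme, model_kind=model_kind,
        predictors=predictors, median=median, prevalence=prevalence,
    )


def _fit_replicate(
    X_all: pd.DataFrame,
    y_all: pd.Series,
    candidates: list[str],
    split: TercileSplit,
    model_kind: str,
    max_features: int,
    epsilon: float,
    mars_params: dict | None,
    select_on: str,
    scheme: str,
    scheme_b_hook: SchemeBHook | None,
) -> Predictor:
    held_out = set(split.test) | set(split.validation)
    assert not (set(split.train) & held_out), "tercile leakage"

    X = X_all
    if scheme == "B":
        if scheme_b_hook is None:
            raise ValueError("scheme B requires a scheme_b_hook")
        train_ids = tuple(g for g in split.train if g in X_all.index)
        assert not (set(train_ids) & held_out)
        b_cols = scheme_b_hook(train_ids)
        X = X_all.copy()
        for col in b_cols.columns:
            X[col] = b_cols[col].reindex(X.index)

    tr = [g for g in split.train if g in X.index]
    te = [g for g in split.test if g in X.index]
    va = [g for g in split.validation if g in X.index]

    Xtr = X.loc[tr, candidates].to_numpy(dtype=float)
    means = Xtr.mean(axis=0)
    stds = Xtr.std(axis=0)
    usable = stds > 0
    stds_safe = np.where(usable, stds, 1.0)

    def z(rows: list[str]) -> np.ndarray:
        return (X.loc[rows, candidates].to_numpy(dtype=float) - means) / stds_safe

    names = [c for c, u in zip(candidates, usable) if u]
    cols = np.flatnonzero(usable)
    Ztr, Zte, Zva = z(tr)[:, cols], z(te)[:, cols], z(va)[:, cols]
    ytr = y_all.loc[tr].to_numpy(dtype=float)
    yte = y_all.loc[te].to_numpy(dtype=float)
    yva = y_all.loc[va].to_numpy(dtype=float)

    feats, model, train_corr, test_corr = greedy_select(
        Ztr, ytr, Zte, yte, names, model_kind=model_kind,
        max_features=max_features, epsilon=epsilon, mars_params=mars_params,
        select_on=select_on,
    )
    sel_idx = [candidates.index(f) for f in feats]
    sub = [names.index(f) for f in feats]
    val_corr = pearson(model.predict(Zva[:, sub]), yva)
    return Predictor(
        features=feats, model_kind=model_kind, model=model,
        replicate=split.replicate, train_corr=train_corr,
        test_corr=test_corr, validation_corr=val_corr,
        means=means[sel_idx], stds=stds_safe[sel_idx],
    )
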
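"""Multivariate adaptive regression splines (forward pass + GCV pruning).

The forward pass greedily adds mirrored hinge pairs h+(x) = max(0, x - t),
h-(x) = max(0, t - x) at observed-value knots, optionally multiplied into an
existing basis term (interaction degree capped at 2).  The backward pass
prunes terms by generalized cross-validation,

    GCV(M) = RSS / n / (1 - C(M) / n)^2,   C(M) = M + d (M - 1) / 2,

with d the knot-penalty parameter (default 3).  A mirrored hinge pair spans
any linear trend, so linear ground truth costs MARS essentially nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: One multiplicative factor of a basis term: sign +1 is max(0, x-t),
#: sign -1 is max(0, t-x).
Hinge = tuple[int, float, int]  # (variable index, knot, sign)


def _eval_term(X: np.ndarray, factors: tuple[Hinge, ...]) -> np.ndarray:
    out = np.ones(X.shape[0])
    for var, knot, sign in factors:
        out *= np.maximum(0.0, sign * (X[:, var] - knot))
    return out


@dataclass
class MarsModel:
    terms: list[tuple[Hinge, ...]]  # () is the intercept term
    coef: np.ndarray
    gcv: float
    n_features: int

    def basis(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([_eval_term(X, t) for t in self.terms])

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError("feature-count mismatch")
        return self.basis(X) @ self.coef


def _lstsq_rss(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, _, _, _ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _gcv(rss: float, n: int, n_terms: int, penalty: float) -> float:
    c = n_terms + penalty * (n_terms - 1) / 2.0
    denom = (1.0 - c / n) ** 2
    if denom <= 0:
        return np.inf
    return rss / n / denom


def _knot_candidates(x: np.ndarray, mask: np.ndarray, max_knots: int) -> np.ndarray:
    vals = np.unique(x[mask]) if mask.any() else np.unique(x)
    if len(vals) <= max_knots:
        return vals
    qs = np.linspace(0, 1, max_knots + 2)[1:-1]
    return np.unique(np.quantile(vals, qs))


def fit_mars(
    X: np.ndarray,
    y: np.ndarray,
    max_terms: int = 21,
    gcv_penalty: float = 3.0,
    max_degree: int = 2,
    max_knots: int = 32,
) -> MarsModel:
    """Fit a MARS model; ``max_terms`` counts basis terms incl. intercept."""
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in MARS inputs")
    n, p = X.shape
    terms: list[tuple[Hinge, ...]] = [()]
    B = np.ones((n, 1))
    coef, rss = _lstsq_rss(B, y)
    tol = 1e-10 * max(rss, 1.0)

    # ---- forward pass ----
    while len(terms) + 2 <= max_terms:
        best = None  # (rss, parent_idx, var, knot)
        for pi, parent in enumerate(terms):
            if len(parent) >= max_degree:
                continue
            used = {f[0] for f in parent}
            support = B[:, pi] > 0
            for var in range(p):
                if var in used:
                    continue
                for knot in _knot_candidates(X[:, var], support, max_knots):
                    hp = B[:, pi] * np.maximum(0.0, X[:, var] - knot)
                    hm = B[:, pi] * np.maximum(0.0, knot - X[:, var])
                    if hp.std() == 0 and hm.std() == 0:
                        continue
                    Bc = np.column_stack([B, hp, hm])
                    _, cand_rss = _lstsq_rss(Bc, y)
                    if best is None or cand_rss < best[0] - 1e-12:
                        best = (cand_rss, pi, var, knot)
        if best is None or best[0] >= rss - tol:
            break
        cand_rss, pi, var, knot = best
        terms.append(terms[pi] + ((var, float(knot), 1),))
        terms.append(terms[pi] + ((var, float(knot), -1),))
        B = np.column_stack([_eval_term(X, t) for t in terms])
        coef, rss = _lstsq_rss(B, y)

    # ---- backward pruning by GCV ----
    current = list(range(len(terms)))
    coef_cur, rss_cur = _lstsq_rss(B[:, current], y)
    best_subset = (list(current), coef_cur,
                   _gcv(rss_cur, n, len(current), gcv_penalty))
    while len(current) > 1:
        step_best = None
        for drop in current:
            if drop == 0:  # keep the intercept
                continue
            subset = [i for i in current if i != drop]
            c, r = _lstsq_rss(B[:, subset], y)
            g = _gcv(r, n, len(subset), gcv_penalty)
            if step_best is None or g < step_best[2]:
                step_best = (subset, c, g)
        if step_best is None:
            break
        current = step_best[0]
        if step_best[2] < best_subset[2]:
            best_subset = step_best
    subset, coef_fin, gcv_fin = best_subset
    return MarsModel(
        terms=[terms[i] for i in subset],
        coef=coef_fin,
        gcv=gcv_fin,
        n_features=p,
    )
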
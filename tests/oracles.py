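"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — exhaustive enumeration and repeated
full refits — kept free of any code path they are used to check.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every nested (non-crossing) set of complementary base pairs."""
    pairs_ok = {"GC", "CG", "AT", "TA", "GT", "TG"}

    def rec(lo: int, hi: int):
        if lo >= hi:
            yield []
            return
        # position lo unpaired
        for rest in rec(lo + 1, hi):
            yield rest
        # position lo paired with j
        for j in range(lo + min_loop + 1, hi + 1):
            if seq[lo] + seq[j] in pairs_ok:
                for inner in rec(lo + 1, j - 1):
                    for outer in rec(j + 1, hi):
                        yield [(lo, j)] + inner + outer

    yield from rec(0, len(seq) - 1)


def best_structure_weight(seq: str, weights: dict[str, float],
                          min_loop: int = 3) -> float:
    """Maximum total pair weight over the exhaustively enumerated structures."""
    best = 0.0
    for structure in enumerate_structures(seq, min_loop):
        total = 0.0
        for i, j in structure:
            key = seq[i] + seq[j]
            total += weights.get(key, weights.get(key[::-1], 0.0))
        best = max(best, total)
    return best


def scan_sorfs(orf: str) -> tuple[int, int]:
    """Brute-force shifted-ORF counts (frames 1 and 2)."""
    counts = [0, 0, 0]
    for s in range(1, len(orf) - 2):
        if orf[s : s + 3] != "ATG":
            continue
        frame = s % 3
        if any(orf[q : q + 3] in STOPS
               for q in range(s + 3, len(orf) - 2, 3)):
            counts[frame] += 1
    return counts[1], counts[2]


def scan_uorfs(utr5: str) -> int:
    n = 0
    for s in range(len(utr5) - 2):
        if utr5[s : s + 3] != "ATG":
            continue
        if any(utr5[q : q + 3] in STOPS
               for q in range(s + 3, len(utr5) - 2, 3)):
            n += 1
    return n


def _ols_train_corr(X: np.ndarray, y: np.ndarray, cols: list[int]) -> float:
    A = np.column_stack([np.ones(len(y)), X[:, cols]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = A @ coef
    if fit.std() == 0:
        return -np.inf
    return float(np.corrcoef(fit, y)[0, 1])


def exhaustive_first_two(X: np.ndarray, y: np.ndarray) -> tuple[int, int | None]:
    """Best first feature, then best ordered second, by full OLS refits."""
    p = X.shape[1]
    first = max(range(p), key=lambda j: (_ols_train_corr(X, y, [j]), -j))
    rest = [j for j in range(p) if j != first]
    if not rest:
        return first, None
    second = max(rest, key=lambda j: (_ols_train_corr(X, y, [first, j]), -j))
    return first, second
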
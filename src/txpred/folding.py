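"""Folding-strength and measured-structure (PARS) features.

The default engine is a self-contained weighted base-pair maximization
(Nussinov-style dynamic program) with pair weights GC=3, AU=2, GU=1 and a
minimum hairpin loop of 3 unpaired nucleotides.  The reported score is the
negated total pair weight so that more structure reads as more negative,
matching the sign convention of thermodynamic folding energies; an external
minimum-free-energy provider can be plugged in behind the same signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numba import njit

from .io_formats import TranscriptRecord

_NT = {b: i for i, b in enumerate("ACGT")}

DEFAULT_PAIR_WEIGHTS = {"GC": 3.0, "AT": 2.0, "GT": 1.0}


def _weight_matrix(pair_weights: dict[str, float]) -> np.ndarray:
    m = np.zeros((4, 4))
    for pair, w in pair_weights.items():
        a, b = _NT[pair[0]], _NT[pair[1]]
        m[a, b] = m[b, a] = w
    return m


@njit(cache=False)
def _nussinov_dp(seq: np.ndarray, wm: np.ndarray, min_loop: int) -> np.ndarray:
    n = len(seq)
    dp = np.zeros((n, n))
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i, j - 1]  # j unpaired
            # or j pairs with some k in [i, j - min_loop - 1]
            for k in range(i, j - min_loop):
                w = wm[seq[k], seq[j]]
                if w > 0.0:
                    left = dp[i, k - 1] if k > i else 0.0
                    inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                    cand = left + inner + w
                    if cand > best:
                        best = cand
            dp[i, j] = best
    return dp


def _traceback_pairs(seq: np.ndarray, dp: np.ndarray, wm: np.ndarray,
                     min_loop: int) -> list[tuple[int, int]]:
    """Base pairs of one optimal structure recovered from the DP matrix."""
    n = len(seq)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            w = wm[seq[k], seq[j]]
            if w > 0.0:
                left = dp[i, k - 1] if k > i else 0.0
                inner = dp[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                if dp[i, j] == left + inner + w:
                    pairs.append((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    stack.append((k + 1, j - 1))
                    break
    return pairs


@dataclass
class FoldingEngine:
    """Deterministic folding backend for window-level structure features."""

    backend: str = "basepair_max"
    min_loop: int = 3
    pair_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_WEIGHTS)
    )
    external: Callable[[str], tuple[float, int]] | None = None

    def __post_init__(self) -> None:
        self._wm = _weight_matrix(self.pair_weights)

    def fold(self, seq: str) -> tuple[float, int]:
        return fold_score(seq, self)


def fold_score(seq: str, engine: FoldingEngine) -> tuple[float, int]:
    """(score, n_basepairs) for one sequence window.

    score = -(maximum total pair weight); n_basepairs counts the pairs in
    one optimal traceback.
    """
    if len(seq) < 1:
        raise ValueError("fold_score needs a non-empty sequence")
    if engine.backend == "external_thermodynamic":
        if engine.external is None:
            raise ValueError("external backend requires a provider callable")
        return engine.external(seq)
    idx = np.array([_NT.get(b, 0) for b in seq], dtype=np.int64)
    if len(seq) <= engine.min_loop + 1:
        return 0.0, 0
    dp = _nussinov_dp(idx, engine._wm, engine.min_loop)
    n_pairs = len(_traceback_pairs(idx, dp, engine._wm, engine.min_loop))
    return -float(dp[0, len(seq) - 1]), n_pairs


def fold_pairs(seq: str, engine: FoldingEngine) -> list[tuple[int, int]]:
    """Paired positions of one optimal basepair_max structure."""
    if engine.backend != "basepair_max":
        raise ValueError("pair traceback requires the basepair_max backend")
    if len(seq) <= engine.min_loop + 1:
        return []
    idx = np.array([_NT.get(b, 0) for b in seq], dtype=np.int64)
    dp = _nussinov_dp(idx, engine._wm, engine.min_loop)
    return _traceback_pairs(idx, dp, engine._wm, engine.min_loop)


# ---------------------------------------------------------------------------
# Window geometry
# ---------------------------------------------------------------------------

#: name -> (segment, anchor, length); anchor "start"/"end" of the segment.
NAMED_WINDOWS: dict[str, tuple[str, str, int]] = {
    "UTR5.folding.last40": ("utr5", "end", 40),
    "ORF.folding.first30c": ("orf", "start", 90),
    "ORF.folding.last30c": ("orf", "end", 90),
    "UTR3.folding.first40": ("utr3", "start", 40),
}

SLIDING_LEN = 40
SLIDING_STEP = 10
SLIDING_EXTENT = 300
SLIDING_WINDOWS = [
    f"ORF.folding.w{start:03d}"
    for start in range(0, SLIDING_EXTENT - SLIDING_LEN + 1, SLIDING_STEP)
]

PARS_WINDOWS = {
    name.replace(".folding.", ".pars."): spec
    for name, spec in NAMED_WINDOWS.items()
}


def _window_seq(rec: TranscriptRecord, segment: str, anchor: str, length: int) -> str:
    seq = getattr(rec, segment)
    return seq[:length] if anchor == "start" else seq[-length:] if seq else ""


def _window_bounds(rec: TranscriptRecord, segment: str, anchor: str,
                   length: int) -> tuple[int, int]:
    """Transcript-coordinate half-open bounds of a clipped window."""
    offs = {"utr5": 0, "orf": len(rec.utr5),
            "utr3": len(rec.utr5) + len(rec.orf)}
    seg_len = len(getattr(rec, segment))
    lo = offs[segment]
    if anchor == "start":
        return lo, lo + min(length, seg_len)
    return lo + max(0, seg_len - length), lo + seg_len


def windowed_folding_features(rec: TranscriptRecord,
                              engine: FoldingEngine) -> dict[str, float]:
    """Folding score, pair count and per-nt score over the default windows.

    Named boundary windows report all three quantities; the sliding windows
    over the first 300 nt of the ORF report the score only.  Empty (clipped
    to nothing) windows emit the catalogue defaults of 0.
    """
    out: dict[str, float] = {}
    for name, (segment, anchor, length) in NAMED_WINDOWS.items():
        seq = _window_seq(rec, segment, anchor, length)
        if seq:
            fe, n_bp = fold_score(seq, engine)
            out[f"{name}.fe"] = fe
            out[f"{name}.n_bp"] = float(n_bp)
            out[f"{name}.fe_per_nt"] = fe / len(seq)
        else:
            out[f"{name}.fe"] = 0.0
            out[f"{name}.n_bp"] = 0.0
            out[f"{name}.fe_per_nt"] = 0.0
    for name in SLIDING_WINDOWS:
        start = int(name[-3:])
        seq = rec.orf[start : start + SLIDING_LEN]
        out[name] = fold_score(seq, engine)[0] if seq else 0.0
    return out


def pars_features(rec: TranscriptRecord) -> dict[str, float]:
    """Measured-structure summaries over the named boundary windows.

    Per window: mean PARS, max PARS and mean expPARS, where expPARS is the
    per-nucleotide exponent exp(PARS_i).  Records without a PARS profile
    emit the defaults (0, 0, 1) so the feature count never changes.
    """
    out: dict[str, float] = {}
    for name, (segment, anchor, length) in PARS_WINDOWS.items():
        if rec.pars is None:
            vals = None
        else:
            lo, hi = _window_bounds(rec, segment, anchor, length)
            vals = rec.pars[lo:hi] if hi > lo else None
        if vals is None or len(vals) == 0:
            out[f"{name}.mean"] = 0.0
            out[f"{name}.max"] = 0.0
            out[f"{name}.exp_mean"] = 1.0
        else:
            out[f"{name}.mean"] = float(np.mean(vals))
            out[f"{name}.max"] = float(np.max(vals))
            out[f"{name}.exp_mean"] = float(np.mean(np.exp(vals)))
    return out
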
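"""Codon-adaptation indices and start-context inference.

Two inference schemes are supported, mirroring the two ways these indices
can be parameterized:

* **Scheme A** is expression-free: tAI weights come from tRNA gene copy
  numbers with the standard wobble penalties, and the CAI reference set and
  context-PSSM training set are the top genes ranked by tAI — a
  transcript-only proxy for high expression.  Scheme-A constructors never
  accept expression data, which is what makes the no-leakage guarantee
  checkable at the interface level.
* **Scheme B** re-estimates the weights on a training set's mRNA levels by
  deterministic coordinate ascent on a rank-correlation objective.

The gene-level index (tAI or CAI alike) is the geometric mean of the codon
weights along the ORF, stop codon excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._tables import DEFAULT_TRNA_COPIES, SENSE_CODONS, SYNONYMS, revcomp
from .io_formats import TranscriptRecord
from .sequence_features import orf_codon_indices

log = logging.getLogger(__name__)

#: Wobble-pairing inefficiencies (1 - s enters the weight sum), standard
#: eukaryotic tAI parameterization.  Keys are pairing classes named by
#: anticodon wobble base : codon third base (DNA alphabet, I = inosine
#: from genomically encoded A).
DEFAULT_S_PARAMS: dict[str, float] = {
    "WC": 0.0,      # Watson-Crick
    "G:T": 0.41,    # anticodon G reading codon-3rd T
    "I:C": 0.28,    # inosine reading C
    "I:A": 0.9999,  # inosine reading A
    "T:G": 0.68,    # anticodon T (U) reading G
}

#: (codon third base) -> [(anticodon wobble base, pairing class)]
_WOBBLE_RULES: dict[str, list[tuple[str, str]]] = {
    "T": [("A", "WC"), ("G", "G:T")],
    "C": [("G", "WC"), ("A", "I:C")],
    "A": [("T", "WC"), ("A", "I:A")],
    "G": [("C", "WC"), ("T", "T:G")],
}


@dataclass
class CodonWeights:
    """Normalized per-codon weights w in (0, 1], aligned with SENSE_CODONS."""

    w: np.ndarray
    provenance: str  # tRNA_copy_number | reference_set | train_optimized
    s_params: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (61,):
            raise ValueError("weights must align with the 61 sense codons")
        if not np.all((self.w > 0) & (self.w <= 1.0 + 1e-12)):
            raise ValueError("weights must lie in (0, 1]")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SENSE_CODONS, self.w))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("codon\tw\tprovenance\n")
            for c, w in zip(SENSE_CODONS, self.w):
                fh.write(f"{c}\t{w:.6g}\t{self.provenance}\n")


def _impute_and_normalize(raw: np.ndarray, provenance: str,
                          s_params: dict[str, float] | None = None) -> CodonWeights:
    """Max-normalize; replace zero weights by the geometric mean of the rest.

    The geometric-mean imputation keeps logs defined for codons no bundled
    anticodon can decode, without making them look well-adapted.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.max() <= 0:
        raise ValueError("all codon weights are zero")
    w = raw / raw.max()
    zero = w <= 0
    if zero.any():
        gm = float(np.exp(np.mean(np.log(w[~zero]))))
        w[zero] = gm
        log.info("imputed %d zero codon weights with geometric mean %.4g",
                 int(zero.sum()), gm)
    return CodonWeights(w=w, provenance=provenance, s_params=s_params or {})


def read_trna_copies(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["anticodon"].str.upper(), df["copies"].astype(int)))


def tai_weights_from_copy_numbers(
    trna_copies: Mapping[str, int] | None = None,
    s_params: Mapping[str, float] | None = None,
) -> CodonWeights:
    """tRNA-adaptation weights from anticodon gene copy numbers.

    W_c = sum over decoding anticodons of (1 - s_pairing) * copies, then
    max-normalized.  Decoding anticodons per codon are the Watson-Crick
    cognate plus the single standard wobble alternative for the codon's
    third base.
    """
    copies = dict(DEFAULT_TRNA_COPIES if trna_copies is None else trna_copies)
    s = dict(DEFAULT_S_PARAMS)
    if s_params:
        s.update(s_params)
    if not any(v > 0 for v in copies.values()):
        raise ValueError("tRNA copy-number table is all zero")
    raw = np.zeros(61)
    for i, codon in enumerate(SENSE_CODONS):
        cognate_tail = revcomp(codon)[1:]
        for wobble_base, klass in _WOBBLE_RULES[codon[2]]:
            anticodon = wobble_base + cognate_tail
            raw[i] += (1.0 - s[klass]) * copies.get(anticodon, 0)
    return _impute_and_normalize(raw, "tRNA_copy_number", dict(s))


def gene_index(orf: str, weights: CodonWeights) -> float:
    """Geometric mean of the codon weights over the gene's sense codons."""
    idx = orf_codon_indices(orf)
    sense = idx[idx >= 0]
    if len(sense) == 0:
        raise ValueError("ORF has no sense codons")
    return float(np.exp(np.mean(np.log(weights.w[sense]))))


def gene_index_matrix(counts: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized gene index from a genes x 61 sense-codon count matrix."""
    total = counts.sum(axis=1)
    return np.exp(counts @ np.log(w) / total)


def codon_count_matrix(orfs: Sequence[str]) -> np.ndarray:
    counts = np.zeros((len(orfs), 61))
    for g, orf in enumerate(orfs):
        idx = orf_codon_indices(orf)
        sense = idx[idx >= 0]
        counts[g] = np.bincount(sense, minlength=61)
    return counts


def cai_weights_from_reference(reference_orfs: Sequence[str]) -> CodonWeights:
    """CAI relative-adaptiveness weights from a reference ORF set.

    w_c = count(c) / count(most frequent synonym of c's amino acid) over the
    pooled reference; zero counts get a 0.5 pseudocount before the ratio.
    """
    if len(reference_orfs) == 0:
        raise ValueError("empty reference set")
    counts = codon_count_matrix(reference_orfs).sum(axis=0)
    counts[counts == 0] = 0.5
    w = np.ones(61)
    codon_pos = {c: i for i, c in enumerate(SENSE_CODONS)}
    for syns in SYNONYMS.values():
        pos = [codon_pos[c] for c in syns]
        w[pos] = counts[pos] / counts[pos].max()
    return CodonWeights(w=w, provenance="reference_set")


def scheme_a_reference_selection(
    transcripts: Sequence[TranscriptRecord],
    weights_tai: CodonWeights,
    top_fraction: float = 0.1,
    min_genes: int = 10,
) -> list[TranscriptRecord]:
    """Expression-free proxy for 'highly expressed genes': top genes by tAI.

    Used to pick the CAI reference set and the context-PSSM training set in
    scheme A.  Deterministic: ties in tAI break by gene id.
    """
    if weights_tai.provenance != "tRNA_copy_number":
        raise ValueError("scheme A requires copy-number (expression-free) weights")
    scored = sorted(
        transcripts,
        key=lambda r: (-gene_index(r.orf, weights_tai), r.gene_id),
    )
    k = max(min_genes, int(round(top_fraction * len(scored))))
    if top_fraction >= 1.0:
        k = len(scored)
    k = min(k, len(scored))
    if k < min_genes:
        raise ValueError(f"reference selection yields {k} genes (< {min_genes})")
    return scored[:k]


def scheme_b_optimize(
    weights0: CodonWeights,
    train_orfs: Sequence[str],
    train_mrna: np.ndarray,
    steps: Sequence[float] = (0.4, 0.2, 0.1, 0.05),
    max_sweeps: int = 200,
    train_ids: Sequence[str] | None = None,
    forbidden_ids: Iterable[str] = (),
    counts: np.ndarray | None = None,
) -> tuple[CodonWeights, float]:
    """Re-estimate codon weights on the train set's mRNA levels.

    Deterministic coordinate ascent over the 61 log-weights in fixed codon
    order: each sweep tries the perturbations +/- ``steps`` (coarse to fine
    — the rank objective is piecewise constant, so small moves alone would
    stall on plateaus) on each log-weight and keeps the best one that
    raises the Spearman correlation between the gene index and train mRNA;
    stops when a full sweep accepts nothing.  The leakage guard rejects any
    train id listed in ``forbidden_ids`` (the caller's test/validation
    genes).

    Returns the optimized weights and the achieved rank correlation.
    """
    if train_ids is not None:
        clash = set(train_ids) & set(forbidden_ids)
        if clash:
            raise ValueError(f"leakage: held-out genes in train set: {sorted(clash)[:3]}")
    mrna = np.asarray(train_mrna, dtype=float)
    if counts is None:
        counts = codon_count_matrix(train_orfs)
    if len(mrna) != counts.shape[0]:
        raise ValueError("train set and train_mrna lengths differ")
    totals = counts.sum(axis=1)
    r_mrna = rankdata(mrna)
    r_mrna_c = r_mrna - r_mrna.mean()
    denom_m = np.sqrt((r_mrna_c ** 2).sum())

    def objective(logw: np.ndarray) -> float:
        scores = counts @ logw / totals
        r = rankdata(scores)
        rc = r - r.mean()
        d = np.sqrt((rc ** 2).sum()) * denom_m
        if d == 0:
            return -np.inf
        val = float((rc * r_mrna_c).sum() / d)
        if not np.isfinite(val):
            raise ValueError("non-finite optimization objective")
        return val

    logw = np.log(weights0.w.copy())
    best = objective(logw)
    deltas = [d for s in steps for d in (s, -s)]
    if max_sweeps > 0:
        for _ in range(max_sweeps):
            improved = False
            for j in range(61):
                old = logw[j]
                best_delta, best_val = 0.0, best
                for delta in deltas:
                    cand = old + delta
                    if cand > 0:  # keep w <= 1
                        continue
                    logw[j] = cand
                    val = objective(logw)
                    if val > best_val:
                        best_delta, best_val = delta, val
                logw[j] = old + best_delta
                if best_delta != 0.0:
                    best = best_val
                    improved = True
            if not improved:
                break
    w = np.exp(logw)
    w = w / w.max()
    return CodonWeights(w=w, provenance="train_optimized"), best


# ---------------------------------------------------------------------------
# Start-codon context PSSM
# ---------------------------------------------------------------------------

_NT_INDEX = {b: i for i, b in enumerate("ACGT")}

#: Offsets relative to the A of ATG: 6 nt upstream, 3 nt downstream.
CONTEXT_OFFSETS = tuple(range(-6, 0)) + tuple(range(3, 6))


@dataclass
class ContextPSSM:
    """Log-odds matrix over the START-flanking window (ATG itself excluded)."""

    logodds: np.ndarray  # len(CONTEXT_OFFSETS) x 4
    background: np.ndarray  # 4 nucleotide frequencies

    def score(self, seq: str, atg_pos: int) -> float:
        """Sum of per-position log-odds; out-of-sequence positions add 0."""
        total = 0.0
        for k, off in enumerate(CONTEXT_OFFSETS):
            p = atg_pos + off
            if 0 <= p < len(seq):
                j = _NT_INDEX.get(seq[p])
                if j is not None:
                    total += self.logodds[k, j]
        return total


def build_context_pssm(training: Sequence[TranscriptRecord],
                       pseudocount: float = 1.0) -> ContextPSSM:
    """PSSM of the main-START context over a training gene set.

    Per-position nucleotide frequencies (pseudocount 1) are converted to
    log-odds against the pooled background frequency of all window
    nucleotides.
    """
    counts = np.zeros((len(CONTEXT_OFFSETS), 4))
    for rec in training:
        tx = rec.transcript
        atg = len(rec.utr5)
        for k, off in enumerate(CONTEXT_OFFSETS):
            p = atg + off
            if 0 <= p < len(tx) and tx[p] in _NT_INDEX:
                counts[k, _NT_INDEX[tx[p]]] += 1
    freq = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
    pooled = counts.sum(axis=0)
    background = (pooled + pseudocount) / (pooled + pseudocount).sum()
    return ContextPSSM(logodds=np.log(freq / background), background=background)
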
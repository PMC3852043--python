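"""Features computable from the transcript string alone.

Covers segment lengths and ratios, nucleotide composition (whole segments and
the "30C" windows around segment boundaries), codon / amino-acid / pair usage
frequencies, upstream and shifted open reading frames, and start-codon
context scores against a trained position-specific matrix.

Conventions: ATG occurrences are counted with an overlapping step-1 scan;
stop codons are the standard TAA/TAG/TGA; "distance" features default to
segment length + 1 (a sentinel larger than any real distance) when the
segment contains no ATG.
"""

from __future__ import annotations

import logging
from typing import TYPE_CHECKING

import numpy as np

from ._tables import (
    AA_INDEX, AMINO_ACIDS, CODON_INDEX, CODON_TO_AA, SENSE_CODONS, STOP_CODONS,
)
from .io_formats import TranscriptRecord

if TYPE_CHECKING:  # pragma: no cover
    from .adaptation import ContextPSSM

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

#: 30 codons = 90 nt: the window size used at segment boundaries.
WINDOW_30C = 90


def count_atg(seq: str) -> int:
    """Overlapping ATG count (step-1 scan)."""
    return sum(1 for i in range(len(seq) - 2) if seq[i : i + 3] == "ATG")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def length_features(rec: TranscriptRecord) -> dict[str, float]:
    n5, no, n3 = len(rec.utr5), len(rec.orf), len(rec.utr3)
    nt = n5 + no + n3
    return {
        "UTR5.length.nt": float(n5),
        "ORF.length.nt": float(no),
        "ORF.length.codons": no / 3.0,
        "UTR3.length.nt": float(n3),
        "TRANSCRIPT.length.nt": float(nt),
        "TRANSCRIPT.length.ratio_utr5_orf": n5 / no,
        "TRANSCRIPT.length.ratio_utr3_orf": n3 / no,
        "TRANSCRIPT.length.ratio_utrs_transcript": (n5 + n3) / nt,
    }


def _comp_block(prefix: str, seq: str) -> dict[str, float]:
    out = {f"{prefix}.gc": gc_fraction(seq)}
    n = len(seq)
    for b in NUCLEOTIDES:
        out[f"{prefix}.freq_{b}"] = seq.count(b) / n if n else 0.0
    return out


def composition_features(rec: TranscriptRecord) -> dict[str, float]:
    """Composition of each segment, the whole transcript, and 30C windows.

    Windows: first/last 90 nt of the ORF, last 90 nt of the 5'UTR, first
    90 nt of the 3'UTR; each truncated to the segment when shorter.
    """
    out: dict[str, float] = {}
    segs = {
        "UTR5": rec.utr5, "ORF": rec.orf, "UTR3": rec.utr3,
        "TRANSCRIPT": rec.transcript,
    }
    for scope, seq in segs.items():
        out.update(_comp_block(f"{scope}.composition", seq))
        out[f"{scope}.composition.n_atg"] = float(count_atg(seq))
    windows = {
        "ORF.composition.first30c": rec.orf[:WINDOW_30C],
        "ORF.composition.last30c": rec.orf[-WINDOW_30C:],
        "UTR5.composition.last30c": rec.utr5[-WINDOW_30C:],
        "UTR3.composition.first30c": rec.utr3[:WINDOW_30C],
    }
    for prefix, seq in windows.items():
        out.update(_comp_block(prefix, seq))
    return out


def orf_codon_indices(orf: str) -> np.ndarray:
    """Sense-codon index per codon of the ORF (stop and invalid codons = -1).

    Internal stop codons are legal here (they are counted and logged by the
    caller-facing wrapper); they simply do not contribute to sense usage.
    """
    idx = np.full(len(orf) // 3, -1, dtype=np.int64)
    for i in range(len(idx)):
        idx[i] = CODON_INDEX.get(orf[3 * i : 3 * i + 3], -1)
    return idx


CODON_FEATURES = [f"ORF.codon.{c}" for c in SENSE_CODONS]
AA_FEATURES = [f"ORF.aa.{a}" for a in AMINO_ACIDS]
CODON_PAIR_FEATURES = [
    f"ORF.codon_pair.{a}_{b}" for a in SENSE_CODONS for b in SENSE_CODONS
]
AA_PAIR_FEATURES = [
    f"ORF.aa_pair.{a}_{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS
]

_CODON_AA = np.array([AA_INDEX[CODON_TO_AA[c]] for c in SENSE_CODONS])


def codon_usage_arrays(
    orf: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Relative usage of codons, amino acids, and adjacent ordered pairs.

    Returns four arrays aligned with ``CODON_FEATURES`` / ``AA_FEATURES`` /
    ``CODON_PAIR_FEATURES`` / ``AA_PAIR_FEATURES``.  Frequencies are over the
    gene's sense codons (stop excluded); each family sums to 1 when the gene
    has enough sense codons, and is all-zero otherwise (catalogue defaults).
    """
    idx = orf_codon_indices(orf)
    n_internal_stop = sum(
        1 for i in range(len(idx) - 1)
        if orf[3 * i : 3 * i + 3] in STOP_CODONS
    )
    if n_internal_stop:
        log.warning("ORF has %d internal stop codon(s)", n_internal_stop)
    sense = idx[idx >= 0]
    codon = np.zeros(61)
    aa = np.zeros(20)
    cpair = np.zeros(61 * 61)
    apair = np.zeros(20 * 20)
    if len(sense):
        counts = np.bincount(sense, minlength=61).astype(float)
        codon = counts / counts.sum()
        aa_counts = np.bincount(_CODON_AA[sense], minlength=20).astype(float)
        aa = aa_counts / aa_counts.sum()
    # pairs over adjacent codons where both are sense
    a, b = idx[:-1], idx[1:]
    ok = (a >= 0) & (b >= 0)
    if ok.sum() >= 1:
        pc = np.bincount(a[ok] * 61 + b[ok], minlength=61 * 61).astype(float)
        cpair = pc / pc.sum()
        pa = np.bincount(
            _CODON_AA[a[ok]] * 20 + _CODON_AA[b[ok]], minlength=400
        ).astype(float)
        apair = pa / pa.sum()
    return codon, aa, cpair, apair


def codon_and_pair_features(orf: str) -> dict[str, float]:
    """Dict view of :func:`codon_usage_arrays` keyed by catalogue names."""
    codon, aa, cpair, apair = codon_usage_arrays(orf)
    out = dict(zip(CODON_FEATURES, codon))
    out.update(zip(AA_FEATURES, aa))
    out.update(zip(CODON_PAIR_FEATURES, cpair))
    out.update(zip(AA_PAIR_FEATURES, apair))
    return out


# ---------------------------------------------------------------------------
# Upstream / shifted open reading frames
# ---------------------------------------------------------------------------


def _atg_positions(seq: str, start: int = 0) -> list[int]:
    return [i for i in range(start, len(seq) - 2) if seq[i : i + 3] == "ATG"]


def _has_inframe_stop(seq: str, atg: int) -> bool:
    for q in range(atg + 3, len(seq) - 2, 3):
        if seq[q : q + 3] in STOP_CODONS:
            return True
    return False


def find_uorfs(
    utr5: str, allow_stop_in_orf: bool = False, orf: str = ""
) -> tuple[int, float]:
    """Upstream ORFs in the 5'UTR and the first-ATG distance to the START.

    A uORF is an ATG in the 5'UTR with an in-frame stop codon downstream,
    by default still inside the 5'UTR (``allow_stop_in_orf=True`` lets the
    stop fall inside the main ORF instead).  The distance is from the first
    ATG — uORF-forming or not — to the main START, in nucleotides; when the
    UTR has no ATG it takes the sentinel default ``len(utr5) + 1``.
    """
    atgs = _atg_positions(utr5)
    search = utr5 + orf if allow_stop_in_orf else utr5
    count = sum(1 for p in atgs if _has_inframe_stop(search, p))
    dist = (len(utr5) - atgs[0]) if atgs else len(utr5) + 1.0
    return count, float(dist)


def find_sorfs(orf: str) -> dict[str, float]:
    """Alternative ATGs inside the ORF, by reading frame.

    Frame = (offset from the main START) mod 3.  A shifted ORF (sORF) is an
    out-of-frame alternative ATG (frame 1 or 2) with a stop codon downstream
    in its own frame, within the ORF.  Frame-0 alternative ATGs are counted
    as-is (their in-frame stop is the gene's own).  The first-alternative-ATG
    distance covers any frame and defaults to ``len(orf) + 1``.
    """
    alt = _atg_positions(orf, start=1)
    n_f0 = sum(1 for p in alt if p % 3 == 0)
    n_f1 = sum(1 for p in alt if p % 3 == 1 and _has_inframe_stop(orf, p))
    n_f2 = sum(1 for p in alt if p % 3 == 2 and _has_inframe_stop(orf, p))
    dist = float(alt[0]) if alt else len(orf) + 1.0
    return {
        "ORF.init.n_alt_atg_f0": float(n_f0),
        "ORF.init.n_sorf_f1": float(n_f1),
        "ORF.init.n_sorf_f2": float(n_f2),
        "ORF.init.first_alt_atg_dist": dist,
    }


def init_features(rec: TranscriptRecord, allow_stop_in_orf: bool = False) -> dict[str, float]:
    n_uorfs, atg_dist = find_uorfs(rec.utr5, allow_stop_in_orf, rec.orf)
    out = {
        "UTR5.init.n_uorfs": float(n_uorfs),
        "UTR5.init.first_atg_dist": atg_dist,
    }
    out.update(find_sorfs(rec.orf))
    return out


# ---------------------------------------------------------------------------
# Start-codon context scores
# ---------------------------------------------------------------------------


def atg_context_scores(rec: TranscriptRecord, pssm: "ContextPSSM",
                       suffix: str = "") -> dict[str, float]:
    """Context score of the main START and of every alternative ATG.

    The main score is the PSSM log-odds over 6 nt upstream + 3 nt downstream
    of the START (flanks taken from the full transcript; positions falling
    outside it contribute 0).  Per segment, the Best and Mean relative scores
    are max/mean over that segment's alternative ATGs of (alternative score -
    main score); segments without an alternative ATG default to 0.
    """
    tx = rec.transcript
    main_pos = len(rec.utr5)
    main = pssm.score(tx, main_pos)
    out = {f"TRANSCRIPT.init.context_score{suffix}": main}
    seg_bounds = {
        "UTR5": (0, main_pos),
        "ORF": (main_pos + 1, main_pos + len(rec.orf)),
        "UTR3": (main_pos + len(rec.orf), len(tx)),
    }
    for scope, (lo, hi) in seg_bounds.items():
        rel = [
            pssm.score(tx, p) - main
            for p in range(lo, min(hi, len(tx) - 2))
            if tx[p : p + 3] == "ATG"
        ]
        out[f"{scope}.init.best_rel_context{suffix}"] = max(rel) if rel else 0.0
        out[f"{scope}.init.mean_rel_context{suffix}"] = (
            float(np.mean(rel)) if rel else 0.0
        )
    return out
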
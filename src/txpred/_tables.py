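"""Genetic-code constants and bundled default parameter tables.

The genetic code is taken from Biopython's standard table (NCBI table 1).
Non-standard codes are out of scope throughout the package.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: The 61 sense codons of the standard code, in lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(sorted(_STANDARD.forward_table))

#: Stop codons of the standard code.
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: codon -> one-letter amino acid (sense codons only).
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)

#: The 20 amino acids, alphabetical one-letter codes.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_TO_AA.values())))

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: amino acid -> list of synonymous sense codons.
SYNONYMS: dict[str, list[str]] = {}
for _c, _a in CODON_TO_AA.items():
    SYNONYMS.setdefault(_a, []).append(_c)
for _a in SYNONYMS:
    SYNONYMS[_a].sort()

START_CODON = "ATG"

COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Default tRNA gene copy numbers (DNA-alphabet anticodons).
#
# Representative budding-yeast-like values bundled so that tRNA-adaptation
# weights and the synthetic transcriptome generator work out of the box.
# They are a synthetic stand-in calibrated to the magnitude and sparsity of
# a real eukaryotic tRNA gene complement, not a curated genome annotation;
# supply a measured table via ``adaptation.read_trna_copies`` for real data.
# ---------------------------------------------------------------------------
DEFAULT_TRNA_COPIES: dict[str, int] = {
    # Ala
    "AGC": 11, "TGC": 5,
    # Arg
    "ACG": 6, "CCG": 1, "CCT": 1, "TCT": 11,
    # Asn
    "GTT": 10,
    # Asp
    "GTC": 16,
    # Cys
    "GCA": 4,
    # Gln
    "CTG": 1, "TTG": 9,
    # Glu
    "CTC": 2, "TTC": 14,
    # Gly
    "GCC": 16, "CCC": 2, "TCC": 3,
    # His
    "GTG": 7,
    # Ile
    "AAT": 13, "TAT": 2,
    # Leu
    "AAG": 7, "CAA": 10, "TAG": 3, "TAA": 7, "GAG": 1,
    # Lys
    "CTT": 14, "TTT": 7,
    # Met (initiator + elongator pooled)
    "CAT": 10,
    # Phe
    "GAA": 10,
    # Pro
    "AGG": 10, "TGG": 2,
    # Ser
    "AGA": 11, "CGA": 1, "GCT": 4, "TGA": 3,
    # Thr
    "AGT": 11, "CGT": 1, "TGT": 4,
    # Trp
    "CCA": 6,
    # Tyr
    "GTA": 8,
    # Val
    "AAC": 14, "CAC": 2, "TAC": 2,
}
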
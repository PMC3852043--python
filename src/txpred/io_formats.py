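"""Reading, validating and writing the pipeline's external representations.

Transcripts arrive as three FASTA files (5'UTR, ORF, 3'UTR) keyed by a shared
gene id; expression measurements as a TSV with columns ``gene_id``, ``mrna``,
``pa``, ``rd``; per-nucleotide PARS structure scores as a TSV with columns
``gene_id``, ``pos`` (1-based over the concatenated transcript), ``score``.
All sequence coordinates are 0-based half-open inside the package; 1-based
coordinates appear only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._tables import START_CODON, STOP_CODONS

log = logging.getLogger(__name__)

_VALID_ALPHABET = frozenset("ACGT")


class ValidationError(ValueError):
    """A transcript record violated a structural invariant."""


@dataclass
class TranscriptRecord:
    """One gene's transcript, split into its three segments.

    ``pars``, when present, holds one measured structure score per nucleotide
    of the concatenated ``utr5 + orf + utr3`` sequence.
    """

    gene_id: str
    utr5: str = ""
    orf: str = ""
    utr3: str = ""
    pars: np.ndarray | None = field(default=None, repr=False)

    @property
    def transcript(self) -> str:
        return self.utr5 + self.orf + self.utr3

    def __len__(self) -> int:
        return len(self.utr5) + len(self.orf) + len(self.utr3)


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def validate_record(rec: TranscriptRecord, strict: bool = True) -> list[str]:
    """Check a record's invariants; return the list of violations.

    In strict mode a non-empty list means the record must be rejected.  In
    permissive mode violations are only warnings (the caller may still have
    repaired e.g. a trailing partial codon before calling).
    """
    problems: list[str] = []
    for name, seg in (("utr5", rec.utr5), ("orf", rec.orf), ("utr3", rec.utr3)):
        bad = set(seg) - _VALID_ALPHABET
        if bad:
            problems.append(f"{name} contains non-ACGT characters {sorted(bad)}")
    if len(rec.orf) == 0:
        problems.append("orf is empty")
    else:
        if len(rec.orf) % 3 != 0:
            problems.append(f"orf length {len(rec.orf)} not divisible by 3")
        else:
            if not rec.orf.startswith(START_CODON):
                problems.append("orf does not begin with ATG")
            if rec.orf[-3:] not in STOP_CODONS:
                problems.append("orf does not end with a stop codon")
    if rec.pars is not None and len(rec.pars) != len(rec):
        problems.append(
            f"pars length {len(rec.pars)} != transcript length {len(rec)}"
        )
    if problems and not strict:
        log.warning("record %s: %s", rec.gene_id, "; ".join(problems))
    return problems


def _read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seqs:
            raise ValidationError(f"duplicate FASTA id {entry.id!r} in {path}")
        seqs[entry.id] = normalize_sequence(str(entry.seq))
    return seqs


def read_transcripts(
    utr5_path: str | Path | None,
    orf_path: str | Path,
    utr3_path: str | Path | None,
    pars_path: str | Path | None = None,
    strict: bool = True,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Load and validate transcripts; the ORF file defines the gene universe.

    Genes missing from a UTR file get an empty string for that segment.  In
    permissive (``strict=False``) mode an ORF whose length is not a multiple
    of 3 is truncated from the 3' end with a warning instead of rejected.

    Returns ``(accepted_records, rejections)`` where ``rejections`` maps each
    rejected gene id to its reason, so accepted + rejected = input count.
    """
    orfs = _read_fasta(orf_path)
    utr5s = _read_fasta(utr5_path) if utr5_path else {}
    utr3s = _read_fasta(utr3_path) if utr3_path else {}

    pars_by_gene: dict[str, dict[int, float]] = {}
    if pars_path:
        pars_df = pd.read_csv(pars_path, sep="\t", dtype={"gene_id": str})
        for gid, grp in pars_df.groupby("gene_id"):
            pars_by_gene[str(gid)] = dict(
                zip(grp["pos"].astype(int), grp["score"].astype(float))
            )

    accepted: list[TranscriptRecord] = []
    rejections: dict[str, str] = {}
    for gid in orfs:
        orf = orfs[gid]
        if len(orf) % 3 != 0 and not strict:
            log.warning(
                "gene %s: ORF length %d not divisible by 3; truncating 3' end",
                gid, len(orf),
            )
            orf = orf[: len(orf) - len(orf) % 3]
        rec = TranscriptRecord(
            gene_id=gid, utr5=utr5s.get(gid, ""), orf=orf, utr3=utr3s.get(gid, "")
        )
        if gid in pars_by_gene:
            vec = np.zeros(len(rec))
            for pos1, score in pars_by_gene[gid].items():
                if not 1 <= pos1 <= len(rec):
                    rejections[gid] = f"PARS position {pos1} outside transcript"
                    break
                vec[pos1 - 1] = score
            else:
                rec.pars = vec
            if gid in rejections:
                log.warning("rejected %s: %s", gid, rejections[gid])
                continue
        problems = validate_record(rec, strict=strict)
        if problems and strict:
            rejections[gid] = "; ".join(problems)
            log.warning("rejected %s: %s", gid, rejections[gid])
        else:
            accepted.append(rec)
    return accepted, rejections


def write_transcripts(
    records: Iterable[TranscriptRecord],
    utr5_path: str | Path,
    orf_path: str | Path,
    utr3_path: str | Path,
    pars_path: str | Path | None = None,
) -> None:
    """Write segment FASTAs (and optionally a PARS TSV) for a record set."""
    records = list(records)
    for path, attr in ((utr5_path, "utr5"), (orf_path, "orf"), (utr3_path, "utr3")):
        with open(path, "w") as fh:
            for rec in records:
                seq = getattr(rec, attr)
                if seq or attr == "orf":
                    fh.write(f">{rec.gene_id}\n{seq}\n")
    if pars_path is not None:
        with open(pars_path, "w") as fh:
            fh.write("gene_id\tpos\tscore\n")
            for rec in records:
                if rec.pars is None:
                    continue
                for i, score in enumerate(rec.pars):
                    fh.write(f"{rec.gene_id}\t{i + 1}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

MEASURED_TARGETS = ("mrna", "pa", "rd")
DERIVED_TARGETS = ("ppr", "rl")
ALL_TARGETS = MEASURED_TARGETS + DERIVED_TARGETS


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a measured-expression TSV (gene_id, mrna, pa, rd).

    Derived columns (ppr, rl) are never read from disk; use
    :func:`derive_targets`, which is their single source of definition.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in ("gene_id", *MEASURED_TARGETS) if c not in df.columns]
    if missing:
        raise ValidationError(f"expression table missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r} in expression table")
    return df.set_index("gene_id")[list(MEASURED_TARGETS)].astype(float)


def derive_targets(
    table: pd.DataFrame,
    rl_definition: str = "density_times_mrna",
    orf_codon_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Add the two derived expression measures to a measured table.

    ppr (proteins per mRNA molecule) = pa / mrna.
    rl  (ribosomal load) = rd * mrna by default, or rd * mrna * ORF codon
    count under ``rl_definition="total_ribosomes"`` (requires
    ``orf_codon_counts``).  Rows with a missing or non-positive operand get a
    missing derived value.
    """
    out = table.copy()
    mrna = out["mrna"].where(out["mrna"] > 0)
    n_bad = int((out["mrna"] <= 0).sum())
    if n_bad:
        log.warning("%d genes with non-positive mrna; derived values set missing", n_bad)
    out["ppr"] = out["pa"] / mrna
    if rl_definition == "density_times_mrna":
        out["rl"] = out["rd"] * mrna
    elif rl_definition == "total_ribosomes":
        if orf_codon_counts is None:
            raise ValueError("total_ribosomes rl_definition needs orf_codon_counts")
        codons = pd.Series(orf_codon_counts, dtype=float).reindex(out.index)
        out["rl"] = out["rd"] * mrna * codons
    else:
        raise ValueError(f"unknown rl_definition {rl_definition!r}")
    return out


def join_universe(
    records: list[TranscriptRecord], expression: pd.DataFrame
) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Intersect sequence and expression gene universes, logging the drops."""
    seq_ids = [r.gene_id for r in records]
    common = [g for g in seq_ids if g in expression.index]
    n_seq_only = len(seq_ids) - len(common)
    n_expr_only = len(expression.index.difference(seq_ids))
    if n_seq_only or n_expr_only:
        log.info(
            "joint universe: %d genes (%d sequence-only, %d expression-only dropped)",
            len(common), n_seq_only, n_expr_only,
        )
    keep = set(common)
    return [r for r in records if r.gene_id in keep], expression.loc[common]


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Serialize a genes x features matrix as TSV (NA for missing values)."""
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()][0]
        raise ValidationError(f"duplicate feature name {dup!r}")
    table.to_csv(path, sep="\t", index_label="gene_id", na_rep="NA",
                 float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    # pandas silently renames duplicate header fields, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ValidationError(f"duplicate feature name {name!r}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"gene_id": str})
    return df.set_index("gene_id")
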
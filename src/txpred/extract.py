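"""Assemble the full feature table and its catalogue for a transcript set.

Scheme A (the default) is entirely expression-free: tAI weights come from a
tRNA gene copy-number table, and the CAI reference set plus the start-context
PSSM training set are the top genes ranked by tAI.  Scheme B adds
expression-optimized variants of those features (column suffix ``_opt``)
which are recomputed per jackknife replicate from the train tercile's mRNA
levels; :func:`make_scheme_b_hook` builds the per-replicate recomputation
used by :func:`txpred.regression.build_family`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import sequence_features as sf
from .adaptation import (
    CodonWeights, ContextPSSM, build_context_pssm, cai_weights_from_reference,
    codon_count_matrix, gene_index_matrix, scheme_a_reference_selection,
    scheme_b_optimize, tai_weights_from_copy_numbers,
)
from .catalogue import FeatureCatalogue, FeatureDef
from .folding import FoldingEngine, pars_features, windowed_folding_features
from .io_formats import TranscriptRecord
from .tasep import FAST_PROFILE, TasepConfig, tasep_feature

log = logging.getLogger(__name__)

SCHEME_B_ADAPT = ["ORF.adaptation.tai_opt", "ORF.adaptation.cai_opt"]


@dataclass
class ExtractConfig:
    trna_copies: Mapping[str, int] | None = None
    cai_top_fraction: float = 0.1
    reference_min_genes: int = 10
    engine: FoldingEngine = field(default_factory=FoldingEngine)
    include_tasep: bool = True
    tasep: TasepConfig = field(
        default_factory=lambda: TasepConfig(**FAST_PROFILE)
    )
    seed: int = 0
    uorf_stop_in_orf: bool = False


@dataclass
class ExtractionResult:
    table: pd.DataFrame
    catalogue: FeatureCatalogue
    tai_weights: CodonWeights
    cai_weights: CodonWeights
    pssm: ContextPSSM


def _small_features(rec: TranscriptRecord, pssm: ContextPSSM,
                    cfg: ExtractConfig) -> dict[str, float]:
    out = sf.length_features(rec)
    out.update(sf.composition_features(rec))
    out.update(sf.init_features(rec, allow_stop_in_orf=cfg.uorf_stop_in_orf))
    out.update(sf.atg_context_scores(rec, pssm))
    return out


_BIG_NAMES = (
    sf.CODON_FEATURES + sf.AA_FEATURES + sf.CODON_PAIR_FEATURES
    + sf.AA_PAIR_FEATURES
)


def extract_features(
    records: Sequence[TranscriptRecord],
    config: ExtractConfig | None = None,
) -> ExtractionResult:
    """Scheme-A feature table for a set of validated transcripts.

    Column order is fixed and identical for every input set, so tables from
    different runs align by construction.
    """
    cfg = config or ExtractConfig()
    tai_w = tai_weights_from_copy_numbers(cfg.trna_copies)
    reference = scheme_a_reference_selection(
        records, tai_w, cfg.cai_top_fraction, min_genes=cfg.reference_min_genes
    )
    cai_w = cai_weights_from_reference([r.orf for r in reference])
    pssm = build_context_pssm(reference)

    counts = codon_count_matrix([r.orf for r in records])
    tai_vals = gene_index_matrix(counts, tai_w.w)
    cai_vals = gene_index_matrix(counts, cai_w.w)

    small_rows = []
    big_rows = np.empty((len(records), len(_BIG_NAMES)))
    fold_rows = []
    pars_rows = []
    tasep_vals = np.zeros(len(records))
    for g, rec in enumerate(records):
        small_rows.append(_small_features(rec, pssm, cfg))
        codon, aa, cpair, apair = sf.codon_usage_arrays(rec.orf)
        big_rows[g] = np.concatenate([codon, aa, cpair, apair])
        fold_rows.append(windowed_folding_features(rec, cfg.engine))
        pars_rows.append(pars_features(rec))
        if cfg.include_tasep:
            tasep_vals[g] = tasep_feature(
                rec.orf, tai_w, cfg.tasep, gene_id=rec.gene_id,
                global_seed=cfg.seed,
            )

    ids = [r.gene_id for r in records]
    parts = [
        pd.DataFrame(small_rows, index=ids),
        pd.DataFrame(big_rows, index=ids, columns=_BIG_NAMES),
        pd.DataFrame(
            {"ORF.adaptation.tai": tai_vals, "ORF.adaptation.cai": cai_vals},
            index=ids,
        ),
        pd.DataFrame(fold_rows, index=ids),
        pd.DataFrame(pars_rows, index=ids),
    ]
    if cfg.include_tasep:
        parts.append(pd.DataFrame({"ORF.tasep.current": tasep_vals}, index=ids))
    table = pd.concat(parts, axis=1)
    table.index.name = "gene_id"
    catalogue = build_catalogue(list(table.columns))
    return ExtractionResult(table, catalogue, tai_w, cai_w, pssm)


def build_catalogue(names: Sequence[str],
                    scheme: str = "A") -> FeatureCatalogue:
    """Catalogue entries inferred from the structured feature names.

    Names follow ``<scope>.<family>.<detail>``; defaults are 0 except
    expPARS means (1, the value of exp(0)) and distance sentinels (recorded
    as -1 here; at extraction time an ATG-free segment yields segment
    length + 1, which no single constant can represent).
    """
    cat = FeatureCatalogue()
    for name in names:
        scope, family = name.split(".", 2)[:2]
        default = 0.0
        if name.endswith("exp_mean"):
            default = 1.0
        elif "dist" in name:
            default = -1.0
        cat.add(FeatureDef(
            name=name, segment_scope=scope, family=family,
            default_value=default,
            requires_expression=name.endswith("_opt"),
        ))
    if scheme == "B":
        for name in scheme_b_feature_names():
            if name not in cat:
                scope, family = name.split(".", 2)[:2]
                cat.add(FeatureDef(name=name, segment_scope=scope,
                                   family=family, requires_expression=True))
    return cat


def scheme_b_feature_names() -> list[str]:
    names = list(SCHEME_B_ADAPT)
    names.append("TRANSCRIPT.init.context_score_opt")
    for scope in ("UTR5", "ORF", "UTR3"):
        names += [f"{scope}.init.best_rel_context_opt",
                  f"{scope}.init.mean_rel_context_opt"]
    return names


def make_scheme_b_hook(
    records: Sequence[TranscriptRecord],
    mrna: pd.Series,
    tai_weights: CodonWeights,
    top_fraction: float = 0.1,
    min_genes: int = 10,
):
    """Per-replicate recomputation of expression-dependent features.

    The returned hook receives the replicate's train gene ids and returns a
    DataFrame (indexed by all genes) of scheme-B columns: tAI with weights
    re-optimized on train mRNA, CAI referenced on the top train-tercile
    mRNA genes, and context scores against a PSSM trained on those same
    genes.  Only train-id expression values are ever touched.
    """
    by_id = {r.gene_id: r for r in records}
    all_ids = [r.gene_id for r in records]
    counts = codon_count_matrix([r.orf for r in records])
    row_of = {g: i for i, g in enumerate(all_ids)}

    def hook(train_ids: tuple[str, ...]) -> pd.DataFrame:
        train_ids = [g for g in train_ids if g in by_id and g in mrna.index]
        tr_rows = [row_of[g] for g in train_ids]
        tr_mrna = mrna.loc[train_ids].to_numpy(dtype=float)
        w_opt, _ = scheme_b_optimize(
            tai_weights, [by_id[g].orf for g in train_ids], tr_mrna,
            train_ids=train_ids, counts=counts[tr_rows],
        )
        order = np.argsort(-tr_mrna, kind="stable")
        k = max(min_genes, int(round(top_fraction * len(train_ids))))
        ref_ids = [train_ids[i] for i in order[:k]]
        cai_b = cai_weights_from_reference([by_id[g].orf for g in ref_ids])
        pssm_b = build_context_pssm([by_id[g] for g in ref_ids])

        data: dict[str, np.ndarray | list[float]] = {
            "ORF.adaptation.tai_opt": gene_index_matrix(counts, w_opt.w),
            "ORF.adaptation.cai_opt": gene_index_matrix(counts, cai_b.w),
        }
        ctx_rows = [sf.atg_context_scores(r, pssm_b, suffix="_opt")
                    for r in records]
        for col in ctx_rows[0]:
            data[col] = [row[col] for row in ctx_rows]
        return pd.DataFrame(data, index=all_ids)

    return hook
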
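"""End-to-end experiment grid.

One experiment runs the jackknife regression for every requested
combination of expression target {mrna, pa, rd, ppr, rl}, feature scope
{UTR5, ORF, UTR3, TRANSCRIPT}, inference scheme {A, B} and model kind
{linear, mars}, against either a synthetic transcriptome or user-supplied
FASTA/TSV inputs.  Per-cell reports go to JSON, the grid summary to a TSV
whose bytes are a deterministic function of (data, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .extract import (
    ExtractConfig, build_catalogue, extract_features, make_scheme_b_hook,
)
from .io_formats import (
    ALL_TARGETS, derive_targets, join_universe, read_expression,
    read_transcripts, write_feature_table,
)
from .regression import PredictorFamily, build_family
from .synthetic import SynthConfig, generate_expression, generate_transcriptome

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # data source: a synthetic profile or explicit input paths
    synth: SynthConfig | None = field(default_factory=SynthConfig)
    utr5_path: str | None = None
    orf_path: str | None = None
    utr3_path: str | None = None
    pars_path: str | None = None
    expression_path: str | None = None
    # grid
    targets: tuple[str, ...] = ALL_TARGETS
    scopes: tuple[str, ...] = ("UTR5", "ORF", "UTR3", "TRANSCRIPT")
    schemes: tuple[str, ...] = ("A",)
    models: tuple[str, ...] = ("linear",)
    # regression hyperparameters
    n_replicates: int = 100
    max_features: int = 30
    epsilon: float = 0.0
    mars_params: dict = field(
        default_factory=lambda: {"max_terms": 11, "max_knots": 16}
    )
    select_on: str = "train"
    rl_definition: str = "density_times_mrna"
    extract: ExtractConfig = field(default_factory=ExtractConfig)
    seed: int = 0
    outdir: str = "txpred_out"


def cell_seed(seed: int, target: str, scope: str, scheme: str, model: str) -> int:
    tag = f"{target}|{scope}|{scheme}|{model}".encode()
    return (zlib.crc32(tag) ^ seed) & 0x7FFFFFFF


@dataclass
class ExperimentReport:
    summary: pd.DataFrame
    families: dict[tuple[str, str, str, str], PredictorFamily]
    failures: dict[tuple[str, str, str, str], str]
    outdir: Path


def _load_data(cfg: RunConfig):
    if cfg.synth is not None:
        synth = replace(cfg.synth, seed=cfg.seed)
        records = generate_transcriptome(synth)
        extraction = extract_features(records, replace(cfg.extract, seed=cfg.seed))
        expression, _ = generate_expression(records, extraction.table, synth)
    else:
        if cfg.orf_path is None or cfg.expression_path is None:
            raise ValueError("non-synthetic runs need orf_path and expression_path")
        records, _ = read_transcripts(
            cfg.utr5_path, cfg.orf_path, cfg.utr3_path, cfg.pars_path
        )
        expression = read_expression(cfg.expression_path)
        records, expression = join_universe(records, expression)
        extraction = extract_features(records, replace(cfg.extract, seed=cfg.seed))
    codons = {r.gene_id: len(r.orf) // 3 for r in records}
    expression = derive_targets(expression, cfg.rl_definition, codons)
    return records, extraction, expression


def log_targets(expression: pd.DataFrame) -> pd.DataFrame:
    """Log-transform every target column; non-positive values become missing."""
    out = {}
    for col in expression.columns:
        v = expression[col].astype(float)
        out[col] = np.log(v.where(v > 0))
    return pd.DataFrame(out, index=expression.index)


def run_experiment(cfg: RunConfig) -> ExperimentReport:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, extraction, expression = _load_data(cfg)
    ly = log_targets(expression)
    write_feature_table(extraction.table, outdir / "features_schemeA.tsv")
    extraction.catalogue.to_tsv(outdir / "catalogue.tsv")

    hook = None
    if "B" in cfg.schemes:
        hook = make_scheme_b_hook(records, expression["mrna"],
                                  extraction.tai_weights,
                                  cfg.extract.cai_top_fraction)
        cat_b = build_catalogue(list(extraction.table.columns), scheme="B")
    cat_a = extraction.catalogue

    families: dict[tuple[str, str, str, str], PredictorFamily] = {}
    failures: dict[tuple[str, str, str, str], str] = {}
    rows = []
    for target in cfg.targets:
        for scope in cfg.scopes:
            for scheme in cfg.schemes:
                cat = cat_a if scheme == "A" else cat_b
                candidates = cat.scope_names(scope)
                for model in cfg.models:
                    key = (target, scope, scheme, model)
                    try:
                        fam = build_family(
                            extraction.table, ly[target], candidates,
                            target=target, scope=scope, scheme=scheme,
                            model_kind=model,
                            n_replicates=cfg.n_replicates,
                            seed=cell_seed(cfg.seed, *key),
                            max_features=cfg.max_features,
                            epsilon=cfg.epsilon,
                            mars_params=cfg.mars_params,
                            select_on=cfg.select_on,
                            scheme_b_hook=hook if scheme == "B" else None,
                        )
                    except Exception as exc:  # noqa: BLE001 - cell isolation
                        log.error("cell %s failed: %s", key, exc)
                        failures[key] = str(exc)
                        continue
                    families[key] = fam
                    report = fam.to_report()
                    name = f"cell_{target}_{scope}_{scheme}_{model}"
                    with open(outdir / f"{name}.json", "w") as fh:
                        json.dump(report, fh, indent=1, sort_keys=True)
                    with open(outdir / f"{name}_prevalence.tsv", "w") as fh:
                        fh.write("feature\tprevalence\n")
                        for f, c in sorted(fam.prevalence.items(),
                                           key=lambda kv: (-kv[1], kv[0])):
                            if c > 0:
                                fh.write(f"{f}\t{c}\n")
                    rows.append({
                        "target": target, "scope": scope, "scheme": scheme,
                        "model": model,
                        "median_validation_corr": report["median_validation_corr"],
                        "mean_n_features": report["mean_n_features"],
                    })
    summary = pd.DataFrame(
        rows, columns=["target", "scope", "scheme", "model",
                       "median_validation_corr", "mean_n_features"],
    )
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("\t".join(summary.columns) + "\n")
        for _, r in summary.iterrows():
            fh.write(
                f"{r['target']}\t{r['scope']}\t{r['scheme']}\t{r['model']}\t"
                f"{r['median_validation_corr']:.6g}\t{r['mean_n_features']:.6g}\n"
            )
    _write_run_info(cfg, outdir)
    return ExperimentReport(summary, families, failures, outdir)


def _write_run_info(cfg: RunConfig, outdir: Path) -> None:
    blob = repr(dataclasses.asdict(cfg)).encode()
    info = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "n_replicates": cfg.n_replicates,
    }
    with open(outdir / "run_info.json", "w") as fh:
        json.dump(info, fh, indent=1, sort_keys=True)


def summarize_cells(outdir: str | Path) -> pd.DataFrame:
    """Re-derive the grid summary from the per-cell JSON reports."""
    rows = []
    for path in sorted(Path(outdir).glob("cell_*.json")):
        if path.stem.endswith("_prevalence"):
            continue
        with open(path) as fh:
            rep = json.load(fh)
        rows.append({
            "target": rep["target"], "scope": rep["scope"],
            "scheme": rep["scheme"], "model": rep["model_kind"],
            "median_validation_corr": rep["median_validation_corr"],
            "mean_n_features": rep["mean_n_features"],
        })
    return pd.DataFrame(rows)
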
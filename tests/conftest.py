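import logging

import pytest

from txpred.extract import ExtractConfig, extract_features
from txpred.io_formats import derive_targets
from txpred.pipeline import log_targets
from txpred.synthetic import generate_expression, generate_transcriptome, profile_config

logging.getLogger("txpred").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_config():
    return profile_config("tiny", seed=11)


@pytest.fixture(scope="session")
def tiny_records(tiny_config):
    return generate_transcriptome(tiny_config)


@pytest.fixture(scope="session")
def tiny_extraction(tiny_records):
    return extract_features(tiny_records, ExtractConfig(seed=11))


@pytest.fixture(scope="session")
def tiny_expression(tiny_records, tiny_extraction, tiny_config):
    expr, latent = generate_expression(tiny_records, tiny_extraction.table,
                                       tiny_config)
    return derive_targets(expr), latent


@pytest.fixture(scope="session")
def tiny_log_targets(tiny_expression):
    return log_targets(tiny_expression[0])


@pytest.fixture(scope="session")
def standard_bundle():
    """1000-gene planted-truth dataset for recovery studies (built once)."""
    cfg = profile_config("standard", seed=5)
    records = generate_transcriptome(cfg)
    extraction = extract_features(records, ExtractConfig(seed=5))
    expr, latent = generate_expression(records, extraction.table, cfg)
    return cfg, records, extraction, derive_targets(expr), latent
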
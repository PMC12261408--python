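import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import atcpred as ap

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_corpus() -> ap.SyntheticCorpus:
    """A 40-drug corpus with a shallow tree; used by pipeline-level tests."""
    return ap.generate_corpus(
        ap.SyntheticConfig(n_drugs=40, branching=(2, 2, 1, 1), seed=11)
    )


@pytest.fixture(scope="session")
def tiny_problem(tiny_corpus):
    """Level-2 table, drug similarities and WHS ATC matrix for the tiny corpus."""
    table = tiny_corpus.truth[2]
    sims = {c: ap.build_similarity_matrix(tiny_corpus.drugs, c) for c in ("CS", "DDI", "SE")}
    atc = ap.atc_similarity_matrix(table.code_labels, "whs", 2).values
    return table, sims, atc


@pytest.fixture()
def small_model_cfg() -> ap.ModelConfig:
    return ap.ModelConfig(
        conv_kernel=8, conv_stride=4, model_width=16, n_heads=4,
        ffn_hidden=32, n_blocks=1, dropout=0.1, seed=5,
    )


@pytest.fixture()
def fast_train_cfg() -> ap.TrainConfig:
    return ap.TrainConfig(epochs=2, batch_size=16, learning_rate=1e-3, seed=5)
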
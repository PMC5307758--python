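import numpy as np
import pandas as pd
import pytest

from markerconcord import GeneratorConfig, emit_cq_table, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """30-sample noise-free cohort used across modules."""
    cfg = GeneratorConfig(
        n_samples=30,
        failure_rate=0.0,
        replicate_sd=0.0,
        run_gene_offset_sd=0.0,
        seed=123,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cq(small_cohort):
    return emit_cq_table(small_cohort)


def make_cq_frame(rows):
    """rows: (sample_id, run_id, gene, replicate, cq-or-None)."""
    return pd.DataFrame(
        rows, columns=["sample_id", "run_id", "gene", "replicate", "cq"]
    ).astype({"cq": float})


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
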
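import numpy as np
import pandas as pd
import pytest

from zdecay import (
    ExpressionMatrix,
    SimulationParams,
    generate_mzt_experiment,
    normalize_expression,
)


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        seed=11,
        n_decay=50,
        n_zga=20,
        n_stable=30,
        n_spikeins=10,
        noise_sd=0.05,
        n_replicates=2,
    )


@pytest.fixture(scope="session")
def small_experiment(small_params):
    return generate_mzt_experiment(small_params)


@pytest.fixture(scope="session")
def small_norm(small_experiment):
    matrix, _ = small_experiment
    return normalize_expression(matrix)


def make_matrix(values: dict, meta: dict, spikein_prefix: str = "ERCC-") -> ExpressionMatrix:
    """Build a tiny ExpressionMatrix from plain dicts (helper, not a fixture).

    values: gene_id -> list of abundances per sample; meta: sample_id ->
    (stage, condition, replicate).
    """
    samples = list(meta)
    frame = pd.DataFrame.from_dict(values, orient="index", columns=samples, dtype=float)
    metadata = pd.DataFrame(
        [{"stage": s, "condition": c, "replicate": r} for s, c, r in meta.values()],
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionMatrix(values=frame, metadata=metadata, spikein_prefix=spikein_prefix)


@pytest.fixture
def four_sample_meta():
    return {
        "z1": ("zygote", "WT", 1),
        "z2": ("zygote", "WT", 2),
        "t1": ("2cell", "WT", 1),
        "t2": ("2cell", "WT", 2),
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
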
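import numpy as np
import pandas as pd
import pytest

from consnet.config import PipelineConfig
from consnet.containers import CountMatrix
from consnet.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default synthetic study, fixed seed."""
    cfg = PipelineConfig(seed=11, n_perm=1000)
    cfg.synth.seed = 11
    return run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_counts(array, dataset_id="ds0", condition="A", prefix="g"):
    array = np.asarray(array)
    genes = [f"{prefix}{i}" for i in range(array.shape[0])]
    samples = [f"s{j}" for j in range(array.shape[1])]
    return CountMatrix(pd.DataFrame(array, index=genes, columns=samples),
                       dataset_id=dataset_id, condition=condition)
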
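import numpy as np
import pytest

from leukodyn import LeslieParams, table4_scenario


@pytest.fixture(scope="session")
def stage_params() -> dict[str, LeslieParams]:
    return {stage: table4_scenario(stage) for stage in ("early", "acute", "chronic")}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20220922)


def random_positive_params(rng: np.random.Generator, n: int) -> list[LeslieParams]:
    """Random positive Leslie parameter sets, rates ~ Uniform(0.05, 2)."""
    draws = rng.uniform(0.05, 2.0, size=(n, 5))
    return [LeslieParams(r1=d[0], c1=d[1], b=d[2], r2=d[3], c2=d[4]) for d in draws]
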
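import numpy as np
import pandas as pd
import pytest

from mirreg.core_io import NORMAL, TUMOR, ExpressionBundle
from mirreg.synthetic_data import SimConfig, generate


def bundle_from_array(
    values: np.ndarray,
    detection: np.ndarray | None = None,
    scale: str = "raw",
    feature_kind: str = "gene",
    feature_ids: list[str] | None = None,
) -> ExpressionBundle:
    """Build a paired bundle from a features x (2*n_patients) array.

    Columns are ordered tumor block then normal block: P1T..PkT, P1N..PkN.
    """
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    assert n_samp % 2 == 0
    k = n_samp // 2
    patients = [f"P{i}" for i in range(1, k + 1)]
    sample_ids = [f"{p}T" for p in patients] + [f"{p}N" for p in patients]
    design = [(p, TUMOR) for p in patients] + [(p, NORMAL) for p in patients]
    if feature_ids is None:
        feature_ids = [f"G{i}" for i in range(1, n_feat + 1)]
    if detection is None:
        detection = np.ones_like(values, dtype=bool)
    return ExpressionBundle(
        values=pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        detection=pd.DataFrame(detection, index=feature_ids, columns=sample_ids),
        design=design,
        scale=scale,
        feature_kind=feature_kind,
    )


@pytest.fixture(scope="session")
def sim_default():
    """Default-condition synthetic dataset (seed 17)."""
    return generate(SimConfig(rng_seed=17))


@pytest.fixture(scope="session")
def sim_zero_noise():
    """Zero-noise synthetic dataset: planted structure exactly recoverable."""
    return generate(SimConfig(rng_seed=17, noise_sd=0.0))
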
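import numpy as np
import pandas as pd
import pytest

import pathsub as ps


@pytest.fixture(scope="session")
def small_cohort():
    """60-sample, 3-subtype cohort with a clear (2 SD) planted structure."""
    return ps.make_cohort(n_samples=60, n_genes=200, k=3, effect=2.0,
                          censor_rate=0.2, seed=1)


@pytest.fixture(scope="session")
def small_enrichment(small_cohort):
    coll = ps.marker_geneset_collection(small_cohort, n_random=10, seed=2)
    return ps.score_enrichment(small_cohort.expression, coll)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_distance(points: np.ndarray) -> np.ndarray:
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d


@pytest.fixture(scope="session")
def exp_survival():
    """200 uncensored exponential survivors in two hazard groups."""
    gen = np.random.default_rng(7)
    h = np.repeat([0.01, 0.03], 100)
    t = gen.exponential(1.0 / h)
    surv = pd.DataFrame({"time": t, "event": 1},
                        index=[f"s{i}" for i in range(200)])
    groups = pd.Series(np.repeat(["a", "b"], 100), index=surv.index)
    return surv, groups
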
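import numpy as np
import pandas as pd
import pytest

import roctree as rt


def make_frame(values: dict[str, list], remitted: list[bool]) -> pd.DataFrame:
    """Tiny cohort table from raw feature columns and labels."""
    n = len(remitted)
    cols = {"subject_id": [f"s{i:02d}" for i in range(n)],
            "cohort": "toy", "remitted": remitted}
    cols.update(values)
    return pd.DataFrame(cols)


def random_frame(rng: np.random.Generator, n: int, n_features: int) -> pd.DataFrame:
    feats = {f"f{j}": rng.integers(0, 8, size=n).astype(float)
             for j in range(n_features)}
    remitted = (rng.random(n) < 0.5).tolist()
    if all(remitted) or not any(remitted):
        remitted[0] = not remitted[0]
    return make_frame(feats, remitted)


@pytest.fixture(scope="session")
def paper_cohort() -> pd.DataFrame:
    """One deterministic draw of the canonical two-cohort configuration."""
    return rt.simulate_cohort(rt.default_paper_config(), seed=1234)


@pytest.fixture(scope="session")
def test_cohort(paper_cohort) -> pd.DataFrame:
    return paper_cohort[paper_cohort["cohort"] == "test"]


@pytest.fixture(scope="session")
def validation_cohort(paper_cohort) -> pd.DataFrame:
    return paper_cohort[paper_cohort["cohort"] == "validation"]
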
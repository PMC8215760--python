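import numpy as np
import pandas as pd
import pytest

from plastisphere import synthetic as syn
from plastisphere.containers import CountMatrix


@pytest.fixture(scope="session")
def default_series():
    """The standard synthetic incubation (shared; treat as read-only)."""
    scenario = syn.default_succession_scenario(seed=11)
    counts, truth = syn.generate_community_series(scenario)
    return scenario, counts, truth


@pytest.fixture(scope="session")
def reference_collection():
    """Small reference genome collection with planted motif carriers."""
    scenario = syn.ReferenceScenario(n_genomes=20, seed=21)
    return scenario, syn.generate_reference_collection(scenario)


@pytest.fixture()
def toy_counts():
    """Hand-sized count matrix: 2 treatments x 3 days x 2 replicates."""
    rng = np.random.default_rng(5)
    samples, meta = [], []
    cols = {}
    for treatment in ("control", "treated"):
        for day in (1, 7, 42):
            for rep in (1, 2):
                sid = f"{treatment}.d{day}.r{rep}"
                samples.append(sid)
                meta.append({"sample_id": sid, "treatment": treatment,
                             "day": day, "replicate": rep})
                cols[sid] = rng.integers(0, 50, size=4)
    counts = pd.DataFrame(cols, index=[f"t{i}" for i in range(4)])
    metadata = pd.DataFrame(meta).set_index("sample_id")
    return CountMatrix(counts, metadata)


def make_count_matrix(values, treatments=None, days=None, replicates=None):
    values = pd.DataFrame(values)
    n = values.shape[1]
    values.columns = [f"s{i}" for i in range(n)]
    values.index = [f"t{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame({
        "treatment": treatments or ["x"] * n,
        "day": days or [1] * n,
        "replicate": replicates or list(range(1, n + 1)),
    }, index=values.columns)
    return CountMatrix(values, meta)
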
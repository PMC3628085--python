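import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import famshare as fs

settings.register_profile("suite", derandomize=True, max_examples=30,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully structured cohort: all four household types."""
    cfg = fs.SimulationConfig(n_families_by_type=(3, 3, 2, 3), n_taxa=120,
                              depth_meanlog=math.log(4000), depth_sdlog=0.2,
                              seed=11)
    table, tree, metadata = fs.simulate_dataset(cfg)
    return cfg, table, tree, metadata


@pytest.fixture(scope="session")
def rarefied_cohort(small_cohort):
    cfg, table, tree, metadata = small_cohort
    table = fs.rarefy(fs.filter_by_depth(table, 2000), 2000, seed=5)
    keep = set(table.sample_ids)
    metadata = metadata.subset([s in keep for s in metadata.frame.index])
    return cfg, table, tree, metadata


@pytest.fixture
def couples_metadata():
    """12 households, one couple each, forehead samples only."""
    rows = []
    for f in range(12):
        for role, tag in (("adult_M", "M"), ("adult_F", "F")):
            rows.append({
                "sample_id": f"F{f:02d}.{tag}.forehead",
                "host_id": f"F{f:02d}.{tag}", "family_id": f"F{f:02d}",
                "body_site": "forehead", "species": "human", "role": role,
                "age": 35.0, "has_dog": False, "has_cat": False,
                "family_size": 2})
    return fs.SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


def euclidean_dm(points, ids):
    from skbio import DistanceMatrix
    pts = np.asarray(points, dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix(d, ids)
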
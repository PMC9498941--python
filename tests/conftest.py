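import numpy as np
import pandas as pd
import pytest

import tmapanel as tp


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort, small enough for fast unit tests."""
    cfg = tp.CohortConfig(
        seed=11,
        groups=[
            tp.GroupSpec("grpA", 20, list(range(0, 30)), 2.0),
            tp.GroupSpec("grpB", 20, list(range(30, 60)), 2.0),
            tp.GroupSpec("grpC", 20, list(range(60, 90)), 2.0),
            tp.GroupSpec("grpD", 20, list(range(90, 120)), 2.0),
        ],
        n_normal_samples=8,
        n_urna_controls=4,
        amplicon_prevalence=0.1,
        tracked_genes=[120],
        planted_fail_read_count=[0, 40],
        planted_fail_low_quality=[15, 70],
    )
    return cfg, tp.generate_cohort(cfg)


@pytest.fixture()
def random_pcm():
    """Random 50-gene x 10-sample count matrix with 5 negative controls."""
    rng = np.random.default_rng(7)
    genes = [f"G{i:03d}" for i in range(50)]
    negs = [f"NEG{i}" for i in range(5)]
    samples = [f"S{i}" for i in range(10)]
    counts = pd.DataFrame(
        rng.integers(0, 5000, size=(55, 10)),
        index=genes + negs,
        columns=samples,
    )
    probe_class = pd.Series(["gene"] * 50 + ["neg_ctrl"] * 5, index=counts.index)
    hk = pd.Series([True] * 9 + [False] * 46, index=counts.index)
    return tp.ProbeCountMatrix(counts=counts, probe_class=probe_class, housekeeping=hk)
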
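import numpy as np
import pytest

from gcimsvoc.io import Chromatogram, Cohort, SampleRecord
from gcimsvoc.simulate import SimulationConfig


def make_chrom(matrix, ret=None, drift=None, sample_id="s"):
    matrix = np.asarray(matrix, dtype=float)
    if ret is None:
        ret = np.arange(matrix.shape[0], dtype=float)
    if drift is None:
        drift = 5.0 + np.arange(matrix.shape[1], dtype=float)
    return Chromatogram(sample_id=sample_id, intensity=matrix,
                        retention_axis=np.asarray(ret, float),
                        drift_axis=np.asarray(drift, float))


def make_cohort(matrices, groups=None):
    groups = groups or ["A"] * len(matrices)
    records, chroms = [], {}
    for i, (m, g) in enumerate(zip(matrices, groups)):
        sid = f"s{i}"
        records.append(SampleRecord(sample_id=sid, group=g))
        chroms[sid] = make_chrom(m, sample_id=sid)
    return Cohort(records=records, chromatograms=chroms)


@pytest.fixture
def small_sim_config():
    """Fast simulation settings: coarse grid, two groups."""
    return SimulationConfig(group_n={"CD": 13, "RCD": 7}, n_ret=40,
                            n_drift=60, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
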
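import numpy as np
import pytest

from inph_rsfc.atlas import Roi, RoiTable
from inph_rsfc.simulate import SimConfig, SubjectSpec


@pytest.fixture(scope="session")
def aal90():
    return RoiTable.default()


@pytest.fixture
def rois6():
    """Tiny 3-left/3-right table with homologous pairs."""
    entries = []
    rid = 0
    for base, (x, y, z) in [("Alpha", (40, 10, 5)), ("Beta", (30, -20, 40)), ("Gamma", (10, -60, 10))]:
        for hemi, sx in (("L", -1), ("R", 1)):
            rid += 1
            entries.append(Roi(rid, f"{base}_{hemi}", hemi, (sx * x, y, z)))
    return RoiTable(entries)


@pytest.fixture
def small_config():
    """Fast 6-ROI configuration for pipeline-level tests."""
    return SimConfig(n_rois=6, n_volumes=60, seed=11)


@pytest.fixture
def small_specs():
    specs = [SubjectSpec(f"P{k}", "iNPH", gs_gait=2 + (k % 2), gs_cognition=2, gs_urinary=1)
             for k in range(5)]
    specs += [SubjectSpec(f"C{k}", "HC") for k in range(5)]
    return specs


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
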
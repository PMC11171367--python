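import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_panel():
    """One 20-variant LD block, moderate correlation, 2000 individuals."""
    from smrprs import LdBlockSpec, make_reference_panel

    spec = LdBlockSpec(n_blocks=1, block_size=20, within_block_corr=0.6, maf_range=(0.15, 0.45))
    return make_reference_panel(spec, 2000, seed=101)


@pytest.fixture(scope="session")
def multi_block_panel():
    """Ten independent 10-variant blocks for scan/PRS-level tests."""
    from smrprs import LdBlockSpec, make_reference_panel

    spec = LdBlockSpec(n_blocks=10, block_size=10, within_block_corr=0.5, maf_range=(0.1, 0.5))
    return make_reference_panel(spec, 1500, seed=202)


def toy_scoreset(cases, controls, label="toy"):
    from smrprs import ScoreSet

    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    return ScoreSet(
        scores=np.concatenate([cases, controls]),
        labels=np.concatenate([np.ones(cases.size, int), np.zeros(controls.size, int)]),
        label=label,
    )


@pytest.fixture
def make_scoreset():
    return toy_scoreset
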
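import numpy as np
import pytest

import ternuseye as te


@pytest.fixture(scope="session")
def default_params():
    return te.GeneratorParams()


@pytest.fixture(scope="session")
def e1_design():
    return te.build_design("E1", seed=11)


@pytest.fixture(scope="session")
def small_session(default_params):
    """One simulated participant on a reduced E1 design (4 trials/cell)."""
    from ternuseye.design import subset_per_cell
    design = subset_per_cell(te.build_design("E1", seed=11), 4)
    recs, responses = te.simulate_session(design, default_params, seed=101,
                                          session_id="sub01_E1")
    return design, recs, responses


@pytest.fixture(scope="session")
def default_report():
    """Full default analysis: 6 virtual participants, complete E1 design.

    Session-scoped because several end-to-end checks (main sequence,
    freezing-effect sign recovery, late inhibition cluster) share it.
    """
    cfg = te.PipelineConfig(experiments=["E1"], n_subjects=6, seed=0,
                            n_iterations=1000)
    return te.run_pipeline(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
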
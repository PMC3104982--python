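import numpy as np
import pytest

from arrayvar import (
    SimulationConfig,
    build_design_matrices,
    build_paper_design,
    simulate_expression,
)
from arrayvar.simdata import study_condition_sds

# Study-condition generating SDs: pooled technical 0.16 (residual 0.10,
# stim/amp splitting the remainder), pooled biological 0.06, interactions 0.
PAPER_SD = study_condition_sds()


@pytest.fixture(scope="session")
def paper_design():
    return build_paper_design(5, 2)


@pytest.fixture(scope="session")
def paper_bundle(paper_design):
    return build_design_matrices(paper_design)


@pytest.fixture(scope="session")
def small_sim(paper_design, paper_bundle):
    """300-gene simulation at study-condition SDs with LPS effects."""
    cfg = SimulationConfig(
        n_genes=300,
        true_sd=PAPER_SD,
        lps_effect_sd=1.0,
        lps_effect_nonzero_fraction=0.35,
        baseline_sd=1.0,
        seed=20,
    )
    matrix, truth = simulate_expression(paper_design, cfg, bundle=paper_bundle)
    return matrix, truth, cfg
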
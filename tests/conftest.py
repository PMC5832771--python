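import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import peptisite as ps


@pytest.fixture(scope="session")
def dimer():
    return ps.build_toy_dimer()


@pytest.fixture(scope="session")
def peptide():
    return ps.build_peptide()


@pytest.fixture(scope="session")
def small_runs(dimer, peptide):
    """Three short diffusion runs plus truth table (shared, read-only)."""
    spec = ps.default_diffusion_spec(n_runs=3, frames_per_run=300, seed=3)
    runs, truth = ps.simulate_diffusion_runs(dimer, peptide, spec)
    return runs, truth, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
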
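import numpy as np
import pytest

from glycoclam.synthetic import (
    ToyGlycoproteinSpec,
    TwoStateSpec,
    generate_toy_glycoprotein_ensemble,
    generate_two_state_ensemble,
)


@pytest.fixture(scope="session")
def small_ensemble():
    """Fast-switching two-state ensemble with well-sampled kinetics."""
    spec = TwoStateSpec(
        rate_close=0.03, rate_open=0.02, n_traj=60, n_frames=5000, seed=11
    )  # relaxation 20 ns, aggregate 60 us = 3000x relaxation
    return spec, generate_two_state_ensemble(spec)


@pytest.fixture(scope="session")
def toy_trajectory():
    """Toy glycoprotein trajectory visiting both basins, with glycan contact.

    The open basin sits at 5.5 nm so far-open conformations (d > 5.2 nm)
    actually occur in the short fixture.
    """
    base = TwoStateSpec(
        rate_close=0.1, rate_open=0.05, mean_open=5.5, n_traj=1, n_frames=150, seed=5
    )
    spec = ToyGlycoproteinSpec.from_two_state(base, n_frames=150, contact_when_closed=0.8)
    return spec, generate_toy_glycoprotein_ensemble(spec)
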
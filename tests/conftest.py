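import numpy as np
import pytest

import rgflex


@pytest.fixture(scope="session")
def hinge():
    """Default two-domain hinge protein with ground truth."""
    return rgflex.make_hinge_protein()


@pytest.fixture(scope="session")
def helix():
    """10-residue poly-ALA alpha helix (plants i -> i+4 hydrogen bonds)."""
    return rgflex.make_toy_peptide("AAAAAAAAAA", "helix")


@pytest.fixture(scope="session")
def hinge_constraints(hinge):
    return rgflex.build_constraints(hinge.open)


@pytest.fixture(scope="session")
def biased_ensemble(hinge):
    """30 Rg-biased frames from the open state toward the closed Rg."""
    cfg = rgflex.SamplerConfig(n_conformers=30, seed=42)
    return rgflex.generate_ensemble(
        hinge.open, cfg, rgflex.RgConstraint(hinge.rg_closed, 0.1))


@pytest.fixture(scope="session")
def unbiased_ensemble(hinge):
    cfg = rgflex.SamplerConfig(n_conformers=30, seed=42)
    return rgflex.generate_ensemble(hinge.open, cfg)


@pytest.fixture(scope="session")
def random_ensemble(hinge):
    """50 jittered copies of the open state (fast, for ranking/cluster tests)."""
    rng = np.random.default_rng(5)
    frames = [hinge.open.coords + rng.normal(0, s, hinge.open.coords.shape)
              for s in np.linspace(0.05, 2.0, 50)]
    return rgflex.Ensemble(hinge.open, frames)
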
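import numpy as np
import pytest

from kapflex import synthetic_data as syn


@pytest.fixture(scope="session")
def default_template():
    return syn.DimerTemplate()


@pytest.fixture(scope="session")
def planted_template():
    return syn.DimerTemplate(d_planted=(60.0, 120.0))


@pytest.fixture(scope="session")
def planted_dimer(planted_template):
    """Asymmetric dumbbell dimer with planted (dA*, dB*) = (60, 120) Å."""
    return syn.build_dumbbell_dimer(planted_template, np.random.default_rng(7))


@pytest.fixture(scope="session")
def rbcc_model():
    """RBCC-only construct: rod plus two terminal modules."""
    return syn.build_rbcc_dumbbell()


@pytest.fixture(scope="session")
def small_template():
    """Down-scaled template for tests that rebuild many models."""
    return syn.DimerTemplate(module_beads=20, cc_beads=20, mobile_beads=12,
                             linker_residues=50, module_radius=25.0,
                             mobile_radius=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def sphere_beads(n: int, radius: float, seed: int = 0) -> np.ndarray:
    """Quasi-uniform bead filling of a solid sphere (test helper)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1)[:, None]
    r = radius * rng.uniform(size=n) ** (1.0 / 3.0)
    return pts * r[:, None]
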
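import numpy as np
import pytest

from serrsmap import correct_map
from serrsmap.synth import GeneratorConfig, default_phantom_layout, simulate_phantom


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def phantom(gen_config):
    """One default three-region phantom: (raw map, truth, rois)."""
    regions, rois, extent = default_phantom_layout(gen_config)
    spectral_map, truth = simulate_phantom(regions, gen_config, extent)
    return spectral_map, truth, rois


@pytest.fixture(scope="session")
def corrected_phantom(phantom):
    """The same phantom after per-point baseline correction (expensive, shared)."""
    spectral_map, truth, rois = phantom
    return correct_map(spectral_map), truth, rois


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def dense_whittaker(y: np.ndarray, w: np.ndarray, lam: float, d: int) -> np.ndarray:
    """Independent dense normal-equations oracle for the Whittaker smoother."""
    n = len(y)
    D = np.diff(np.eye(n), d, axis=0)
    A = np.diag(w) + lam * (D.T @ D)
    return np.linalg.solve(A, w * y)


def pooled_ttest(a, b):
    """Textbook pooled-variance two-sample t-test (independent oracle)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p
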
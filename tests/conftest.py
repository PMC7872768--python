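import numpy as np
import pytest

from scnkit.synthetic_cohort import SyntheticConfig, generate_cohort


def random_graph(rng: np.random.Generator, n: int, p: float | None = None,
                 n_edges: int | None = None) -> np.ndarray:
    """Random undirected simple graph as a uint8 adjacency matrix."""
    iu, ju = np.triu_indices(n, 1)
    if n_edges is not None:
        pick = rng.choice(iu.size, size=min(n_edges, iu.size), replace=False)
        mask = np.zeros(iu.size, dtype=bool)
        mask[pick] = True
    else:
        mask = rng.random(iu.size) < (p if p is not None else 0.3)
    a = np.zeros((n, n), dtype=np.uint8)
    a[iu[mask], ju[mask]] = 1
    a[ju[mask], iu[mask]] = 1
    return a


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One 30-ROI synthetic cohort shared by fast tests."""
    cfg = SyntheticConfig(
        n_roi=30, n_factors=3, atrophy_rois=(12, 13), clinical_target_roi=12,
        perturbed_rois=tuple(range(5)), seed=42,
    )
    volumes, cohort, truth = generate_cohort(cfg)
    return cfg, volumes, cohort, truth


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size (90 ROI, 24/26) synthetic cohort at the generator defaults."""
    cfg = SyntheticConfig(seed=1)
    volumes, cohort, truth = generate_cohort(cfg)
    return cfg, volumes, cohort, truth
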
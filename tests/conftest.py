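import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixedde import CountMatrix, DesignTable

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def small_matrix() -> CountMatrix:
    return CountMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        np.array([[10, 20, 30, 40], [5, 5, 5, 5], [0, 1, 2, 3]], dtype=float),
    )


@pytest.fixture
def small_design() -> DesignTable:
    return DesignTable(
        ["s1", "s2", "s3", "s4"],
        ["A", "A", "B", "B"],
        {"gender": ["M", "F", "M", "F"]},
    )


@pytest.fixture(scope="session")
def acceptance_grid():
    """Preprocessing grid shared by the filtering-loss and BCV checks.

    5,000-gene fixed-effect matrices over replicates {2,4,6,10} x DEG
    proportions {0.1,0.2,0.3} x seeds {1,2,3}; for each cell the percent
    of true DEGs lost in preprocessing and the post-preprocessing BCV.
    """
    from mixedde import SimConfig, preprocess, simulate_fixed
    from mixedde.dispersion import estimate_bcv

    rows = []
    for reps in (2, 4, 6, 10):
        for prop in (0.1, 0.2, 0.3):
            for seed in (1, 2, 3):
                sim = simulate_fixed(
                    SimConfig(
                        n_genes=5000, replicates=reps,
                        deg_proportion=prop, seed=seed,
                    )
                )
                _, report = preprocess(
                    sim.matrix, sim.design, truth_deg=sim.truth_deg
                )
                retained = sim.matrix.subset_genes(report.retained_ids)
                bcv = estimate_bcv(retained, sim.design).bcv
                rows.append(
                    {
                        "replicates": reps,
                        "deg_proportion": prop,
                        "seed": seed,
                        "deg_loss_percent": report.deg_loss_percent,
                        "post_bcv": bcv,
                    }
                )
    return rows
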
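import numpy as np
import pandas as pd
import pytest

from thermoresp import simulate as sim
from thermoresp.io_tables import LibraryRecord, SpeciesExpression
from thermoresp.pipeline import PipelineConfig, run_pipeline_objects


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced-scale synthetic study bundle shared across tests."""
    return sim.simulate_dataset(sim.small_config(11))


@pytest.fixture(scope="session")
def small_result(small_bundle):
    """Full pipeline run on the small bundle (orthogroup quorums 5/4)."""
    cfg = PipelineConfig(seed=11, presence_min=5, expressed_min=4, n_resamples=200)
    b = small_bundle
    return run_pipeline_objects(
        cfg, b.metadata, b.expression, b.annotations, b.orthogroups, b.traces
    )


@pytest.fixture
def tiny_expression():
    """3 genes x 2 libraries with a boundary-case filter example."""
    tpm = pd.DataFrame(
        {"lib1": [12.0, 5.0, 20.0], "lib2": [8.0, 5.0, 40.0]},
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return SpeciesExpression("spA", tpm)


@pytest.fixture
def tiny_metadata():
    return [
        LibraryRecord("lib1", "spA", "control", "arid"),
        LibraryRecord("lib2", "spA", "hot", "arid"),
    ]


def make_lmm_data(
    rng: np.random.Generator,
    counts,
    beta_cold: float,
    beta_hot: float,
    sigma_sp: float,
    sigma_res: float,
    intercept: float = 5.0,
) -> pd.DataFrame:
    """Simulate library-level responses from the random-intercept model."""
    rows = []
    for s, (nc, ncold, nh) in enumerate(counts):
        u = rng.normal(0, sigma_sp)
        for treatment, n, b in (
            ("control", nc, 0.0), ("cold", ncold, beta_cold), ("hot", nh, beta_hot)
        ):
            for _ in range(n):
                rows.append(
                    {
                        "species_id": f"s{s:02d}",
                        "treatment": treatment,
                        "estimate": intercept + b + u + rng.normal(0, sigma_res),
                    }
                )
    return pd.DataFrame(rows)


#: the real study's unbalanced library design (188 libraries over 20 species)
STUDY_COUNTS = [
    (2, 2, 3), (4, 4, 4), (4, 3, 4), (4, 4, 4), (1, 1, 2), (4, 3, 4), (4, 3, 4),
    (1, 1, 1), (1, 1, 1), (3, 3, 3), (4, 4, 4), (3, 4, 4), (2, 2, 1), (4, 4, 4),
    (4, 3, 4), (3, 4, 4), (4, 4, 4), (3, 4, 4), (3, 3, 3), (3, 4, 4),
]
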
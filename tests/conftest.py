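import numpy as np
import pytest

from escape_clock.forest import CopyForest, GainPosterior, forest_from_records
from escape_clock.simdata import SimConfig


@pytest.fixture
def diploid_forest():
    return CopyForest([], 1, 1, segment_id="diploid")


@pytest.fixture
def single_gain_forest():
    """CN (2,1), one gain on the major allele at t=0.3."""
    return forest_from_records([(0, None, "major", 0.3, False)], (2, 1), segment_id="gain")


@pytest.fixture
def wgd_forest():
    """CN (2,2), WGD at t=0.4."""
    return forest_from_records(
        [(0, None, "major", 0.4, True), (1, None, "minor", 0.4, True)],
        (2, 2),
        segment_id="wgd",
    )


def fixed_gain_posterior(forest, S):
    """Gain posterior repeating one forest for every draw."""
    times = np.tile(
        [n.time for n in sorted(forest.nodes.values(), key=lambda n: n.node_id)],
        (S, 1),
    )
    if times.size == 0:
        times = np.zeros((S, 0))
    return GainPosterior(forest.segment_id, topology=forest, times=times)


@pytest.fixture
def small_config():
    return SimConfig(
        cancer_types=["A", "B"],
        samples_per_type=3,
        mean_depth=80.0,
        n_segments=6,
        driver_genes=[f"DRV{i}" for i in range(1, 6)],
        pathway_gene_sets={"pwA": ["G1", "G2", "G3"], "pwB": ["H1", "H2", "H3"]},
        pathway_time_distributions={
            "pwA": {"family": "beta", "a": 2, "b": 8},
            "pwB": {"family": "beta", "a": 8, "b": 2},
        },
        draws_S=40,
        seed=123,
    )
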
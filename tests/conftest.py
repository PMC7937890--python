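import numpy as np
import pytest
from hypothesis import settings

from rsmscope.formats import Feature, GenomeAnnotation, TagLibrary
from rsmscope.synthio import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_annotation():
    """Five features on one 10 kb replicon, including a divergent pair."""
    feats = (
        Feature("g1", "coding_gene", "chr", 500, 1400, "+"),
        Feature("nc1", "ncRNA", "chr", 1900, 2060, "-"),
        # divergent head-to-head pair sharing the 4000-4120 gap
        Feature("g2", "coding_gene", "chr", 3200, 4000, "-"),
        Feature("g3", "coding_gene", "chr", 4120, 5100, "+"),
        Feature("g4", "coding_gene", "chr", 7000, 8200, "-"),
    )
    return GenomeAnnotation((("chr", 10_000),), feats)


@pytest.fixture
def small_sim_config():
    """Desk-scale-but-fast simulation: ~120 kb, shallow libraries."""
    return SimulationConfig(
        genome_length=120_000,
        n_features=60,
        n_divergent_pairs=4,
        n_repeat_groups=1,
        repeat_copies=3,
        venn_design={
            ("RsmA", "RsmE", "RsmI"): 2,
            ("RsmA",): 2,
            ("RsmE",): 2,
            ("RsmI",): 1,
        },
        pulldown_depth=40_000,
        control_depth=80_000,
        n_bio_reps={"RsmA": 2, "RsmE": 2, "RsmI": 2},
    )


def uniform_library(rng, n_tags=5000, length=50_000, sample_id="t", role="pulldown"):
    """A library of uniformly placed tags on one replicon."""
    positions = rng.integers(0, length, size=n_tags)
    strands = rng.random(n_tags) < 0.5
    return TagLibrary(
        sample_id=sample_id,
        protein="RsmA",
        role=role,
        bio_rep=1,
        tech_rep=1,
        replicons=(("chr", length),),
        tags=tuple(
            ("chr", int(p), "+" if s else "-") for p, s in zip(positions, strands)
        ),
    )
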
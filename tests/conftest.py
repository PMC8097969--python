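import numpy as np
import pandas as pd
import pytest

from svdiverge.pipeline import PipelineConfig, run_pipeline
from svdiverge.records import SV_TYPES
from svdiverge.synthetic import SimulationConfig, generate_genome_pair


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        seed=1,
        genome_length=200_000,
        n_chromosomes=1,
        sv_counts={t: 2 for t in SV_TYPES},
        sv_size_range={t: (10, 1500) for t in SV_TYPES},
        n_accessions=4,
        background_divergence=0.0,
        min_sv_spacing=4000,
        edge_margin=6000,
        short_read_depth=20.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_pair():
    """A small genome pair with 14 planted SVs, shared across tests."""
    cfg = small_config()
    genome_a, genome_b, truth = generate_genome_pair(cfg)
    return cfg, genome_a, genome_b, truth


@pytest.fixture()
def toy_matrix():
    """Deterministic two-group genotype matrix with one contrasted SV."""
    rng = np.random.default_rng(42)
    acc = [f"a{i:02d}" for i in range(12)]
    labels = pd.Series(["g1"] * 6 + ["g2"] * 6, index=acc, name="group")
    cols = {}
    cols["contrast"] = ["A"] * 6 + ["B"] * 6
    for j in range(5):
        cols[f"null{j}"] = list(rng.choice(["A", "B", "H"], size=12))
    cols["mostly_u"] = ["U"] * 10 + ["A", "B"]
    return pd.DataFrame(cols, index=acc), labels


DEMO = dict(genome_length=250_000, n_chromosomes=1, sv_count_per_type=2,
            sv_max_size=2500, n_accessions=4, short_read_depth=20,
            n_genes=12, min_sv_spacing=4000, edge_margin=6000)


@pytest.fixture(scope="session")
def demo_runs(tmp_path_factory):
    """The demonstration pipeline executed twice with the same seed."""
    base = tmp_path_factory.mktemp("pipeline")
    summary1 = run_pipeline(PipelineConfig(seed=9, **DEMO), base / "run1")
    summary2 = run_pipeline(PipelineConfig(seed=9, **DEMO), base / "run2")
    return base, summary1, summary2
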
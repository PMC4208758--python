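import numpy as np
import pandas as pd
import pytest

from hostmicro.simulate import GeneratorParams, generate_study
from hostmicro.tables import LineageTable, SampleMetadata


@pytest.fixture(scope="session")
def default_study():
    """One synthetic study at the study-design defaults."""
    return generate_study(GeneratorParams(), seed=1)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast structural tests."""
    params = GeneratorParams(
        n_plots_by_richness={1: 3, 2: 3, 3: 2},
        n_lineages=40,
        n_contaminants=4,
        n_controls=4,
    )
    return generate_study(params, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_metadata(spec):
    """Metadata from a compact spec: list of (plot, richness, [species...])."""
    rows = []
    i = 0
    for plot, richness, species_list in spec:
        for sp in species_list:
            i += 1
            rows.append({
                "sample_id": f"S{i:03d}",
                "host_individual_id": f"H{i:03d}",
                "host_species": sp,
                "plot_id": plot,
                "community_richness": richness,
            })
    return SampleMetadata(pd.DataFrame(rows))


def make_table(counts, lineages=None, samples=None):
    counts = np.asarray(counts)
    lineages = lineages or [f"L{i}" for i in range(counts.shape[0])]
    samples = samples or [f"S{j}" for j in range(counts.shape[1])]
    return LineageTable(pd.DataFrame(counts, index=lineages, columns=samples))
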
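import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from snvtrack.panel import AlleleCountPanel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_panel(
    sink_counts,
    source_counts,
    positions=None,
    species=None,
    contigs=None,
    sink_name="sink",
    source_names=None,
):
    """Small hand-built panel; counts are lists of (ref, alt) per site."""
    sink_counts = np.asarray(sink_counts)
    source_counts = np.asarray(source_counts)  # (S, J, 2)
    S, J = source_counts.shape[0], source_counts.shape[1]
    positions = positions if positions is not None else list(range(1, S + 1))
    species = species if species is not None else ["sp1"] * S
    contigs = contigs if contigs is not None else [f"{sp}_c1" for sp in species]
    keys = pd.DataFrame(
        {
            "species_id": species,
            "contig_id": contigs,
            "position": positions,
            "ref_allele": ["A"] * S,
            "alt_allele": ["G"] * S,
        }
    )
    return AlleleCountPanel(
        keys=keys,
        sink_name=sink_name,
        source_names=source_names or [f"src{j + 1}" for j in range(J)],
        sink_ref=sink_counts[:, 0],
        sink_alt=sink_counts[:, 1],
        source_ref=source_counts[:, :, 0],
        source_alt=source_counts[:, :, 1],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_source_panel():
    """Three sites, two sources, all well covered."""
    return make_panel(
        sink_counts=[(7, 3), (10, 0), (2, 8)],
        source_counts=[
            [(10, 0), (0, 10)],
            [(12, 0), (11, 1)],
            [(1, 9), (9, 3)],
        ],
    )
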
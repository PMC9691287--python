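import pandas as pd
import pytest

from bsplice.containers import CountMatrix
from bsplice.synthetic import (
    SimulationConfig,
    build_toy_annotation,
    generate_counts,
    toy_events,
)


@pytest.fixture(scope="session")
def toy():
    """Toy annotation: dict of transcripts, domain table, dict of events."""
    transcripts, domains = build_toy_annotation()
    return {t.transcript_id: t for t in transcripts}, domains, toy_events()


@pytest.fixture(scope="session")
def default_panel():
    """One default B-cell panel plus its truth (seed 7)."""
    return generate_counts(SimulationConfig(seed=7))


@pytest.fixture()
def small_matrix():
    """A tiny handmade count matrix: 4 genes x 4 samples, 2 conditions."""
    counts = pd.DataFrame(
        {
            "A_1": [10, 100, 40, 0],
            "A_2": [12, 110, 38, 0],
            "B_1": [11, 105, 42, 0],
            "B_2": [9, 95, 41, 0],
        },
        index=["g1", "g2", "g3", "g_zero"],
    )
    cond = {"A_1": "A", "A_2": "A", "B_1": "B", "B_2": "B"}
    return CountMatrix(counts, cond)
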
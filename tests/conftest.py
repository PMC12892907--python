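import pandas as pd
import pytest

import markerseg as m


@pytest.fixture(scope="session")
def gland():
    """Seed-1 healthy gland: (transcripts, observed segmentation, truth)."""
    return m.simulate_gland(m.GlandParams(seed=1))


@pytest.fixture(scope="session")
def reseg(gland):
    transcripts, observed, _ = gland
    return m.run_marker_resegmentation(observed, transcripts)


@pytest.fixture(scope="session")
def basal_ids(gland):
    _, _, truth = gland
    return {c for c, t in truth.cell_types.items() if t == "basal"}


def make_transcripts(rows):
    """Build a transcript table from (x, y, gene, qv, cell_id) tuples."""
    return pd.DataFrame(
        {
            "transcript_id": [f"t{i}" for i in range(len(rows))],
            "x": [r[0] for r in rows],
            "y": [r[1] for r in rows],
            "gene": [r[2] for r in rows],
            "qv": [float(r[3]) for r in rows],
            "cell_id": [r[4] for r in rows],
        }
    )
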
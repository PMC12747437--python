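import numpy as np
import pandas as pd
import pytest

from lear import (
    GroundTruthPair,
    SimulationSpec,
    TraceSet,
    add_localization_error,
    generate_polymer_traces,
)


def make_traceset(positions, resolution_bp=1000, roles=None, repeat_pairs=None):
    """Build a TraceSet around a raw (N, L, D) array with stub metadata."""
    positions = np.asarray(positions, dtype=float)
    n, l, _ = positions.shape
    starts = np.arange(l) * resolution_bp
    lt = pd.DataFrame(
        {
            "chrom": "chrT",
            "start": starts,
            "end": starts + resolution_bp,
            "role": roles if roles is not None else "initial",
        }
    )
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "allele_id": [f"t{i}" for i in range(n)],
            "condition": "fix",
            "burst_state": "none",
        }
    )
    return TraceSet(positions, lt, meta, repeat_pairs or [])


@pytest.fixture
def chain_gt() -> GroundTruthPair:
    """A modest noise-free chain used across tests (L=12, N=400)."""
    return generate_polymer_traces(SimulationSpec(n_loci=12, n_traces=400, seed=11))


@pytest.fixture
def noisy_chain(chain_gt) -> GroundTruthPair:
    return add_localization_error(chain_gt, 50.0, seed=12)
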
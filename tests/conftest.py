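import numpy as np
import pandas as pd
import pytest

from fpscan.genotype_io import GenotypeMatrix
from fpscan.synthetic_data import SimConfig, simulate_panel


def make_matrix(calls, ids=None, chrom=None, pos=None, groups=None):
    """Small GenotypeMatrix from a raw call array (rows = lines)."""
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    ids = ids or [f"L{i:02d}" for i in range(n)]
    lines = pd.DataFrame({
        "line_id": ids,
        "group": groups if groups is not None else "unassigned",
        "membership": np.nan,
    })
    markers = pd.DataFrame({
        "marker_id": [f"M{j:03d}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos_bp": pos if pos is not None else (np.arange(m) + 1) * 1000,
        "ref": ["A"] * m,
        "alt": ["G"] * m,
    })
    return GenotypeMatrix(lines, markers, calls)


@pytest.fixture(scope="session")
def ci_panel():
    """The desk-scale simulated panel used across recovery tests (seed 7)."""
    cfg = SimConfig.ci_scale(seed=7)
    g, truth = simulate_panel(cfg)
    return cfg, g, truth
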
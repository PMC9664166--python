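import numpy as np
import pandas as pd
import pytest

from rvomics import IntensityMatrix, SimConfig
from rvomics.simulate import gen_mapping_and_go, gen_proteome, gen_transcriptome


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast, fully featured simulation configuration."""
    return SimConfig(n_proteins=400, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(matrix, truth, transcripts, mapping, annotation) for the small config."""
    matrix, truth = gen_proteome(small_cfg)
    transcripts = gen_transcriptome(small_cfg, truth)
    mapping, annotation = gen_mapping_and_go(small_cfg, truth)
    return matrix, truth, transcripts, mapping, annotation


@pytest.fixture()
def tiny_matrix() -> IntensityMatrix:
    """Hand-written 2x(3+3) matrix for arithmetic checks."""
    data = pd.DataFrame(
        {
            "c1": [100.0, 80.0],
            "c2": [120.0, 100.0],
            "c3": [80.0, 120.0],
            "m1": [400.0, 40.0],
            "m2": [420.0, 50.0],
            "m3": [380.0, 60.0],
        },
        index=pd.Index(["A", "B"], name="accession"),
    )
    design = pd.Series(
        ["control"] * 3 + ["MCT"] * 3, index=["c1", "c2", "c3", "m1", "m2", "m3"]
    )
    return IntensityMatrix(data, design)
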
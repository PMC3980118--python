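import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pymset.io import ExpressionMatrix, ProbeAnnotation

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_expr() -> ExpressionMatrix:
    """3 probes x 4 samples, clear effect on probe p1 only."""
    values = pd.DataFrame(
        [[9.0, 9.2, 7.0, 7.1],
         [8.0, 8.1, 8.05, 7.95],
         [6.0, 6.3, 6.1, 6.2]],
        index=["p1", "p2", "p3"],
        columns=["c1", "c2", "v1", "v2"])
    groups = {"c1": "case", "c2": "case", "v1": "control", "v2": "control"}
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def ten_sample_expr() -> ExpressionMatrix:
    """100 null probes, 5 vs 5, fixed seed."""
    rng = np.random.default_rng(11)
    samples = [f"c{i}" for i in range(5)] + [f"v{i}" for i in range(5)]
    values = pd.DataFrame(rng.normal(8, 1, size=(100, 10)),
                          index=[f"p{i}" for i in range(100)],
                          columns=samples)
    groups = {s: ("case" if s.startswith("c") else "control")
              for s in samples}
    return ExpressionMatrix(values=values, groups=groups)


@pytest.fixture
def annotation() -> ProbeAnnotation:
    return ProbeAnnotation(symbol_of_probe={
        "p1": "FABP7", "p2": "FABP7", "p3": "GRM3", "p4": "", "p5": "NR1D1"})


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "BPD|SZGene\tdesc\tFabp7\tGRM3\tfabp7\n"
        "BPD|GAD\tdesc\tFABP7\tPDGFRB\tNR1D1\n"
        "arthritis|GAD\tdesc\tCOL1A1\tMMP3\n")
    return path
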
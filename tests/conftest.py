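import numpy as np
import pandas as pd
import pytest

from ublsig.gpr import read_gpr
from ublsig.matrix import assemble_matrix, IntensityMatrix
from ublsig.preprocess import preprocess_chain
from ublsig.simulate import SimulationConfig, simulate_protoarray_study


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A compact simulated array study shared across tests."""
    cfg = SimulationConfig(n_proteins=200, rng_seed=11)
    outdir = tmp_path_factory.mktemp("study")
    paths, meta, truth = simulate_protoarray_study(cfg, outdir)
    return cfg, paths, meta, truth


@pytest.fixture(scope="session")
def small_matrix(small_study):
    cfg, paths, meta, truth = small_study
    spots = {p.stem: read_gpr(p) for p in paths}
    return assemble_matrix(spots, meta, cfg.channels)


@pytest.fixture(scope="session")
def normalized_matrix(small_matrix):
    matrix, _ = preprocess_chain(small_matrix)
    return matrix


def make_protein_matrix(values: dict[str, dict[str, list[float]]],
                        meta_rows: list[tuple]) -> IntensityMatrix:
    """Hand-built protein-level matrix.

    ``values``: modifier -> {array_id: column}; ``meta_rows``: tuples of
    (array_id, experiment, cell_line, condition, nem_control).
    """
    channels = {mod: pd.DataFrame(cols) for mod, cols in values.items()}
    for df in channels.values():
        df.index = [f"P{i + 1:03d}" for i in range(len(df))]
        df.index.name = "protein_id"
    meta = pd.DataFrame(meta_rows, columns=["array_id", "experiment",
                                            "cell_line", "condition",
                                            "nem_control"]).set_index("array_id")
    return IntensityMatrix(channels=channels, meta=meta, background=None)
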
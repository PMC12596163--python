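import numpy as np
import pandas as pd
import pytest

from ecnorm import (SimulationConfig, estimate_dispersions,
                    estimate_size_factors, nb_wald_test, simulate_dataset)

SEED = 1  # global fixed seed for every deterministic simulation in the suite


@pytest.fixture(scope="session")
def default_sim():
    """Default 2000-gene x 40-sample test bed with planted ECs and DEGs."""
    cfg = SimulationConfig(seed=SEED)
    cm, meta, truth = simulate_dataset(cfg)
    return cfg, cm, meta, truth


@pytest.fixture(scope="session")
def default_de(default_sim):
    """Full differential-expression run on the default test bed."""
    _cfg, cm, meta, truth = default_sim
    sf = estimate_size_factors(cm)
    disp = estimate_dispersions(cm, sf, meta, shrink=True)
    res = nb_wald_test(cm, sf, disp, meta)
    return cm, meta, truth, sf, disp, res


@pytest.fixture()
def small_fixture(tmp_path):
    """A small simulated fixture written to disk (counts + metadata paths)."""
    from ecnorm import write_fixture_bundle

    cfg = SimulationConfig(n_genes=300, n_per_group=(8, 8), n_stable=20,
                           frac_de=0.1, seed=SEED)
    paths = write_fixture_bundle(cfg, tmp_path / "fixture")
    return cfg, paths


def make_count_frame(rows: dict[str, list[int]], samples: list[str]) -> pd.DataFrame:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "gene_id"
    return df


@pytest.fixture()
def tiny_counts_csv(tmp_path):
    """Hand-written 3x2 count matrix file."""
    path = tmp_path / "tiny.csv"
    make_count_frame({"g1": [10, 20], "g2": [0, 0], "g3": [5, 5]},
                     ["s1", "s2"]).to_csv(path)
    return path


@pytest.fixture()
def tiny_metadata_csv(tmp_path):
    path = tmp_path / "meta.csv"
    pd.DataFrame({"sample_id": ["s1", "s2", "s3", "s4"],
                  "group": ["D", "D", "C", "C"]}).to_csv(path, index=False)
    return path
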
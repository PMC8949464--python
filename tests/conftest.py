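import numpy as np
import pandas as pd
import pytest

import biduomap as bm


@pytest.fixture(scope="session")
def path3_graph():
    """Three areas in a line: A - B - C."""
    return bm.AreaGraph.from_id_pairs(["A", "B", "C"], [("A", "B"), ("B", "C")])


@pytest.fixture(scope="session")
def grid3():
    return bm.make_grid_graph(3, 3, "rook")


@pytest.fixture(scope="session")
def two_area_counts():
    """Hand-checkable 2-area x 2-stratum table (single year).

    Person-years: area A (100, 100), area B (100, 300); stratum death totals
    (2, 4) split as A=(1,1), B=(1,3).  Regional rates are 2/200 and 4/400, so
    E_A = 100*0.01 + 100*0.01 = 2 and E_B = 100*0.01 + 300*0.01 = 4.
    """
    rows = []
    for k in ("P", "O"):
        rows += [
            ("A", k, 0, 2000, 1, 100),
            ("A", k, 1, 2000, 1, 100),
            ("B", k, 0, 2000, 1, 100),
            ("B", k, 1, 2000, 3, 300),
        ]
    return pd.DataFrame(
        rows, columns=["area_id", "disease", "age_class", "year", "deaths", "population"]
    )


@pytest.fixture(scope="session")
def m4_fit():
    """A converged-enough M4 fit on a 10x10 grid, shared by reporting tests."""
    cfg = bm.SimulationConfig(rows=10, cols=10, seed=11, e_min=20, e_max=200)
    data, truth, graph = bm.simulate_bivariate_dataset(cfg)
    draws = bm.fit_model(
        "M4", data, graph, n_chains=2, n_iter=1500, burn_in=600, thin=3, seed=17
    )
    return data, truth, graph, draws


def moran_i(field: np.ndarray, graph: bm.AreaGraph) -> float:
    """Moran's spatial autocorrelation index with binary weights."""
    i, j = graph.edge_arrays()
    z = field - field.mean()
    num = 2.0 * np.sum(z[i] * z[j])  # both edge directions
    den = np.sum(z**2)
    w_sum = 2.0 * len(i)
    return graph.n_areas / w_sum * num / den
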
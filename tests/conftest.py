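import numpy as np
import pandas as pd
import pytest

from mucoseq.containers import CountMatrix
from mucoseq.simulate import SimulationConfig, simulate_all
from mucoseq.termgraph import OntologyDAG


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study reused by read-only tests."""
    return simulate_all(
        SimulationConfig(rng_seed=11, n_genes=1200, n_de_genes=60, n_sets=24)
    )


@pytest.fixture(scope="session")
def small_de(small_study):
    """DE results for the inflamed-vs-control contrast on the small study."""
    from mucoseq.containers import DesignSpec
    from mucoseq.de import (
        estimate_dispersions,
        estimate_size_factors,
        filter_low_counts,
        fit_nb_wald,
    )

    cm = filter_low_counts(small_study.counts, "auto")
    sf = estimate_size_factors(cm.counts)
    disp, trend = estimate_dispersions(cm.counts, sf, groups=cm.samples["group"])
    res = fit_nb_wald(
        cm, DesignSpec("group", ("UC.I", "Cntrl"), covariate="gender"), sf, disp
    )
    res.dispersion_trend = trend
    return cm, res


@pytest.fixture()
def toy_counts():
    """Tiny all-positive count matrix with two equal groups."""
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.poisson(50, size=(8, 6)) + 1,
        index=[f"g{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(6)],
    )
    samples = pd.DataFrame(
        {"group": ["A"] * 3 + ["B"] * 3, "gender": ["male", "female"] * 3},
        index=counts.columns,
    )
    return CountMatrix(counts, samples)


@pytest.fixture()
def toy_dag():
    """root with two subtrees: (A, B) under M1, (C) under M2; leaves deeper."""
    edges = [
        ("M1", "root", "is_a"),
        ("M2", "root", "is_a"),
        ("A", "M1", "is_a"),
        ("B", "M1", "is_a"),
        ("C", "M2", "is_a"),
        ("D", "A", "is_a"),
        ("E", "A", "part_of"),
    ]
    return OntologyDAG.from_edges(edges)
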
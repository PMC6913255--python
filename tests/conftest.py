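"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from condeseq.experiment_io import ContrastPair, CountExperiment
from condeseq.simulate import SimConfig, bundled_params, simulate_experiment


@pytest.fixture(scope="session")
def nb_params():
    return bundled_params()


@pytest.fixture(scope="session")
def pair_ab():
    return ContrastPair("A", "B")


@pytest.fixture(scope="session")
def small_sim(nb_params):
    """A 1,500-gene, 3v3 simulation with 75 planted DE genes (5%)."""
    cfg = SimConfig(n_genes=1500, n_de=75, replicates=3, seed=11)
    return simulate_experiment(cfg, nb_params, seed=11)


@pytest.fixture(scope="session")
def null_sim(nb_params):
    """A 1,500-gene, 3v3 simulation with no DE at all."""
    cfg = SimConfig(n_genes=1500, n_de=0, replicates=3, seed=7)
    return simulate_experiment(cfg, nb_params, seed=7)


@pytest.fixture(scope="session")
def null_pvalues(nb_params):
    """Raw p-values of each engine on 10 independent 2,000-gene null sims."""
    from condeseq.de_engines import ENGINES

    pair = ContrastPair("A", "B")
    out = {name: [] for name in ENGINES}
    for seed in range(10):
        cfg = SimConfig(n_genes=2000, n_de=0, replicates=3, seed=seed)
        sim = simulate_experiment(cfg, nb_params, seed=seed)
        for name, fit in ENGINES.items():
            out[name].append(fit(sim.experiment, pair).table["p_raw"].to_numpy())
    return out


def make_experiment(counts: np.ndarray, groups: list[str], **meta_cols) -> CountExperiment:
    """Build a CountExperiment from a raw array and group labels."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    samples = [f"s{j + 1}" for j in range(n)]
    frame = pd.DataFrame(
        counts, index=[f"g{i + 1}" for i in range(counts.shape[0])], columns=samples
    )
    meta = pd.DataFrame(
        {"file": samples, "group": groups, **meta_cols},
        index=pd.Index(samples, name="sample"),
    )
    return CountExperiment(counts=frame, sample_meta=meta)


@pytest.fixture()
def fourfold_experiment(nb_params):
    """Null 3v3 counts with one high-depth gene exactly 4x in group B.

    The planted gene has large counts and (being a deterministic 4x scaling
    of Poisson-scale draws) essentially zero dispersion, so every engine
    should recover logFC close to 2.
    """
    cfg = SimConfig(n_genes=1200, n_de=0, replicates=3, seed=5)
    sim = simulate_experiment(cfg, nb_params, seed=5)
    counts = sim.experiment.counts.copy()
    rng = np.random.default_rng(2)
    base = rng.poisson(5000, size=3)
    gene = "gene_42"
    counts.loc[gene] = np.concatenate([base, 4 * base])
    exp = CountExperiment(counts=counts, sample_meta=sim.experiment.sample_meta)
    return exp, gene
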
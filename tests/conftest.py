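"""Shared fixtures: small synthetic systems with known causal structure."""

import numpy as np
import pandas as pd
import pytest

import ednascreen as es


def coupled_logistic_pair(seed, n=200, c21=0.1, c12=0.0, r1=3.8, r2=3.5,
                          noise=0.01):
    """Two logistic maps; taxon 1 drives taxon 2 when c21 > 0.

    Returns (driver, response) arrays of length n.
    """
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(0.2, 0.8, 2)
    xs, ys = [], []
    for _ in range(n):
        xs.append(x)
        ys.append(y)
        x2 = x * (r1 - r1 * x - c12 * y) + rng.normal(0, noise)
        y2 = y * (r2 - r2 * y - c21 * x) + rng.normal(0, noise)
        x, y = float(np.clip(x2, 0, 1)), float(np.clip(y2, 0, 1))
    return np.array(xs), np.array(ys)


def ar1(seed, n=200, phi=0.5):
    rng = np.random.default_rng(seed)
    out = np.zeros(n)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + rng.normal()
    return out


def copies_long(traj):
    """Long CopyTable built from latent truth of a simulated experiment."""
    taxa = [f"Taxa{i+1:03d}" for i in range(traj.n_taxa)]
    rows = [{"plot": pl, "date": d, "taxon": tx,
             "copies_per_ml": traj.abundances[p, di, i]}
            for p, pl in enumerate(traj.plots)
            for di, d in enumerate(traj.dates)
            for i, tx in enumerate(taxa)]
    return pd.DataFrame(rows), taxa


@pytest.fixture(scope="session")
def small_experiment():
    """One fixed simulated experiment: 20 taxa, 3 plots, 100 days, 3 true causes."""
    network = es.make_network(n_taxa=20, n_causes=3, seed=11)
    traj, _ = es.simulate_experiment(network, n_days=100, n_plots=3, seed=11)
    return traj, network


@pytest.fixture(scope="session")
def noiseless_observation():
    """Tiny experiment observed without read noise (exact round-trip input)."""
    network = es.make_network(n_taxa=5, n_causes=1, seed=3)
    traj, _ = es.simulate_experiment(network, n_days=20, n_plots=2, seed=3)
    reads, manifest = es.generate_read_table(traj, noise_model="none", seed=5)
    return traj, reads, manifest
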
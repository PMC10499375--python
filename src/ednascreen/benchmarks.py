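"""Validation scenarios with known ground truth.

Each benchmark generates synthetic data whose causal structure is known,
runs the corresponding pipeline stage, and returns the measured rate. The
scenario sizes (series length 200 for two-species systems; 20 taxa x 100
days x 3 plots for the screen; B = 200 bootstrap replicates; lag scans to
-5) are the package's standard validation conditions, sized to run on a
single CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .embedding import EmbeddingSpec
from .screen import screen_climate, screen_taxa, standardize
from .synthdata import make_network, simulate_experiment
from .uic import uic_scan

__all__ = [
    "coupled_logistic_pair",
    "directionality_benchmark",
    "type1_benchmark",
    "planted_screen_benchmark",
]

#: scenario-wide bootstrap replicates and embedding-search cap
SCENARIO_B = 200
SCENARIO_E_MAX = 5


def coupled_logistic_pair(seed, n: int = 200, c21: float = 0.1,
                          c12: float = 0.0, r1: float = 3.8, r2: float = 3.5,
                          noise_sd: float = 0.01):
    """Two logistic maps where species 1 drives species 2 (c21 > 0).

    The canonical benchmark system for attractor-reconstruction causality:
    x_{t+1} = x_t (r1 - r1 x_t - c12 y_t), y_{t+1} = y_t (r2 - r2 y_t - c21 x_t),
    plus small Gaussian process noise, states clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    x, y = rng.uniform(0.2, 0.8, 2)
    xs = np.empty(n)
    ys = np.empty(n)
    for t in range(n):
        xs[t] = x
        ys[t] = y
        x2 = x * (r1 - r1 * x - c12 * y) + rng.normal(0, noise_sd)
        y2 = y * (r2 - r2 * y - c21 * x) + rng.normal(0, noise_sd)
        x = float(np.clip(x2, 0, 1))
        y = float(np.clip(y2, 0, 1))
    return xs, ys


def directionality_benchmark(n_seeds: int = 50, n: int = 200,
                             seed: int = 0) -> tuple[float, float]:
    """Detection rates for driver->response and response->driver.

    The coupling acts at one time step, so both directions are tested at
    the known lag tp = -1. Returns (forward rate, reverse rate): the
    fraction of seeds with a statistically clear lag in each direction.
    """
    ss = np.random.SeedSequence(seed).spawn(n_seeds)
    spec = EmbeddingSpec(E_max=SCENARIO_E_MAX)
    fwd = rev = 0
    for i, child in enumerate(ss):
        s1, s2, s3 = (int(c.generate_state(1)[0] % (2 ** 31)) for c in child.spawn(3))
        driver, resp = coupled_logistic_pair(s1, n=n)
        pf = uic_scan(standardize(resp), standardize(driver), spec=spec,
                      tp_range=[-1], B=SCENARIO_B, seed=s2)
        pr = uic_scan(standardize(driver), standardize(resp), spec=spec,
                      tp_range=[-1], B=SCENARIO_B, seed=s3)
        fwd += pf.best_tp is not None
        rev += pr.best_tp is not None
    return fwd / n_seeds, rev / n_seeds


def type1_benchmark(n_replicates: int = 100, n: int = 200,
                    seed: int = 0, alpha: float = 0.05) -> float:
    """Rejection rate for an independent cause against an AR(1) effect."""
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    spec = EmbeddingSpec(E_max=SCENARIO_E_MAX)
    rej = 0
    for child in ss:
        s1, s2 = (int(c.generate_state(1)[0] % (2 ** 31)) for c in child.spawn(2))
        rng = np.random.default_rng(s1)
        eff = np.zeros(n)
        for t in range(1, n):
            eff[t] = 0.5 * eff[t - 1] + rng.normal()
        cause = rng.normal(size=n)
        profile = uic_scan(standardize(eff), standardize(cause), spec=spec,
                           tp_range=[-1], B=SCENARIO_B, seed=s2, alpha=alpha)
        rej += profile.best_tp is not None
    return rej / n_replicates


def _screen_once(seed: int, null: bool) -> tuple[set, set]:
    net = make_network(n_taxa=20, n_causes=0 if null else 3, seed=seed)
    traj, _ = simulate_experiment(net, n_days=100, n_plots=3, seed=seed)
    taxa = [f"Taxa{i+1:03d}" for i in range(20)]
    rows = [{"plot": pl, "date": d, "taxon": tx,
             "copies_per_ml": traj.abundances[p, di, i]}
            for p, pl in enumerate(traj.plots)
            for di, d in enumerate(traj.dates)
            for i, tx in enumerate(taxa)]
    copies = pd.DataFrame(rows)
    spec = EmbeddingSpec(E_max=SCENARIO_E_MAX)
    tp_range = range(0, -6, -1)
    conds = screen_climate(traj.growth_rate, {"temperature": traj.temperature},
                           spec, tp_range, B=SCENARIO_B, seed=seed)
    cond_series = [traj.temperature] if conds else []
    table = screen_taxa(copies, traj.growth_rate, cond_series, spec,
                        tp_range, B=SCENARIO_B, seed=seed)
    flagged = set(table.loc[table["causal"].fillna(False).astype(bool), "taxon"])
    truth = {taxa[i] for i in net.true_causes}
    return flagged, truth


def planted_screen_benchmark(n_seeds: int = 20, seed: int = 0,
                             null_seeds: int = 8) -> tuple[float, float]:
    """Planted-cause recovery and null flagging of the full screen.

    Returns (recovery rate, null flag rate): the fraction of seeds in which
    all three true causes are flagged, and the fraction of taxa flagged in
    a configuration with no true causes.
    """
    ss = np.random.SeedSequence(seed).spawn(n_seeds + null_seeds)
    recovered = 0
    for child in ss[:n_seeds]:
        s = int(child.generate_state(1)[0] % (2 ** 31))
        flagged, truth = _screen_once(s, null=False)
        recovered += truth <= flagged
    flags = total = 0
    for child in ss[n_seeds:]:
        s = int(child.generate_state(1)[0] % (2 ** 31))
        flagged, _ = _screen_once(s, null=True)
        flags += len(flagged)
        total += 20
    return recovered / n_seeds, flags / total
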
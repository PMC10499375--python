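"""Transfer-entropy core: predictions, TE identities, bootstrap, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ednascreen as es
from ednascreen.embedding import EmbeddedDataset, EmbeddingSpec, make_embedding
from ednascreen.uic import (VARIANCE_FLOOR, bootstrap_pvalue, loo_predict,
                            select_embedding_dimension, transfer_entropy,
                            uic_scan)

from conftest import ar1, coupled_logistic_pair
from oracle import oracle_te


def _dataset(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return EmbeddedDataset(X=X, y=y, t=np.arange(1, len(y) + 1),
                           block=np.zeros(len(y)),
                           columns=[f"c{i}" for i in range(X.shape[1])])


def test_nearest_neighbour_lookup():
    ds = _dataset([[0.0], [1.0], [2.0]], [0.0, 10.0, 20.0])
    pred, _ = loo_predict(ds, k=1)
    assert pred[0] == 10.0  # nearest other row to 0 is 1
    assert pred[2] == 10.0


def test_perfect_prediction_hits_variance_floor():
    ds = _dataset(np.arange(10.0).reshape(-1, 1), np.full(10, 7.0))
    _, sigma2 = loo_predict(ds, k=3)
    assert sigma2 == VARIANCE_FLOOR


def test_too_few_rows_raise():
    ds = _dataset([[0.0], [1.0]], [0.0, 1.0])
    with pytest.raises(ValueError):
        loo_predict(ds, k=2)


def test_te_zero_when_models_identical():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 2))
    y = rng.normal(size=30)
    full = _dataset(X, y)
    res = transfer_entropy(full, _dataset(X, y), k=3)
    assert res.te == 0.0


def test_te_large_in_deterministic_limit():
    # target is an exact function of x_t; replicated states let the
    # neighbours predict it perfectly, so sigma2_full hits the floor
    rng = np.random.default_rng(1)
    x = np.repeat(rng.uniform(size=20), 3)
    y = np.sin(3 * x)
    full = _dataset(x.reshape(-1, 1), y)
    reduced = _dataset(np.empty((len(y), 0)), y)
    res = transfer_entropy(full, reduced, k=2)
    assert res.sigma2_full == VARIANCE_FLOOR
    assert res.te > 5.0


@pytest.mark.parametrize("seed", range(20))
def test_te_matches_bruteforce_oracle(seed):
    """Optimised estimator equals direct neighbour enumeration, T <= 50."""
    rng = np.random.default_rng(seed)
    T = int(rng.integers(20, 51))
    p = int(rng.integers(2, 4))
    X = rng.normal(size=(T, p))
    y = rng.normal(size=T)
    full = _dataset(X, y)
    reduced = _dataset(X[:, 1:], y)
    k = p + 1
    res = transfer_entropy(full, reduced, k=k)
    expected = oracle_te(X.tolist(), X[:, 1:].tolist(), y.tolist(), k)
    assert res.te == pytest.approx(expected, abs=1e-9)


def test_te_on_coupled_maps_matches_oracle():
    driver, resp = coupled_logistic_pair(4, n=54)
    full, reduced = make_embedding(resp, driver, spec=EmbeddingSpec(E=2, tp=-1))
    k = full.n_predictors + 1
    res = transfer_entropy(full, reduced, k=k)
    expected = oracle_te(full.X.tolist(), reduced.X.tolist(), full.y.tolist(), k)
    assert res.te == pytest.approx(expected, abs=1e-9)


@given(st.floats(min_value=0.1, max_value=50.0))
@settings(max_examples=20, deadline=None)
def test_te_invariant_to_common_rescaling(scale):
    """Multiplying every predictor column by one scalar leaves TE unchanged."""
    rng = np.random.default_rng(7)
    X = rng.normal(size=(40, 3))
    y = rng.normal(size=40)
    base = transfer_entropy(_dataset(X, y), _dataset(X[:, 1:], y), k=4).te
    scaled = transfer_entropy(_dataset(scale * X, y),
                              _dataset(scale * X[:, 1:], y), k=4).te
    assert scaled == pytest.approx(base, abs=1e-10)


def test_bootstrap_p_bounds_and_determinism():
    driver, resp = coupled_logistic_pair(2)
    full, reduced = make_embedding(resp, driver, spec=EmbeddingSpec(E=2, tp=-1))
    p1 = bootstrap_pvalue(full, reduced, B=999, seed=5)
    p2 = bootstrap_pvalue(full, reduced, B=999, seed=5)
    assert p1 == p2
    assert 1 / 1000 <= p1 <= 1.0
    # strong coupling: every resampled TE positive -> smoothed minimum
    assert p1 == pytest.approx(1 / 1000)


def test_bootstrap_type_one_error_controlled():
    """Independent cause vs AR(1) effect: rejection rate stays near alpha."""
    rej = 0
    n = 100
    for s in range(n):
        eff = ar1(s)
        cause = np.random.default_rng(10_000 + s).normal(size=len(eff))
        full, reduced = make_embedding(es.standardize(eff), es.standardize(cause),
                                       spec=EmbeddingSpec(E=2, tp=-1))
        p = bootstrap_pvalue(full, reduced, B=200, seed=s)
        rej += p < 0.05
    assert rej / n <= 0.10


class TestEmbeddingDimensionSelection:
    def test_logistic_map_selects_low_dimension(self):
        """A 1-D deterministic map needs at most two delay coordinates."""
        ok = 0
        for s in range(50):
            x, _ = coupled_logistic_pair(s, c21=0.0)
            noise = np.random.default_rng(10_000 + s).normal(size=len(x))
            E = select_embedding_dimension(es.standardize(x), es.standardize(noise),
                                           spec=EmbeddingSpec(E_max=5), B=100, seed=s)
            ok += E in (1, 2)
        assert ok >= 45

    def test_white_noise_selects_one(self):
        ok = 0
        for s in range(50):
            rng = np.random.default_rng(s)
            x = es.standardize(rng.normal(size=200))
            y = es.standardize(rng.normal(size=200))
            E = select_embedding_dimension(x, y, spec=EmbeddingSpec(E_max=5),
                                           B=100, seed=s)
            ok += E == 1
        assert ok > 25  # majority

    def test_e_max_one_forces_one(self):
        x, y = coupled_logistic_pair(0)
        assert select_embedding_dimension(x, y, spec=EmbeddingSpec(E_max=1),
                                          B=50, seed=0) == 1


class TestLagScan:
    def test_scan_produces_one_entry_per_tp(self):
        driver, resp = coupled_logistic_pair(1)
        profile = uic_scan(es.standardize(resp), es.standardize(driver),
                           spec=EmbeddingSpec(E_max=3),
                           tp_range=range(0, -15, -1), B=100, seed=0)
        assert len(profile.results) == 15
        assert profile.results["tp"].tolist() == list(range(0, -15, -1))

    def test_planted_lag_recovered(self):
        """A taxon driving growth at lag 3 yields best tp = -3."""
        hits = 0
        n = 20
        for s in range(n):
            net = es.TrueNetwork(n_taxa=2, interaction_matrix=np.zeros((2, 2)),
                                 growth_drivers=[(0, 3, 0.8)],
                                 climate_driver=(2, 0.08),
                                 intrinsic_rates=np.array([3.8, 3.5]))
            traj, _ = es.simulate_experiment(net, n_days=100, n_plots=3, seed=s)
            prof = uic_scan(es.standardize(traj.growth_rate),
                            es.standardize(traj.states[:, :, 0]),
                            [es.standardize(traj.temperature)],
                            EmbeddingSpec(E_max=5), tp_range=range(0, -7, -1),
                            B=200, seed=s)
            hits += prof.best_tp == -3
        assert hits >= 0.8 * n

    def test_constant_cause_rejected(self):
        with pytest.raises(ValueError, match="constant series"):
            uic_scan(np.random.default_rng(0).normal(size=50), np.ones(50),
                     tp_range=[0], B=10, seed=0)

    def test_scan_deterministic_given_seed(self):
        driver, resp = coupled_logistic_pair(3)
        kwargs = dict(spec=EmbeddingSpec(E_max=3), tp_range=range(0, -4, -1),
                      B=100, seed=99)
        a = uic_scan(es.standardize(resp), es.standardize(driver), **kwargs)
        b = uic_scan(es.standardize(resp), es.standardize(driver), **kwargs)
        assert a.results.equals(b.results)
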
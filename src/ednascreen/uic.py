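"""Transfer entropy between time series via cross-map nearest-neighbour
regression (unified information-theoretic causality, UIC).

The statistic compares the leave-one-out predictive skill of two nested
nearest-neighbour ("simplex") regressions on a delay embedding of the
effect series: the *full* model keeps the most recent effect coordinate
``x_t``, the *reduced* model drops it. Writing ``sigma2`` for the mean
squared leave-one-out prediction error of each model, the transfer entropy
is

    TE = 0.5 * ln(sigma2_reduced / sigma2_full)   (nats)

which is the mean pointwise log-ratio of Gaussian predictive densities when
each model's predictive variance is taken to be its own mean squared error.
Positive TE means the current state of the effect carries information about
the (possibly lagged) cause beyond what the effect's own past and the
conditioning variables already explain — the cross-mapping signature of a
causal influence of the cause on the effect.

Statistical clarity is assessed by bootstrapping embedded rows and counting
how often the resampled TE falls at or below zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .embedding import EmbeddedDataset, EmbeddingSpec, build_design, make_embedding, _as_blocks

__all__ = [
    "UICResult",
    "UICProfile",
    "loo_predict",
    "transfer_entropy",
    "bootstrap_pvalue",
    "uic_test",
    "select_embedding_dimension",
    "uic_scan",
]

logger = logging.getLogger(__name__)

#: Floor on mean squared prediction errors; prevents log(0) when a model
#: predicts a deterministic target perfectly.
VARIANCE_FLOOR = 1e-12


@dataclass
class UICResult:
    """Outcome of a single transfer-entropy evaluation."""

    te: float
    p_value: float | None
    E: int
    tp: int
    T: int
    sigma2_full: float
    sigma2_reduced: float


@dataclass
class UICProfile:
    """Lag-scan outcome: one row per prediction time step ``tp``."""

    results: pd.DataFrame  # columns: tp, E, te, p, T
    E: int
    alpha: float

    @property
    def best_tp(self) -> int | None:
        """tp maximising TE among statistically clear lags, else None."""
        clear = self.results.dropna(subset=["te"])
        clear = clear[clear["p"] < self.alpha]
        if clear.empty:
            return None
        return int(clear.loc[clear["te"].idxmax(), "tp"])

    @property
    def best(self) -> pd.Series:
        """Row at best_tp, or the max-TE row when no lag is clear."""
        valid = self.results.dropna(subset=["te"])
        if valid.empty:
            raise ValueError("profile has no valid entries")
        tp = self.best_tp
        if tp is None:
            return valid.loc[valid["te"].idxmax()]
        return valid[valid["tp"] == tp].iloc[0]


# ---------------------------------------------------------------------------
# nearest-neighbour leave-one-out machinery


def _distance_matrix(X: np.ndarray) -> np.ndarray:
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], X.shape[0]))
    return cdist(X, X)


def _exclusion(t: np.ndarray, block: np.ndarray, theiler: int) -> np.ndarray:
    """Boolean mask of forbidden neighbour pairs (self + Theiler window)."""
    T = len(t)
    if theiler <= 0:
        return np.eye(T, dtype=bool)
    same_block = block[:, None] == block[None, :]
    close = np.abs(t[:, None] - t[None, :]) <= theiler
    return same_block & close


def _loo_errors(D: np.ndarray, y: np.ndarray, k: int, marginal: bool = False):
    """Predictions and inflation-adjusted squared LOO errors.

    ``D`` must already carry ``inf`` in excluded (self/Theiler) entries.
    ``marginal=True`` ignores distances and uses the leave-one-out mean of
    all other targets — the null model when no predictors remain.

    The simplex prediction is a linear smoother ``yhat_t = sum_i w~_i y_i``
    with normalised weights ``w~``; for an uninformative predictor space
    its squared LOO error has expectation ``Var(y) * (1 + sum_i w~_i^2)``.
    Each squared error is divided by that row's exact inflation factor so
    that the error comparison between models of different dimension (whose
    weight profiles differ systematically) is centred under the null.
    """
    T = D.shape[0]
    if T <= k:
        raise ValueError(f"need T > k neighbours, got T={T}, k={k}")
    if marginal:
        pred = (y.sum() - y) / (T - 1)
        return pred, (y - pred) ** 2 / (1.0 + 1.0 / (T - 1))
    nb = np.argpartition(D, k - 1, axis=1)[:, :k]
    d = np.take_along_axis(D, nb, axis=1)
    if not np.isfinite(d).all():
        raise ValueError("fewer than k admissible neighbours for some rows "
                         "(Theiler window too wide for this block length)")
    d1 = d.min(axis=1)
    w = np.ones_like(d)
    pos = d1 > 0
    w[pos] = np.exp(-d[pos] / d1[pos, None])
    w /= w.sum(axis=1, keepdims=True)
    pred = (w * y[nb]).sum(axis=1)
    inflation = 1.0 + (w ** 2).sum(axis=1)
    return pred, (y - pred) ** 2 / inflation


def _dataset_errors(dataset: EmbeddedDataset, k: int, theiler: int = 0):
    D = _distance_matrix(dataset.X).copy()
    D[_exclusion(dataset.t, dataset.block, theiler)] = np.inf
    return _loo_errors(D, dataset.y, k, marginal=dataset.n_predictors == 0)


def loo_predict(dataset: EmbeddedDataset, k: int, theiler: int = 0):
    """Leave-one-out simplex (k-NN) prediction of the target column.

    For each row the k nearest other rows in predictor space (Euclidean
    distance; self and, optionally, temporal neighbours within the Theiler
    window excluded) predict the target as a weighted mean with simplex
    weights ``w_i = exp(-d_i/d_1)`` (uniform when ``d_1 = 0``). A dataset
    with zero predictor columns uses the leave-one-out marginal mean.

    Returns
    -------
    (predictions, sigma2) : (ndarray, float)
        Per-row predictions and the inflation-adjusted mean squared LOO
        error (see ``_loo_errors``), floored at ``VARIANCE_FLOOR``.
    """
    pred, e2 = _dataset_errors(dataset, k, theiler)
    return pred, max(float(e2.mean()), VARIANCE_FLOOR)


def transfer_entropy(full: EmbeddedDataset, reduced: EmbeddedDataset,
                     k: int | None = None, theiler: int = 0) -> UICResult:
    """Transfer entropy from the nested pair of embedded datasets.

    ``k`` defaults to the simplex convention: number of full-model
    predictor columns + 1.
    """
    if full.T != reduced.T or not np.array_equal(full.y, reduced.y):
        raise ValueError("full and reduced datasets must share rows and target")
    if k is None:
        k = full.n_predictors + 1
    _, s2_full = loo_predict(full, k, theiler)
    if reduced.n_predictors == full.n_predictors:
        # identical predictor sets: TE is exactly zero by construction
        s2_red = s2_full
    else:
        _, s2_red = loo_predict(reduced, k, theiler)
    te = 0.5 * np.log(s2_red / s2_full)
    return UICResult(te=float(te), p_value=None, E=0, tp=0, T=full.T,
                     sigma2_full=s2_full, sigma2_reduced=s2_red)


def bootstrap_pvalue(full: EmbeddedDataset, reduced: EmbeddedDataset,
                     k: int | None = None, B: int = 1000,
                     seed: int | np.random.Generator | None = None,
                     theiler: int = 0) -> float:
    """Bootstrap p-value for TE > 0 (data resampled after embedding).

    Both models are fitted once by leave-one-out simplex regression; the
    embedded rows (predictor + target jointly, hence the rows' squared
    prediction errors) are then resampled with replacement B times and TE
    recomputed on each resample as

        TE_b = 0.5 * ln(mean_b(e_reduced^2) / mean_b(e_full^2)).

    p = (1 + #{TE_b <= 0}) / (B + 1). The fitted predictions are held
    fixed across resamples — refitting neighbours on a resample would let
    duplicated rows act as zero-distance perfect neighbours and destroy
    the calibration of the test.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if full.T != reduced.T or not np.array_equal(full.y, reduced.y):
        raise ValueError("full and reduced datasets must share rows and target")
    if k is None:
        k = full.n_predictors + 1
    rng = np.random.default_rng(seed)
    _, e2f = _dataset_errors(full, k, theiler)
    _, e2r = _dataset_errors(reduced, k, theiler)
    T = full.T
    idx = rng.integers(0, T, (B, T))
    s2f = np.maximum(e2f[idx].mean(axis=1), VARIANCE_FLOOR)
    s2r = np.maximum(e2r[idx].mean(axis=1), VARIANCE_FLOOR)
    te_b = 0.5 * np.log(s2r / s2f)
    return float((1 + np.sum(te_b <= 0)) / (B + 1))


def uic_test(effect, cause, conditions=None, spec: EmbeddingSpec = EmbeddingSpec(),
             k: int | None = None, B: int = 1000,
             seed: int | np.random.Generator | None = None,
             theiler: int = 0) -> UICResult:
    """One TE evaluation with bootstrap significance at the spec's tp."""
    full, reduced = make_embedding(effect, cause, conditions, spec)
    res = transfer_entropy(full, reduced, k, theiler)
    res.p_value = bootstrap_pvalue(full, reduced, k, B, seed, theiler)
    res.E = spec.E
    res.tp = spec.tp
    return res


# ---------------------------------------------------------------------------
# embedding-dimension selection (TE version of simplex projection)


def _pair_blocks(effect, cause, conditions):
    eff = _as_blocks(effect)
    cau = _as_blocks(cause)
    if len(eff) != len(cau):
        raise ValueError("effect and cause must have the same block structure")
    conds = [_as_blocks(c) for c in (conditions or [])]
    blocks, ids = [], []
    for i, ((bid, x), (_, y)) in enumerate(zip(eff, cau)):
        if len(x) != len(y):
            raise ValueError(f"effect and cause differ in length in block {bid!r}")
        blk = {"x": x, "y": y}
        for j, cb in enumerate(conds):
            blk[f"z{j}"] = cb[i][1]
        blocks.append(blk)
        ids.append(bid)
    return blocks, ids, len(conds)


def select_embedding_dimension(effect, cause, conditions=None,
                               spec: EmbeddingSpec = EmbeddingSpec(),
                               k: int | None = None, B: int = 100,
                               seed: int | np.random.Generator | None = None,
                               alpha: float = 0.05, theiler: int = 0) -> int:
    """Select the embedding dimension by one-step-forward predictive gain.

    For E = 1..E_max the effect series' own future ``x_{t+1}`` is predicted
    from ``{y_t, x_t, ..., x_{t-(E-1)tau}, z_t}`` (full) versus the optimal
    lower-dimensional model ``{y_t, x_t, ..., x_{t-(E_R-1)tau}, z_t}``,
    where E_R is the best dimension established so far (for E = 1 the
    reduced set is the no-x baseline ``{y_t, z_t}``). E* advances to E only
    on a statistically clear gain (bootstrap p < alpha) over the current
    best model; if no E gains, E* = 1.
    """
    blocks, ids, n_cond = _pair_blocks(effect, cause, conditions)
    rng = np.random.default_rng(seed)
    best = 0
    for E in range(1, spec.E_max + 1):
        lags = [("y", 0)] + [("x", j * spec.tau) for j in range(E)]
        lags += [(f"z{j}", 0) for j in range(n_cond)]
        try:
            full = build_design(blocks, lags, target=("x", 1), block_ids=ids)
        except ValueError:
            logger.warning("embedding dimension search stopped at E=%d: no valid rows", E)
            break
        kk = full.n_predictors + 1 if k is None else k
        if full.T <= kk:
            logger.warning("embedding dimension search stopped at E=%d: T=%d too small", E, full.T)
            break
        # reduced model keeps only the E_R = best-so-far delay coordinates
        # of x (plus y_t and conditions); same rows as the full model
        keep = [0] + list(range(1, best + 1)) + list(range(E + 1, E + 1 + n_cond))
        reduced = EmbeddedDataset(X=full.X[:, keep], y=full.y, t=full.t,
                                  block=full.block,
                                  columns=[full.columns[j] for j in keep])
        res = transfer_entropy(full, reduced, kk, theiler)
        p = bootstrap_pvalue(full, reduced, kk, B, rng, theiler)
        if res.te > 0 and p < alpha:
            best = E
    return max(best, 1)


# ---------------------------------------------------------------------------
# lag scanning


def uic_scan(effect, cause, conditions=None, spec: EmbeddingSpec = EmbeddingSpec(),
             tp_range=range(0, -15, -1), k: int | None = None, B: int = 1000,
             seed: int | None = None, alpha: float = 0.05,
             theiler: int = 0, E: int | None = None) -> UICProfile:
    """Scan prediction time steps, testing TE(cause -> effect) at each.

    The self-prediction-optimal embedding dimension E* is selected once
    per pair (one-step-forward criterion) and the causal test embeds the
    effect with E* + 1 delay coordinates — the cross-mapping convention:
    the effect's reconstruction needs one extra dimension to accommodate
    the causal variable's state. Negative tp values probe influence of the
    cause from ``|tp|`` days ago.

    Parameters
    ----------
    E : int, optional
        Skip selection and force this embedding dimension (used as given,
        without the + 1).
    """
    tp_range = list(tp_range)
    if not tp_range:
        raise ValueError("tp_range must be non-empty")
    for name, series in (("cause", cause), ("effect", effect)):
        vals = np.concatenate([v for _, v in _as_blocks(series)])
        vals = vals[np.isfinite(vals)]
        if vals.size == 0 or np.ptp(vals) == 0:
            raise ValueError(f"constant series: {name}")

    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(tp_range) + 1)
    if E is None:
        E_star = select_embedding_dimension(effect, cause, conditions, spec,
                                            k=k, B=min(B, 100),
                                            seed=np.random.default_rng(child[0]),
                                            alpha=alpha, theiler=theiler)
        E = E_star + 1
    rows = []
    for i, tp in enumerate(tp_range):
        s = EmbeddingSpec(E=E, tau=spec.tau, tp=tp, E_max=spec.E_max)
        try:
            res = uic_test(effect, cause, conditions, s, k=k, B=B,
                           seed=np.random.default_rng(child[i + 1]),
                           theiler=theiler)
            rows.append({"tp": tp, "E": E, "te": res.te, "p": res.p_value, "T": res.T})
        except ValueError as exc:
            logger.warning("tp=%d skipped: %s", tp, exc)
            rows.append({"tp": tp, "E": E, "te": np.nan, "p": np.nan, "T": 0})
    return UICProfile(results=pd.DataFrame(rows), E=E, alpha=alpha)
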
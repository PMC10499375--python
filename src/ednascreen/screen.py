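"""Causal screening of community members against rice growth.

Orchestrates the full screening analysis: per-plot standardization of all
series, identification of causal climate conditioning variables, then a
transfer-entropy lag scan of every taxon's copy-number series against the
rice growth rate. Emits a ranked table of potentially influential taxa
(one row per taxon, flagged causal when the bootstrap p-value at the best
lag is below alpha).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .embedding import EmbeddingSpec
from .uic import uic_scan

__all__ = ["standardize", "screen_climate", "screen_taxa", "UICScreen"]

logger = logging.getLogger(__name__)


def standardize(series, per_block: bool = True) -> np.ndarray:
    """Zero-mean, unit-variance (n-1 denominator) standardization.

    Input may be 1-D (single plot) or 2-D (plots x time); 2-D input is
    standardized within each plot block. Missing values are ignored in the
    moments and preserved in the output.

    Raises
    ------
    ValueError
        "constant series" when a (block's) series has < 2 distinct values.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        vals = arr[np.isfinite(arr)]
        if vals.size < 2 or np.ptp(vals) == 0:
            raise ValueError("constant series")
        return (arr - vals.mean()) / vals.std(ddof=1)
    if arr.ndim == 2 and per_block:
        return np.stack([standardize(arr[i]) for i in range(arr.shape[0])])
    if arr.ndim == 2:
        return standardize(arr.ravel()).reshape(arr.shape)
    raise ValueError("series must be 1-D or 2-D")


def screen_climate(growth: np.ndarray, climate_vars: dict[str, np.ndarray],
                   spec: EmbeddingSpec = EmbeddingSpec(),
                   tp_range=range(0, -15, -1), alpha: float = 0.05,
                   B: int = 1000, seed: int | None = None,
                   k: int | None = None, theiler: int = 0) -> list[str]:
    """Select climate variables that are causal factors of rice growth.

    Each candidate is lag-scanned against growth (no conditioning); those
    with a statistically clear lag (any p < alpha) become conditioning
    variables ``z`` for the taxon screen.
    """
    selected = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(len(climate_vars), 1))
    for (name, series), child in zip(sorted(climate_vars.items()), children):
        try:
            profile = uic_scan(standardize(growth), standardize(series),
                               conditions=None, spec=spec, tp_range=tp_range,
                               k=k, B=B, seed=int(child.generate_state(1)[0] % (2**31)),
                               alpha=alpha, theiler=theiler)
        except ValueError as exc:
            logger.warning("climate variable %s not testable: %s", name, exc)
            continue
        if profile.best_tp is not None:
            selected.append(name)
    return selected


def screen_taxa(copies: pd.DataFrame, growth: np.ndarray,
                conditions: list[np.ndarray] | None = None,
                spec: EmbeddingSpec = EmbeddingSpec(),
                tp_range=range(0, -15, -1), alpha: float = 0.05,
                B: int = 1000, seed: int | None = None,
                k: int | None = None, theiler: int = 0,
                min_detection_frac: float = 0.1) -> pd.DataFrame:
    """Transfer-entropy lag scan of every taxon against rice growth.

    Parameters
    ----------
    copies : DataFrame
        Long CopyTable with columns ``plot, date, taxon, copies_per_ml``,
        or wide table indexed by (plot, date) with taxon columns.
    growth : ndarray (n_plots, n_days)
        Growth-rate series per plot, aligned to the copy table's plot/date
        grid (sorted plot then date).
    conditions : list of ndarray, optional
        Conditioning series (e.g. causal climate variables), same shape.

    Returns
    -------
    DataFrame
        One row per taxon: ``taxon, tested, reason, best_tp, te, p_value,
        E, T, causal, q_value``; tested rows sorted by TE descending,
        untested rows (constant or too-sparse series) appended with the
        reason. The causal flag is ``p_value < alpha`` at the best lag;
        q_value is a Benjamini-Hochberg adjustment across tested taxa,
        reported as an extra column only and never used for the flag.
    """
    wide = _to_wide(copies)
    plots = wide.index.get_level_values("plot").unique().tolist()
    n_days = len(wide.index.get_level_values("date").unique())
    growth = np.asarray(growth, dtype=float)
    if growth.shape != (len(plots), n_days):
        raise ValueError(f"growth shape {growth.shape} does not match copies grid "
                         f"({len(plots)} plots x {n_days} days)")
    growth_std = standardize(growth)
    cond_std = [standardize(np.asarray(c, dtype=float)) for c in (conditions or [])]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(wide.columns))
    tested_rows, untested_rows = [], []
    for taxon, child in zip(wide.columns, children):
        series = wide[taxon].to_numpy(dtype=float).reshape(len(plots), n_days)
        finite = series[np.isfinite(series)]
        if finite.size < 2 or np.ptp(finite) == 0:
            untested_rows.append({"taxon": taxon, "tested": False, "reason": "constant series"})
            continue
        if (np.count_nonzero(finite) / finite.size) < min_detection_frac:
            untested_rows.append({"taxon": taxon, "tested": False, "reason": "sparse series"})
            continue
        try:
            taxon_std = standardize(series)
        except ValueError:
            untested_rows.append({"taxon": taxon, "tested": False, "reason": "constant series"})
            continue
        try:
            profile = uic_scan(growth_std, taxon_std, conditions=cond_std, spec=spec,
                               tp_range=tp_range, k=k, B=B,
                               seed=int(child.generate_state(1)[0] % (2**31)),
                               alpha=alpha, theiler=theiler)
            best = profile.best
        except ValueError as exc:
            untested_rows.append({"taxon": taxon, "tested": False, "reason": str(exc)})
            continue
        tested_rows.append({"taxon": taxon, "tested": True, "reason": "",
                            "best_tp": int(best["tp"]), "te": float(best["te"]),
                            "p_value": float(best["p"]), "E": int(best["E"]),
                            "T": int(best["T"]),
                            "causal": bool(best["p"] < alpha)})
    table = pd.DataFrame(tested_rows)
    if not table.empty:
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values("te", ascending=False, kind="mergesort")
    un = pd.DataFrame(untested_rows)
    out = pd.concat([table, un], ignore_index=True) if not un.empty else table
    cols = ["taxon", "tested", "reason", "best_tp", "te", "p_value", "E", "T",
            "causal", "q_value"]
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[cols].reset_index(drop=True)


def _to_wide(copies: pd.DataFrame) -> pd.DataFrame:
    """Normalise a CopyTable to wide (plot, date) x taxon layout."""
    if isinstance(copies.index, pd.MultiIndex):
        wide = copies.copy()
    else:
        required = {"plot", "date", "taxon", "copies_per_ml"}
        if not required.issubset(copies.columns):
            raise ValueError(f"copy table must have columns {sorted(required)}")
        wide = copies.pivot_table(index=["plot", "date"], columns="taxon",
                                  values="copies_per_ml", aggfunc="mean")
    wide = wide.sort_index()
    # complete the (plot x date) grid so per-plot series share the time axis;
    # absent combinations become explicit missing values
    plots = wide.index.get_level_values(0).unique()
    dates = wide.index.get_level_values(1).unique().sort_values()
    full = pd.MultiIndex.from_product([plots, dates], names=["plot", "date"])
    return wide.reindex(full)


class UICScreen(BaseEstimator):
    """Univariate causal screen of taxa against a response series.

    scikit-learn-style estimator: ``fit`` runs the complete screening
    (climate-variable selection, then a transfer-entropy lag scan per
    taxon) and exposes the ranked results; ``get_support`` returns the
    boolean causal mask over taxa, so the screen composes with sklearn
    model-selection utilities.

    Parameters
    ----------
    tp_min, tp_max : int
        Scanned prediction time steps run from ``tp_max`` down to
        ``tp_min`` (default 0 to -14: influences from up to 14 days ago).
    alpha : float
        Statistical-clarity threshold for the bootstrap p-value.
    E_max, tau, k, theiler : embedding/neighbour parameters (see uic module).
    B : int
        Bootstrap replicates.
    random_state : int or None
        Seeds every stochastic step; fits are byte-reproducible.

    Attributes
    ----------
    results_ : DataFrame
        Ranked CausalScreenTable (one row per taxon).
    conditions_ : list of str
        Climate variables selected as conditioning factors.
    taxa_ : list
        Taxon column order of the fitted table.
    """

    def __init__(self, tp_min: int = -14, tp_max: int = 0, alpha: float = 0.05,
                 E_max: int = 10, tau: int = 1, k: int | None = None,
                 B: int = 1000, theiler: int = 0,
                 min_detection_frac: float = 0.1, random_state: int | None = None):
        self.tp_min = tp_min
        self.tp_max = tp_max
        self.alpha = alpha
        self.E_max = E_max
        self.tau = tau
        self.k = k
        self.B = B
        self.theiler = theiler
        self.min_detection_frac = min_detection_frac
        self.random_state = random_state

    def _spec(self) -> EmbeddingSpec:
        return EmbeddingSpec(E=1, tau=self.tau, tp=0, E_max=self.E_max)

    def _tp_range(self):
        return range(self.tp_max, self.tp_min - 1, -1)

    def fit(self, X: pd.DataFrame, y: np.ndarray, climate: dict[str, np.ndarray] | None = None):
        """Run the screen.

        Parameters
        ----------
        X : DataFrame
            Copy table (long with plot/date/taxon/copies_per_ml columns, or
            wide indexed by (plot, date)).
        y : ndarray (n_plots, n_days)
            Response series (rice growth rate) per plot.
        climate : dict name -> ndarray (n_plots, n_days), optional
            Candidate conditioning variables, screened against ``y`` first.
        """
        ss = np.random.SeedSequence(self.random_state)
        s_climate, s_taxa = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
        climate = climate or {}
        self.conditions_ = screen_climate(
            np.asarray(y, dtype=float), climate, self._spec(), self._tp_range(),
            self.alpha, self.B, s_climate, self.k, self.theiler)
        cond_series = [climate[name] for name in self.conditions_]
        self.results_ = screen_taxa(
            X, y, cond_series, self._spec(), self._tp_range(), self.alpha,
            self.B, s_taxa, self.k, self.theiler, self.min_detection_frac)
        self.taxa_ = list(_to_wide(X).columns)
        return self

    def get_support(self) -> np.ndarray:
        """Boolean causal mask aligned to ``taxa_`` order."""
        check_is_fitted(self, "results_")
        flags = self.results_.set_index("taxon")["causal"].fillna(False)
        return np.array([bool(flags.get(t, False)) for t in self.taxa_])

    @property
    def causal_taxa_(self) -> list:
        check_is_fitted(self, "results_")
        r = self.results_
        return r.loc[r["causal"].fillna(False).astype(bool), "taxon"].tolist()
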
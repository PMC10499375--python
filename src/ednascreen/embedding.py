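"""Time-delay embedding of (multi-plot) time series.

State-space reconstruction follows the standard delay-coordinate recipe:
an observed series ``x`` is unfolded into rows ``(x_t, x_{t-tau}, ...,
x_{t-(E-1)tau})``; a target column ``y_{t+tp}`` is aligned to each row.
Series from different plots ("blocks") are embedded independently and the
rows pooled, so no embedding vector ever spans a plot boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = ["EmbeddingSpec", "EmbeddedDataset", "make_embedding"]


@dataclass(frozen=True)
class EmbeddingSpec:
    """Parameters of a delay embedding.

    Attributes
    ----------
    E : int
        Embedding dimension (number of lagged copies of the effect series),
        >= 1.
    tau : int
        Lag unit in time steps, >= 1.
    tp : int
        Prediction time step of the target relative to the embedding row.
        Negative values align the target to the past (lagged causal
        influence of the cause series).
    E_max : int
        Upper bound of the embedding-dimension search.
    """

    E: int = 1
    tau: int = 1
    tp: int = 0
    E_max: int = 10

    def __post_init__(self) -> None:
        if self.E < 1:
            raise ValueError(f"E must be >= 1, got {self.E}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.E_max < 1:
            raise ValueError(f"E_max must be >= 1, got {self.E_max}")

    def with_E(self, E: int) -> "EmbeddingSpec":
        return replace(self, E=E)


@dataclass
class EmbeddedDataset:
    """Pooled embedded predictor matrix with an aligned target column.

    Attributes
    ----------
    X : ndarray of shape (T, p)
        Predictor matrix. Rows are valid time points; columns are delay
        coordinates (most recent first) followed by condition columns.
    y : ndarray of shape (T,)
        Target column ``y_{t+tp}``.
    t : ndarray of shape (T,)
        1-based time index of each row within its block.
    block : ndarray of shape (T,)
        Block (plot) id of each row.
    columns : list of str
        Human-readable names of the predictor columns.
    """

    X: np.ndarray
    y: np.ndarray
    t: np.ndarray
    block: np.ndarray
    columns: list[str] = field(default_factory=list)

    @property
    def T(self) -> int:
        return self.X.shape[0]

    @property
    def n_predictors(self) -> int:
        return self.X.shape[1]

    def drop_column(self, index: int) -> "EmbeddedDataset":
        """Return a copy without predictor column ``index`` (same rows)."""
        keep = [j for j in range(self.X.shape[1]) if j != index]
        names = self.columns if len(self.columns) == self.X.shape[1] \
            else [f"c{j}" for j in range(self.X.shape[1])]
        return EmbeddedDataset(
            X=self.X[:, keep],
            y=self.y,
            t=self.t,
            block=self.block,
            columns=[names[j] for j in keep],
        )


def _as_blocks(series) -> list[tuple[object, np.ndarray]]:
    """Normalise input to a list of (block_id, 1-D float array)."""
    if isinstance(series, Mapping):
        return [(key, np.asarray(v, dtype=float).ravel()) for key, v in series.items()]
    arr = np.asarray(series, dtype=float)
    if arr.ndim == 1:
        return [(0, arr)]
    if arr.ndim == 2:  # rows are blocks
        return [(i, arr[i].astype(float)) for i in range(arr.shape[0])]
    raise ValueError("series must be 1-D, 2-D (blocks x time) or a mapping")


def build_design(
    blocks: Sequence[Mapping[str, np.ndarray]],
    predictor_lags: Sequence[tuple[str, int]],
    target: tuple[str, int],
    block_ids: Sequence[object] | None = None,
) -> EmbeddedDataset:
    """Assemble an embedded design matrix from named series per block.

    Parameters
    ----------
    blocks : sequence of dict
        One dict per block mapping series name -> 1-D array; all series in
        a block share the time axis.
    predictor_lags : sequence of (name, lag)
        Each predictor column is ``series[name]`` shifted back by ``lag``
        (lag 0 is the current value).
    target : (name, shift)
        Target column is ``series[name]`` shifted forward by ``shift``
        (``shift`` may be negative).

    Rows with any out-of-range index or NaN are dropped; rows never span
    blocks.
    """
    t_name, tp = target
    X_parts, y_parts, t_parts, b_parts = [], [], [], []
    if block_ids is None:
        block_ids = list(range(len(blocks)))
    for bid, blk in zip(block_ids, blocks):
        n = len(blk[t_name])
        max_lag = max((lag for _, lag in predictor_lags), default=0)
        # 0-based valid range: t - max_lag >= 0 and 0 <= t + tp < n
        lo = max(max_lag, -tp if tp < 0 else 0)
        hi = min(n, n - tp) if tp > 0 else n
        if lo >= hi:
            continue
        tt = np.arange(lo, hi)
        cols = [np.asarray(blk[name], dtype=float)[tt - lag] for name, lag in predictor_lags]
        X = np.column_stack(cols) if cols else np.empty((len(tt), 0))
        y = np.asarray(blk[t_name], dtype=float)[tt + tp]
        ok = np.isfinite(y)
        if X.shape[1]:
            ok &= np.isfinite(X).all(axis=1)
        X_parts.append(X[ok])
        y_parts.append(y[ok])
        t_parts.append(tt[ok] + 1)  # 1-based reporting
        b_parts.append(np.full(ok.sum(), bid, dtype=object))
    if not X_parts or sum(len(p) for p in y_parts) == 0:
        raise ValueError("no valid rows: embedding window exceeds every block length")
    names = [f"{name}_lag{lag}" for name, lag in predictor_lags]
    return EmbeddedDataset(
        X=np.vstack(X_parts),
        y=np.concatenate(y_parts),
        t=np.concatenate(t_parts),
        block=np.concatenate(b_parts),
        columns=names,
    )


def make_embedding(
    effect,
    cause,
    conditions: Sequence | None = None,
    spec: EmbeddingSpec = EmbeddingSpec(),
) -> tuple[EmbeddedDataset, EmbeddedDataset]:
    """Build the full and reduced embedded datasets for a UIC test.

    The full predictor set is ``{x_t, x_{t-tau}, ..., x_{t-(E-1)tau}, z_t}``
    where ``x`` is the effect series and ``z`` the condition series; the
    reduced set drops the most recent effect coordinate ``x_t``. The target
    is the cause series at ``t + tp``. Transfer entropy compares the
    predictive skill of the two sets.

    Parameters
    ----------
    effect, cause : array-like or mapping
        1-D series, 2-D (blocks x time) arrays, or mappings block_id ->
        series. Cause must be aligned to effect within each block.
    conditions : sequence of series, optional
        Zero or more conditioning series with the same layout.

    Returns
    -------
    (full, reduced) : EmbeddedDataset
        Share the same rows and target column.
    """
    eff_blocks = _as_blocks(effect)
    cause_blocks = _as_blocks(cause)
    if len(eff_blocks) != len(cause_blocks):
        raise ValueError("effect and cause must have the same block structure")
    cond_blocks = [_as_blocks(c) for c in (conditions or [])]

    blocks = []
    ids = []
    for i, ((bid, x), (_, y)) in enumerate(zip(eff_blocks, cause_blocks)):
        if len(x) != len(y):
            raise ValueError(f"effect and cause differ in length in block {bid!r}")
        blk = {"x": x, "y": y}
        for j, cb in enumerate(cond_blocks):
            z = cb[i][1]
            if len(z) != len(x):
                raise ValueError(f"condition {j} differs in length in block {bid!r}")
            blk[f"z{j}"] = z
        blocks.append(blk)
        ids.append(bid)

    lags = [("x", j * spec.tau) for j in range(spec.E)]
    lags += [(f"z{j}", 0) for j in range(len(cond_blocks))]
    full = build_design(blocks, lags, target=("y", spec.tp), block_ids=ids)
    reduced = full.drop_column(0)
    return full, reduced
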
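"""Spike-in standard-curve calibration: sequence reads -> absolute copies.

Each sequencing library carries internal standard DNAs of known
concentration (copies/ul of extract). Because reads are proportional to
template within a library, a per-sample through-origin regression

    reads = slope * copies_per_ul

calibrates that sample; taxon reads divided by the slope give copies/ul,
and the manifest's volumes convert to copies per ml of sampled water:

    copies/ml water = copies/ul * elution volume (ul) / filtered water (ml)

The through-origin form encodes the physical constraint that zero template
yields zero expected reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "fit_curves",
    "reads_to_copies",
    "qc_controls",
    "SpikeInCalibrator",
]

logger = logging.getLogger(__name__)

#: quality thresholds below which a curve is unusable for conversion
MIN_R2 = 0.5
MIN_NONZERO_STANDARDS = 2


@dataclass
class StandardCurve:
    """Per-sample calibration line through the origin.

    Attributes
    ----------
    slope : float
        Reads per (copies/ul); NaN when degenerate.
    r2 : float
        Coefficient of determination of the through-origin fit
        (1 - SS_res / sum(reads^2)); NaN when degenerate.
    degenerate : bool
        True when every standard read is zero (no signal to calibrate on).
    """

    sample_id: str | None
    slope: float
    n_standards: int
    r2: float
    degenerate: bool

    @property
    def usable(self) -> bool:
        """Whether the curve may be used to convert reads to copies."""
        if self.degenerate:
            return False
        return self.r2 >= MIN_R2 and self.n_nonzero >= MIN_NONZERO_STANDARDS

    n_nonzero: int = 0


def fit_standard_curve(standard_reads, known_copies, sample_id: str | None = None) -> StandardCurve:
    """Fit the through-origin regression of standard reads on known copies.

    slope = sum(copies * reads) / sum(copies^2) — the least-squares solution
    without intercept.

    Parameters
    ----------
    standard_reads : array-like
        Non-negative read counts, one per standard.
    known_copies : array-like
        Known concentrations (copies/ul), strictly positive.
    """
    reads = np.asarray(standard_reads, dtype=float)
    copies = np.asarray(known_copies, dtype=float)
    if reads.shape != copies.shape:
        raise ValueError(
            f"standard reads ({reads.shape}) and known copies ({copies.shape}) differ in length")
    if len(copies) < 2:
        raise ValueError("need at least 2 standards")
    if (copies <= 0).any():
        raise ValueError("known copies must be strictly positive")
    if (reads < 0).any():
        raise ValueError("reads must be non-negative")
    n_nonzero = int((reads > 0).sum())
    if n_nonzero == 0:
        return StandardCurve(sample_id, np.nan, len(copies), np.nan,
                             degenerate=True, n_nonzero=0)
    slope = float((copies * reads).sum() / (copies ** 2).sum())
    ss_res = float(((reads - slope * copies) ** 2).sum())
    ss_tot = float((reads ** 2).sum())  # uncentered, as fits a no-intercept model
    r2 = 1.0 - ss_res / ss_tot
    return StandardCurve(sample_id, slope, len(copies), r2,
                         degenerate=False, n_nonzero=n_nonzero)


def _split_columns(reads: pd.DataFrame, standard_ids) -> tuple[list, list]:
    std_cols = [c for c in reads.columns if c in set(standard_ids)]
    missing = set(standard_ids) - set(std_cols)
    if missing:
        raise ValueError(f"read table lacks standard columns: {sorted(missing)}")
    taxa_cols = [c for c in reads.columns if c not in set(standard_ids)]
    return std_cols, taxa_cols


def fit_curves(reads: pd.DataFrame, standards: pd.DataFrame) -> dict[str, StandardCurve]:
    """Fit one standard curve per sample (row of the read table).

    Parameters
    ----------
    reads : DataFrame
        Indexed by sample id; columns are taxa and standard ids.
    standards : DataFrame
        Columns ``standard_id`` and ``copies_per_ul``.
    """
    std_ids = list(standards["standard_id"])
    known = standards.set_index("standard_id")["copies_per_ul"]
    std_cols, _ = _split_columns(reads, std_ids)
    copies = known.loc[std_cols].to_numpy(dtype=float)
    return {
        sid: fit_standard_curve(reads.loc[sid, std_cols].to_numpy(dtype=float), copies, sid)
        for sid in reads.index
    }


def reads_to_copies(reads: pd.DataFrame, curves: dict[str, StandardCurve],
                    manifest: pd.DataFrame, standards: pd.DataFrame) -> pd.DataFrame:
    """Convert taxon reads to copies per ml of water via per-sample curves.

    Returns a long-format table with columns ``sample_id, plot, date,
    taxon, copies_per_ml``. Samples whose curve is degenerate or of poor
    quality yield missing values (never fabricated zeros) and are logged.
    Control samples in the manifest are skipped.

    Raises
    ------
    KeyError
        If a non-control sample lacks a curve or manifest volumes.
    """
    man = manifest.set_index("sample_id")
    _, taxa_cols = _split_columns(reads, list(standards["standard_id"]))
    records = []
    for sid in reads.index:
        if sid not in man.index:
            raise KeyError(f"sample {sid!r} missing from manifest")
        row = man.loc[sid]
        if row.get("sample_class", "sample") != "sample":
            continue
        if sid not in curves:
            raise KeyError(f"no standard curve for sample {sid!r}")
        curve = curves[sid]
        water_ml = float(row["water_ml"])
        elution_ul = float(row["elution_ul"])
        if not np.isfinite(water_ml) or water_ml <= 0 or elution_ul <= 0:
            raise ValueError(f"invalid volumes for sample {sid!r}")
        if not curve.usable:
            logger.warning("sample %s: unusable standard curve (degenerate=%s, r2=%s); "
                           "copies set to missing", sid, curve.degenerate, curve.r2)
            per_ml = np.full(len(taxa_cols), np.nan)
        else:
            per_ul = reads.loc[sid, taxa_cols].to_numpy(dtype=float) / curve.slope
            per_ml = per_ul * elution_ul / water_ml
        for taxon, value in zip(taxa_cols, per_ml):
            records.append({"sample_id": sid, "plot": row["plot"], "date": row["date"],
                            "taxon": taxon, "copies_per_ml": value})
    return pd.DataFrame.from_records(records)


def qc_controls(reads: pd.DataFrame, manifest: pd.DataFrame,
                standards: pd.DataFrame, threshold: float = 10) -> pd.DataFrame:
    """Check negative/positive control samples for contamination.

    Every control sample's total non-standard reads are compared against
    ``threshold``; the report has one row per control with columns
    ``sample_id, sample_class, nonstandard_reads, passed``.
    """
    man = manifest.set_index("sample_id")
    _, taxa_cols = _split_columns(reads, list(standards["standard_id"]))
    rows = []
    for sid, row in man.iterrows():
        cls = row.get("sample_class", "sample")
        if cls == "sample":
            continue
        total = float(reads.loc[sid, taxa_cols].sum()) if sid in reads.index else 0.0
        rows.append({"sample_id": sid, "sample_class": cls,
                     "nonstandard_reads": total, "passed": total <= threshold})
    return pd.DataFrame(rows, columns=["sample_id", "sample_class",
                                       "nonstandard_reads", "passed"])


class SpikeInCalibrator(TransformerMixin, BaseEstimator):
    """Transformer mapping a read table to absolute copies/ul of extract.

    Fits one through-origin standard curve per sample from the spike-in
    columns and divides taxon reads by the sample's slope. Rows with
    degenerate or poor-quality curves transform to NaN.

    Parameters
    ----------
    standards : DataFrame
        Columns ``standard_id``, ``copies_per_ul``.

    Attributes
    ----------
    curves_ : dict[str, StandardCurve]
        Fitted per-sample curves.
    taxa_columns_ : list
        Non-standard columns of the fitted read table.

    Examples
    --------
    >>> cal = SpikeInCalibrator(standards).fit(reads)
    >>> copies_per_ul = cal.transform(reads)      # doctest: +SKIP
    """

    def __init__(self, standards: pd.DataFrame | None = None):
        self.standards = standards

    def fit(self, X: pd.DataFrame, y=None):
        if self.standards is None:
            raise ValueError("SpikeInCalibrator requires a standards table")
        self.curves_ = fit_curves(X, self.standards)
        _, self.taxa_columns_ = _split_columns(X, list(self.standards["standard_id"]))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "curves_")
        out = pd.DataFrame(index=X.index, columns=self.taxa_columns_, dtype=float)
        for sid in X.index:
            curve = self.curves_.get(sid)
            if curve is None or not curve.usable:
                out.loc[sid] = np.nan
            else:
                out.loc[sid] = X.loc[sid, self.taxa_columns_].to_numpy(dtype=float) / curve.slope
        return out
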
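"""Variance-based classification of translation states.

Replicate translation states from a panel of wild-type samples (the
reference design is 12 biological replicates pooled from 4 separate
experiments) are summarized by their per-gene standard deviation on the
log2 scale.  The top ``top_fraction`` (default 20%) of genes by SD are
classified as having a highly variable translation state; the rest are
"stable".  The identical operation applied to total-transcript (TC)
panels classifies transcript-level variability — same code path,
different input.

The threshold is the nearest-rank (1 - top_fraction) quantile of the
computable SDs; genes strictly above it are variable, so ties at the
threshold land on the stable side.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dtg import nearest_rank_quantile

__all__ = ["StabilityClassifier", "classify_stability", "sd_histogram"]


class StabilityClassifier(BaseEstimator):
    """Flag the most variable genes across a replicate panel.

    scikit-learn-style estimator over a panel with replicates as
    samples (rows) and genes as features (columns).

    Parameters
    ----------
    top_fraction : float
        Fraction of genes (with a computable SD) to flag as variable.
    min_replicates : int
        Minimum number of non-missing replicate values per gene; genes
        below it are uncomputable (neither stable nor variable).

    Attributes
    ----------
    sd_ : per-gene sample SD (ddof=1), NaN where uncomputable
    threshold_ : the SD cut; genes strictly above it are variable
    variable_ / stable_ : boolean masks (mutually exclusive; both False
        only for uncomputable genes)
    """

    def __init__(self, top_fraction: float = 0.20, min_replicates: int = 3):
        self.top_fraction = top_fraction
        self.min_replicates = min_replicates

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected replicates x genes panel")
        if X.shape[0] < self.min_replicates:
            raise ValueError(
                f"panel has {X.shape[0]} replicates; "
                f"need >= {self.min_replicates}")
        if not 0.0 < self.top_fraction < 1.0:
            raise ValueError("top_fraction must be in (0, 1)")
        n_obs = np.sum(~np.isnan(X), axis=0)
        with np.errstate(invalid="ignore"):
            sd = np.nanstd(X, axis=0, ddof=1)
        sd = np.where(n_obs >= self.min_replicates, sd, np.nan)
        computable = np.isfinite(sd)
        if not computable.any():
            raise ValueError("no gene has enough replicates")
        self.sd_ = sd
        self.threshold_ = nearest_rank_quantile(sd[computable],
                                                1.0 - self.top_fraction)
        self.variable_ = computable & (sd > self.threshold_)
        self.stable_ = computable & ~self.variable_
        return self

    def fit_predict(self, X, y=None):
        """1 for variable genes, 0 for stable, -1 for uncomputable."""
        self.fit(X)
        return np.where(self.variable_, 1, np.where(self.stable_, 0, -1))


def classify_stability(panel: pd.DataFrame, top_fraction: float = 0.20,
                       min_replicates: int = 3) -> pd.DataFrame:
    """Classify genes by replicate-panel SD of log2 TL (or log2 TC).

    Parameters
    ----------
    panel
        Genes x replicates DataFrame of log2 values.

    Returns
    -------
    DataFrame indexed by gene with columns ``sd``, ``variable_flag``,
    ``stable_flag``; the SD threshold is stored in
    ``frame.attrs["threshold"]``.
    """
    est = StabilityClassifier(top_fraction=top_fraction,
                              min_replicates=min_replicates)
    est.fit(panel.to_numpy(dtype=float).T)
    out = pd.DataFrame({"sd": est.sd_, "variable_flag": est.variable_,
                        "stable_flag": est.stable_}, index=panel.index)
    out.index.name = "gene"
    out.attrs["threshold"] = est.threshold_
    out.attrs["n_replicates"] = panel.shape[1]
    return out


def sd_histogram(sd: pd.Series, bin_width: float = 0.05) -> pd.DataFrame:
    """Binned counts of a per-gene SD distribution (histogram-ready
    table with one row per bin)."""
    vals = sd.dropna().to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("no computable SDs")
    hi = float(np.ceil(vals.max() / bin_width) * bin_width) or bin_width
    edges = np.round(np.arange(0.0, hi + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(vals, bins=edges)
    return pd.DataFrame({"sd_low": edges[:-1], "sd_high": edges[1:],
                         "count": counts})
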
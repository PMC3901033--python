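"""Identification of differentially translated genes (DTGs).

Two routes are implemented and combined:

FDR route
    Four prefiltered gene sets are built from detection calls and a
    wild-type stability panel ("All", "P/M", "Stable", "Stable and
    P/M").  Within each set an empirical-Bayes moderated two-sample t
    statistic compares replicate log2 translation states between mutant
    and wild-type, p-values are Benjamini-Hochberg adjusted within the
    set, and a gene is a DTG in that set when |Dlog2 TL| clears a fold
    cutoff (default log2 >= 1.0, twofold) at FDR < alpha (default
    0.05).  The non-redundant union over the four sets is the final
    call; its realized FDR is slightly above alpha because of the extra
    comparisons.

Ad hoc route
    A replicate-consistency filter on per-replicate log2 fold changes:
    (i) more than twofold in every replicate (same direction), or
    (ii) coefficient of variation < 50%, or (iii) SD < 0.5; combined
    with a minimum mean fold change (default 1.5-fold, log2 = 0.59).
    It does not control the FDR but captures most FDR-route DTGs while
    keeping reproducible sub-twofold trends.

The moderated t shrinks each gene's pooled variance s2_g (d_g residual
df) toward a prior s0^2 with d0 prior df:

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)
    t = delta / sqrt(s2_post * (1/n1 + 1/n2)),  df = d0 + d_g

(d0, s0^2) are estimated once per gene universe by moment matching of
log s2_g using a Newton inversion of the trigamma function, the
standard empirical-Bayes fit for a scaled-F variance model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "build_prefilter_sets", "ModeratedTTest",
           "moderated_t", "bh_fdr", "adhoc_filter",
           "per_replicate_fold_changes", "identify_dtg", "venn_counts"]

PREFILTER_SETS = ("All", "PM", "Stable", "Stable_and_PM")


# ----------------------------------------------------------------------
# prefilter gene sets
# ----------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """The four prefiltered gene universes used by the FDR route."""

    all_genes: pd.Index
    pm: pd.Index
    stable: pd.Index
    stable_and_pm: pd.Index

    def __getitem__(self, name: str) -> pd.Index:
        return {"All": self.all_genes, "PM": self.pm, "Stable": self.stable,
                "Stable_and_PM": self.stable_and_pm}[name]

    def sizes(self) -> dict[str, int]:
        return {name: len(self[name]) for name in PREFILTER_SETS}

    def membership_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.all_genes)
        for name in PREFILTER_SETS:
            out[f"set_{name}"] = out.index.isin(self[name])
        out.index.name = "gene"
        return out


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Nearest-rank (ceil) empirical quantile of a 1-D sample."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty sample")
    k = int(np.ceil(q * values.size))
    k = min(max(k, 1), values.size)
    return float(values[k - 1])


def build_prefilter_sets(calls: pd.DataFrame, wt_panel_sd: pd.Series,
                         sd_quantile: float = 0.80) -> GeneSetCollection:
    """Build the four prefiltered gene sets.

    Parameters
    ----------
    calls
        Genes x arrays P/M/A detection-call DataFrame over the full
        gene universe.
    wt_panel_sd
        Per-gene SD of log2 TL across the wild-type replicate panel
        (missing where uncomputable).
    sd_quantile
        Genes whose panel SD is <= the nearest-rank ``sd_quantile``
        quantile of computable SDs form the "Stable" set (default 0.80,
        i.e. the bottom 80% by variability; ties at the threshold are
        included).

    The "P/M" set requires P or M calls in at least 50% of arrays; the
    "Stable and P/M" set applies the stricter rule of being devoid of
    any Absent call on top of stability.
    """
    if hasattr(calls, "calls"):
        calls = calls.calls
    universe = calls.index
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    wt_panel_sd = wt_panel_sd.reindex(universe)

    arr = calls.to_numpy()
    pm_frac = (arr != "A").mean(axis=1)
    pm = universe[pm_frac >= 0.5]
    no_absent = universe[(arr != "A").all(axis=1)]

    sds = wt_panel_sd.dropna()
    threshold = nearest_rank_quantile(sds.to_numpy(), sd_quantile)
    stable = sds.index[sds.to_numpy() <= threshold]
    stable_and_pm = stable.intersection(no_absent)
    return GeneSetCollection(all_genes=universe, pm=pm, stable=stable,
                             stable_and_pm=stable_and_pm)


# ----------------------------------------------------------------------
# empirical-Bayes moderated t
# ----------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _fit_prior_variance(s2: np.ndarray, df: float, d0: float) -> float:
    """Prior variance s0^2 implied by the log-variance mean for a given
    (possibly infinite) prior df."""
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if not ok.any():
        return 0.0
    e = np.log(s2[ok]) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    if np.isinf(d0):
        return float(np.exp(emean))
    return float(np.exp(emean + special.digamma(d0 / 2.0)
                        - np.log(d0 / 2.0)))


def squeeze_variance(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate the prior df d0 and prior variance s0^2 from per-gene
    sample variances, by moment matching of log s2.

    Under s2_g ~ s0^2 * F(d_g, d0), e_g = log s2_g - digamma(d_g/2) +
    log(d_g/2) has mean log s0^2 + digamma(d0/2) ... ; the excess
    variance of e_g over trigamma(d_g/2) identifies trigamma(d0/2).
    When the observed variances are under-dispersed (near-constant),
    d0 = inf with s0^2 the common value, with a logged warning.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        # degenerate (e.g. noiseless) data: no spread to moment-match
        log.warning("fewer than 2 positive variances; using d0=inf with "
                    "the mean variance as the prior")
        return np.inf, float(np.nanmean(np.where(np.isfinite(s2),
                                                 s2, np.nan)))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        log.warning("variance moment estimate non-positive; falling back "
                    "to d0=inf (all gene variances shrunk to the prior)")
        d0 = np.inf
        s02 = np.exp(emean)
    return float(d0), float(s02)


class ModeratedTTest(BaseEstimator):
    """Two-group empirical-Bayes moderated t-test, one test per gene.

    scikit-learn-style estimator: ``fit(X, y)`` with ``X`` of shape
    (n_arrays, n_genes) and ``y`` the two group labels per array.  The
    contrast is mean(second group) - mean(first group), where group
    order is order of first appearance in ``y`` (put the wild-type
    first).

    Parameters
    ----------
    prior_df : "auto", float or numpy.inf
        d0.  "auto" estimates it by moment matching; 0 gives the
        ordinary pooled-variance t; inf shrinks every gene to the
        common prior variance.

    Attributes
    ----------
    delta_, s2_, df_residual_, s2_post_, t_, p_ : per-gene arrays
    df_prior_, s2_prior_ : the fitted (or forced) prior
    classes_ : the two group labels, reference first
    """

    def __init__(self, prior_df="auto"):
        self.prior_df = prior_df

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = list(dict.fromkeys(y.tolist()))
        if len(classes) != 2:
            raise ValueError(f"expected exactly 2 groups, got {classes}")
        g1 = X[y == classes[0]]
        g2 = X[y == classes[1]]
        n1, n2 = g1.shape[0], g2.shape[0]
        if max(n1, n2) < 2:
            raise ValueError("at least one group needs >=2 replicates")
        df = n1 + n2 - 2
        if df < 1:
            raise ValueError("pooled residual df must be >= 1")
        m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
        ss = ((g1 - m1) ** 2).sum(axis=0) + ((g2 - m2) ** 2).sum(axis=0)
        s2 = ss / df
        delta = m2 - m1

        if self.prior_df == "auto":
            d0, s02 = squeeze_variance(s2, df)
        else:
            d0 = float(self.prior_df)
            if d0 < 0:
                raise ValueError("prior_df must be >= 0")
            s02 = _fit_prior_variance(s2, df, d0) if d0 > 0 else 0.0

        if np.isinf(d0):
            s2_post = np.full_like(s2, s02)
        else:
            s2_post = (d0 * s02 + df * s2) / (d0 + df)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            # se = 0 (noiseless data): any nonzero delta is infinitely
            # significant, a zero delta is not at all
            t = np.where(se > 0, delta / np.where(se > 0, se, 1.0),
                         np.where(delta != 0,
                                  np.sign(delta) * np.inf, 0.0))
        df_total = d0 + df
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)

        self.classes_ = classes
        self.n_per_group_ = (n1, n2)
        self.delta_ = delta
        self.s2_ = s2
        self.df_residual_ = float(df)
        self.df_prior_ = float(d0)
        self.s2_prior_ = float(s02)
        self.s2_post_ = s2_post
        self.t_ = t
        self.p_ = p
        return self

    def results_frame(self, genes=None) -> pd.DataFrame:
        out = pd.DataFrame({"delta": self.delta_, "s2": self.s2_,
                            "s2_post": self.s2_post_, "t": self.t_,
                            "p": self.p_})
        if genes is not None:
            out.index = pd.Index(genes, name="gene")
        return out


def moderated_t(group1, group2, prior_df="auto") -> pd.DataFrame:
    """Moderated t of ``group1`` vs ``group2`` replicate values.

    ``group1``/``group2`` are genes x replicates DataFrames or arrays
    (e.g. mutant and wild-type log2 TL).  Returns a per-gene frame with
    delta = mean(group1) - mean(group2), the shrunken variance,
    moderated t and its p-value; the fitted prior is stored in
    ``frame.attrs['df_prior']`` and ``frame.attrs['s2_prior']``.
    """
    genes = group1.index if isinstance(group1, pd.DataFrame) else None
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    X = np.vstack([b.T, a.T])  # reference (group2) first
    y = np.array(["ref"] * b.shape[1] + ["alt"] * a.shape[1])
    est = ModeratedTTest(prior_df=prior_df).fit(X, y)
    out = est.results_frame(genes)
    out.attrs["df_prior"] = est.df_prior_
    out.attrs["s2_prior"] = est.s2_prior_
    out.attrs["df_residual"] = est.df_residual_
    return out


# ----------------------------------------------------------------------
# multiple testing
# ----------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing p-values are excluded from the adjustment (they do not
    count toward m) and returned as missing.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        pv = p[ok]
        if (pv < 0).any() or (pv > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(pv, method="fdr_bh")[1]
    return out


# ----------------------------------------------------------------------
# ad hoc replicate-consistency filter
# ----------------------------------------------------------------------

def per_replicate_fold_changes(mut: pd.DataFrame,
                               wt: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate log2 fold changes, mutant vs wild-type.

    Mutant replicate i is paired with wild-type replicate i when the
    counts match (samples processed in parallel); with unequal counts
    each mutant replicate is compared against the wild-type mean.
    """
    if mut.shape[1] == wt.shape[1]:
        fc = mut.to_numpy(dtype=float) - wt.to_numpy(dtype=float)
    else:
        fc = mut.to_numpy(dtype=float) \
            - wt.to_numpy(dtype=float).mean(axis=1, keepdims=True)
    return pd.DataFrame(fc, index=mut.index,
                        columns=[f"fc.{i + 1}" for i in range(fc.shape[1])])


def adhoc_filter(fold_changes: pd.DataFrame, twofold: float = 1.0,
                 cv_max: float = 0.5, sd_max: float = 0.5,
                 min_abs_mean: float = 0.59) -> pd.DataFrame:
    """Three-criterion ad hoc DTG filter on per-replicate log2 FCs.

    (i)   |FC| >= ``twofold`` in every replicate, all the same sign;
    (ii)  coefficient of variation SD/|mean| < ``cv_max`` (undefined,
          hence False, at mean 0);
    (iii) SD < ``sd_max``.

    A gene is DTG(ad hoc) when any criterion holds and |mean FC| >=
    ``min_abs_mean`` (default 0.59, a 1.5-fold change).
    """
    fc = fold_changes.to_numpy(dtype=float)
    if fc.shape[1] < 2:
        raise ValueError("ad hoc filter needs >=2 replicate fold changes")
    mean = np.nanmean(fc, axis=1)
    sd = np.nanstd(fc, axis=1, ddof=1)
    same_sign = (np.nanmin(fc, axis=1) > 0) | (np.nanmax(fc, axis=1) < 0)
    crit_i = same_sign & (np.nanmin(np.abs(fc), axis=1) >= twofold)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / np.abs(mean), np.inf)
    crit_ii = cv < cv_max
    crit_iii = sd < sd_max
    dtg = (crit_i | crit_ii | crit_iii) & (np.abs(mean) >= min_abs_mean)
    return pd.DataFrame({"mean_fc": mean, "sd_fc": sd,
                         "adhoc_i": crit_i, "adhoc_ii": crit_ii,
                         "adhoc_iii": crit_iii, "dtg_adhoc": dtg},
                        index=fold_changes.index)


# ----------------------------------------------------------------------
# combined DTG table
# ----------------------------------------------------------------------

def identify_dtg(ts_table: pd.DataFrame, sets: GeneSetCollection,
                 mutant: str, wild_type: str = "WT",
                 fold_cutoff: float = 1.0, alpha: float = 0.05,
                 prior_df="auto", adhoc_kwargs: dict | None = None
                 ) -> pd.DataFrame:
    """Assemble the DTG table for one mutant from a translation-state
    table (see :func:`translatome.core.build_translation_state_table`).

    The moderated t and its BH adjustment are computed independently
    within each prefilter set (the number of tests m differs per set);
    the reported t/p/fdr columns are those of the "All" set.  The
    non-redundant union flag ORs the four per-set calls; the ad hoc
    route is evaluated on per-replicate TL fold changes and reported
    alongside.
    """
    mut_cols = [c for c in ts_table.columns
                if c.startswith(f"tl.{mutant}.")]
    wt_cols = [c for c in ts_table.columns
               if c.startswith(f"tl.{wild_type}.")]
    if not mut_cols or not wt_cols:
        raise ValueError(f"no replicate TL columns for {mutant!r} or "
                         f"{wild_type!r}")
    mut = ts_table[mut_cols]
    wt = ts_table[wt_cols]
    complete = ts_table.index[mut.notna().all(axis=1)
                              & wt.notna().all(axis=1)]

    out = pd.DataFrame(index=ts_table.index)
    out.index.name = "gene"
    out["delta_log2_tl"] = ts_table[f"delta_tl.{mutant}"]
    for col in ("t", "p", "fdr"):
        out[col] = np.nan

    for name in PREFILTER_SETS:
        members = sets[name].intersection(complete)
        flag = pd.Series(False, index=out.index)
        if len(members) >= 2:
            res = moderated_t(mut.loc[members], wt.loc[members],
                              prior_df=prior_df)
            res["fdr"] = bh_fdr(res["p"].to_numpy())
            sig = (res["fdr"] < alpha) \
                & (res["delta"].abs() >= fold_cutoff)
            flag.loc[members] = sig.to_numpy()
            if name == "All":
                out.loc[members, ["t", "p", "fdr"]] = \
                    res[["t", "p", "fdr"]].to_numpy()
        out[f"dtg_{name}"] = flag
    set_cols = [f"dtg_{name}" for name in PREFILTER_SETS]
    out["dtg_union"] = out[set_cols].any(axis=1)
    out["direction"] = np.where(
        out["dtg_union"],
        np.where(out["delta_log2_tl"] > 0, "over", "under"), "")

    fc = per_replicate_fold_changes(mut, wt)
    adhoc = adhoc_filter(fc, **(adhoc_kwargs or {}))
    out = out.join(adhoc[["adhoc_i", "adhoc_ii", "adhoc_iii",
                          "dtg_adhoc"]])
    return out


def venn_counts(dtg_table: pd.DataFrame) -> pd.DataFrame:
    """Bookkeeping of per-set and union DTG counts, including the count
    unique to each prefilter set."""
    rows = []
    set_cols = [f"dtg_{name}" for name in PREFILTER_SETS]
    for name in PREFILTER_SETS:
        col = f"dtg_{name}"
        others = [c for c in set_cols if c != col]
        rows.append({"set": name,
                     "n_dtg": int(dtg_table[col].sum()),
                     "n_unique": int((dtg_table[col]
                                      & ~dtg_table[others].any(axis=1))
                                     .sum())})
    rows.append({"set": "union", "n_dtg": int(dtg_table["dtg_union"].sum()),
                 "n_unique": int(dtg_table["dtg_union"].sum())})
    return pd.DataFrame(rows)
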
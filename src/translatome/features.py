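"""Sequence features of mRNAs and their association with differential
translation.

Covers the feature side of the analysis: scanning 5' leaders for
upstream open reading frames (uORFs), classifying transcripts into
uORF / long-ORF / short-ORF classes, binning Dlog2 TL and testing each
bin's class composition against the no-change bin (Fisher's exact test,
or chi-square with Yates' continuity correction when all expected
counts allow), mean-vs-reference-bin Student t tables, rank-based
sign-concordance tests between mutants, and Pearson R^2.

A uORF is an AUG-initiated reading frame starting strictly upstream of
the main CDS; it either terminates within the leader
(``contained_in_leader``) or runs past the main start codon
(``overlaps_main_orf``).  The long/short main-ORF split defaults to
1,086 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["UORFRecord", "scan_uorfs", "classify_transcripts",
           "fisher_or_yates", "bin_association_analysis",
           "bin_ttest_table", "length_bin_analysis",
           "sign_concordance_test", "pearson_r2", "significance_tier",
           "DEFAULT_DELTA_EDGES", "LONG_ORF_NT"]

STOP_CODONS = ("TAA", "TAG", "TGA")
LONG_ORF_NT = 1086
#: Dlog2 TL bin edges: 0.2-wide bins, a (-0.2, 0.2) no-change bin in the
#: middle, open-ended extremes.
DEFAULT_DELTA_EDGES = (-np.inf, -1.0, -0.8, -0.6, -0.4, -0.2,
                       0.2, 0.4, 0.6, 0.8, 1.0, np.inf)


# ----------------------------------------------------------------------
# uORF scanning
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class UORFRecord:
    """One upstream ORF in transcript coordinates (0-based)."""

    start: int            # position of the A of the uORF AUG
    stop: int             # position of the last nt of the stop codon
    length_codons: int    # coding codons incl. the AUG, excl. the stop
    overlap_class: str    # contained_in_leader | overlaps_main_orf


def scan_uorfs(sequence: str, main_cds_start: int,
               min_codons: int = 1) -> list[UORFRecord]:
    """Find all AUG-initiated upstream ORFs in a transcript.

    Every ATG strictly upstream of ``main_cds_start`` opens a candidate
    frame that is walked codon by codon until the first in-frame stop
    (TAA/TAG/TGA) anywhere in the transcript; candidates that never hit
    a stop before the sequence ends are discarded.  uORFs whose stop
    lies before ``main_cds_start`` are ``contained_in_leader``; the
    rest ``overlaps_main_orf``.

    Parameters
    ----------
    sequence
        Uppercase DNA transcript sequence (5'->3').
    main_cds_start
        0-based start of the main ORF; must satisfy
        0 <= main_cds_start < len(sequence).
    min_codons
        Minimum number of coding codons (including the AUG) for a
        candidate to be reported.
    """
    seq = str(sequence).upper()
    if not 0 <= main_cds_start < len(seq):
        raise ValueError(f"main_cds_start={main_cds_start} outside the "
                         f"sequence (length {len(seq)})")
    records: list[UORFRecord] = []
    for pos in range(main_cds_start):
        if seq[pos:pos + 3] != "ATG":
            continue
        n_codons = 0
        stop_end = None
        for cpos in range(pos, len(seq) - 2, 3):
            codon = seq[cpos:cpos + 3]
            if codon in STOP_CODONS:
                stop_end = cpos + 2
                break
            n_codons += 1
        if stop_end is None or n_codons < min_codons:
            continue
        overlap = ("contained_in_leader" if stop_end < main_cds_start
                   else "overlaps_main_orf")
        records.append(UORFRecord(start=pos, stop=stop_end,
                                  length_codons=n_codons,
                                  overlap_class=overlap))
    return records


def classify_transcripts(annotation: pd.DataFrame,
                         long_orf_nt: int = LONG_ORF_NT) -> pd.Series:
    """Three-way feature class per gene: ``uorf``, ``no_uorf_long``
    (main ORF > ``long_orf_nt``) or ``no_uorf_short``.

    ``annotation`` needs ``n_uorfs`` (or boolean ``has_uorf``) and
    ``cds_length`` columns.
    """
    has_uorf = (annotation["n_uorfs"] > 0 if "n_uorfs" in annotation
                else annotation["has_uorf"].astype(bool))
    cls = np.where(has_uorf, "uorf",
                   np.where(annotation["cds_length"] > long_orf_nt,
                            "no_uorf_long", "no_uorf_short"))
    return pd.Series(cls, index=annotation.index, name="feature_class")


# ----------------------------------------------------------------------
# contingency machinery
# ----------------------------------------------------------------------

def fisher_or_yates(table) -> tuple[float, str]:
    """Two-sided p for a 2x2 table: chi-square with Yates' continuity
    correction when every expected count is >= 5, otherwise Fisher's
    exact test.  Returns (p, test_name)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if table.sum() == 0:
        return np.nan, "none"
    expected = stats.contingency.expected_freq(table)
    if (expected >= 5).all():
        p = stats.chi2_contingency(table, correction=True)[1]
        return float(p), "chi2_yates"
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return float(p), "fisher"


def significance_tier(p: float) -> str:
    """Asterisk convention: ``**`` for p < 0.0001, ``*`` for
    0.0001 <= p < 0.05, empty otherwise."""
    if not np.isfinite(p):
        return ""
    if p < 1e-4:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _bin_labels(edges: np.ndarray) -> list[str]:
    def fmt(x):
        return "-inf" if x == -np.inf else "inf" if x == np.inf \
            else f"{x:g}"
    return [f"({fmt(lo)}, {fmt(hi)}]" if lo != -np.inf
            else f"[{fmt(lo)}, {fmt(hi)}]"
            for lo, hi in zip(edges[:-1], edges[1:])]


def _assign_bins(values: pd.Series, edges) -> pd.Series:
    edges = np.asarray(edges, dtype=float)
    if not np.all(np.diff(edges) > 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = pd.cut(values, bins=edges, labels=False, include_lowest=True)
    return idx


def _reference_bin_index(edges: np.ndarray, no_change: tuple) -> int:
    edges = np.asarray(edges, dtype=float)
    lo, hi = no_change
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        if np.isclose(a, lo) and np.isclose(b, hi):
            return i
    raise ValueError(f"no bin matches the no-change interval {no_change}; "
                     "adjust bin_edges")


def bin_association_analysis(delta_tl: pd.Series, annotation: pd.DataFrame,
                             bin_edges=DEFAULT_DELTA_EDGES,
                             no_change: tuple = (-0.2, 0.2),
                             long_orf_nt: int = LONG_ORF_NT) -> pd.DataFrame:
    """Class composition of Dlog2 TL bins, each tested against the
    no-change bin.

    For every bin and every feature class (uORF, no-uORF long ORF,
    no-uORF short ORF) a 2x2 table (class vs rest, bin vs no-change
    bin) is tested with :func:`fisher_or_yates`.  Returns a tidy table
    with one row per bin x class: counts, percentages (summing to 100
    within a bin), p-value (1.0 in the reference bin by convention),
    test used, and the asterisk tier.
    """
    genes = delta_tl.dropna().index.intersection(annotation.index)
    delta = delta_tl.loc[genes]
    cls = classify_transcripts(annotation.loc[genes], long_orf_nt)
    edges = np.asarray(bin_edges, dtype=float)
    bins = _assign_bins(delta, edges)
    ref = _reference_bin_index(edges, no_change)
    labels = _bin_labels(edges)
    classes = ("uorf", "no_uorf_long", "no_uorf_short")

    counts = pd.DataFrame(0, index=range(len(labels)), columns=classes)
    for b, c in zip(bins, cls):
        if not np.isnan(b):
            counts.loc[int(b), c] += 1
    totals = counts.sum(axis=1)

    rows = []
    for b in range(len(labels)):
        n_bin = int(totals[b])
        for c in classes:
            k = int(counts.loc[b, c])
            pct = 100.0 * k / n_bin if n_bin else np.nan
            if n_bin == 0:
                p, test = np.nan, "none"
            elif b == ref:
                p, test = 1.0, "reference"
            else:
                tbl = [[k, n_bin - k],
                       [int(counts.loc[ref, c]),
                        int(totals[ref] - counts.loc[ref, c])]]
                p, test = fisher_or_yates(tbl)
            rows.append({"bin": labels[b], "bin_low": edges[b],
                         "bin_high": edges[b + 1],
                         "is_reference": b == ref, "n_bin": n_bin,
                         "feature_class": c, "count": k, "percent": pct,
                         "p": p, "test": test,
                         "stars": significance_tier(p)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# bin t-test tables
# ----------------------------------------------------------------------

def bin_ttest_table(bin_by: pd.Series, values: pd.Series, bin_edges,
                    reference_bin: int | None = None) -> pd.DataFrame:
    """Mean +/- SEM of ``values`` within bins of ``bin_by``, with a
    pooled-variance two-sample Student t test of each bin against a
    reference bin.

    ``reference_bin=None`` uses the bin containing the median of
    ``bin_by``.  Bins with n < 2 get no test.
    """
    common = bin_by.dropna().index.intersection(values.dropna().index)
    bin_by = bin_by.loc[common]
    values = values.loc[common]
    edges = np.asarray(bin_edges, dtype=float)
    bins = _assign_bins(bin_by, edges)
    labels = _bin_labels(edges)
    if reference_bin is None:
        med = float(bin_by.median())
        reference_bin = int(np.clip(np.searchsorted(edges, med) - 1,
                                    0, len(labels) - 1))
    ref_vals = values[bins == reference_bin].to_numpy()

    rows = []
    for b in range(len(labels)):
        v = values[bins == b].to_numpy()
        n = v.size
        mean = float(v.mean()) if n else np.nan
        sem = float(v.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        if b == reference_bin:
            t, p = np.nan, 1.0
        elif n >= 2 and ref_vals.size >= 2:
            t, p = stats.ttest_ind(v, ref_vals, equal_var=True)
            t, p = float(t), float(p)
        else:
            t, p = np.nan, np.nan
        rows.append({"bin": labels[b], "bin_low": edges[b],
                     "bin_high": edges[b + 1],
                     "is_reference": b == reference_bin, "n": n,
                     "mean": mean, "sem": sem, "t": t, "p": p,
                     "stars": significance_tier(p)
                     if b != reference_bin else ""})
    return pd.DataFrame(rows)


def length_bin_analysis(delta_tl: pd.Series, lengths: pd.Series,
                        bin_edges=None,
                        reference_bin: int | None = None) -> pd.DataFrame:
    """Mean Dlog2 TL +/- SEM per length bin, t-tested against a
    reference bin.

    ``bin_edges`` default to the deciles of the length distribution;
    ``reference_bin=None`` picks the bin holding the median length.
    The same machinery can be run in the transposed orientation (bin on
    Dlog2 TL, compare lengths) via :func:`bin_ttest_table`.
    """
    if bin_edges is None:
        qs = np.quantile(lengths.dropna().to_numpy(dtype=float),
                         np.linspace(0, 1, 11))
        bin_edges = np.unique(qs)
        bin_edges[0] -= 1e-9
        bin_edges[-1] += 1e-9
    return bin_ttest_table(lengths, delta_tl, bin_edges,
                           reference_bin=reference_bin)


# ----------------------------------------------------------------------
# concordance and correlation
# ----------------------------------------------------------------------

def sign_concordance_test(deltas, alternative: str = "greater") -> dict:
    """Are the selected Dlog2 TL values shifted from zero in the stated
    direction?

    Runs the Wilcoxon signed-rank test (exact distribution for n <= 25
    without ties, normal approximation with continuity correction
    above) and, because "ranked sign test" can also mean the plain sign
    test, the binomial sign test alongside.  Zero deltas are dropped;
    if all deltas are zero both p-values are 1.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[np.isfinite(d)]
    if d.size == 0:
        raise ValueError("empty selector")
    d = d[d != 0]
    if d.size == 0:
        return {"n": 0, "wilcoxon_p": 1.0, "sign_p": 1.0}
    n = d.size
    n_pos = int((d > 0).sum())
    sign_p = stats.binomtest(n_pos, n, 0.5, alternative=alternative).pvalue
    if n == 1:
        # degenerate for the signed-rank statistic; the sign test carries
        wilc_p = sign_p
    else:
        method = "exact" if (n <= 25
                             and np.unique(np.abs(d)).size == n) \
            else "approx"
        wilc_p = stats.wilcoxon(d, alternative=alternative, method=method,
                                correction=(method == "approx")).pvalue
    return {"n": n, "wilcoxon_p": float(wilc_p), "sign_p": float(sign_p)}


def pearson_r2(x, y) -> dict:
    """Squared Pearson correlation with its sign.

    Needs >= 3 paired finite values and non-zero variance in both
    vectors; otherwise R^2 is undefined (missing, ``defined=False``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r2": np.nan, "sign": 0, "n": int(x.size),
                "defined": False}
    r = stats.pearsonr(x, y)[0]
    return {"r2": float(r * r), "sign": int(np.sign(r)), "n": int(x.size),
            "defined": True}
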
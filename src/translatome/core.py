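"""Translation states and mutant-vs-wild-type differentials.

The translation state (TL) of an mRNA is the ratio of its signal in the
polysomal (PL) to the non-polysomal (NP) sucrose-gradient fraction,
reported on the log2 scale:

    log2 TL = log2(PL / NP)

An mRNA that is 80% polysomal and 20% non-polysomal has TL = 4.0 and
log2 TL = +2.0.  Because PL and NP are both proportional to transcript
abundance, TL is independent of the transcript level: multiplying both
fractions by any positive constant leaves it unchanged.

Differential translation between a mutant and the wild-type is the
log-difference

    Dlog2 TL = mean log2 TL(mut) - mean log2 TL(WT),

with the same contract applied to total-transcript (TC) signals to give
Dlog2 TC.  Replicate TLs are log-transformed first and averaged second.
No global polysome-shift adjustment is applied by default (a hook
exists), so results speak to gene-specific changes only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import SignalMatrix

__all__ = ["translation_state", "polysomal_fraction", "delta_log2",
           "build_translation_state_table"]


def translation_state(pl, np_signal, log2_input: bool = False):
    """log2 translation state from paired PL and NP signals.

    Parameters
    ----------
    pl, np_signal
        Scalars or arrays of polysomal and non-polysomal signals.  On
        the linear scale non-positive values yield a missing value
        (never +/-inf); with ``log2_input=True`` the inputs are already
        log2 signals and the result is their difference.

    Returns
    -------
    log2 TL, same shape as the inputs (scalar in, scalar out).
    """
    pl = np.asarray(pl, dtype=float)
    np_ = np.asarray(np_signal, dtype=float)
    if log2_input:
        out = pl - np_
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where((pl > 0) & (np_ > 0),
                           np.log2(np.where(pl > 0, pl, 1.0))
                           - np.log2(np.where(np_ > 0, np_, 1.0)),
                           np.nan)
    return out.item() if out.ndim == 0 else out


def polysomal_fraction(log2_tl):
    """Proportion of an mRNA in the polysomal fraction implied by its
    log2 TL; the inverse of :func:`translation_state` on fractional
    inputs.  log2 TL = 2.0 maps to 0.80, -2.0 to 0.20."""
    x = np.asarray(log2_tl, dtype=float)
    t = np.exp2(x)
    out = t / (1.0 + t)
    # 2**x overflows for very large x; the limit is 1.
    out = np.where(np.isinf(t), 1.0, out)
    return out.item() if out.ndim == 0 else out


def delta_log2(values_mut, values_wt, return_paired: bool = True):
    """Mean log2 difference between mutant and wild-type replicates.

    Returns ``delta`` (mean(mut) - mean(wt)) and, when replicate counts
    are equal and ``return_paired``, the per-replicate-pair differences
    used by the ad hoc replicate-consistency filter; otherwise the
    per-replicate differences against the wild-type mean.
    """
    mut = np.asarray(values_mut, dtype=float)
    wt = np.asarray(values_wt, dtype=float)
    if mut.size == 0 or wt.size == 0:
        raise ValueError("delta_log2 requires >=1 replicate on each side")
    delta = float(np.nanmean(mut) - np.nanmean(wt))
    if not return_paired:
        return delta
    if mut.shape == wt.shape:
        paired = mut - wt
    else:
        paired = mut - np.nanmean(wt)
    return delta, paired


def _replicate_tl(signals: SignalMatrix, genotype: str) -> pd.DataFrame:
    pl = signals.select(genotype=genotype, fraction="PL")
    np_ = signals.select(genotype=genotype, fraction="NP")
    if pl.shape[1] != np_.shape[1]:
        raise ValueError(
            f"genotype {genotype!r}: {pl.shape[1]} PL arrays but "
            f"{np_.shape[1]} NP arrays")
    if pl.shape[1] == 0:
        raise ValueError(f"genotype {genotype!r} has no PL/NP arrays")
    reps = [c.rsplit(".", 1)[1] for c in pl.columns]
    tl = pd.DataFrame(pl.to_numpy() - np_.to_numpy(), index=pl.index,
                      columns=[f"tl.{genotype}.{r}" for r in reps])
    return tl


def build_translation_state_table(signals: SignalMatrix,
                                  wild_type: str = "WT") -> pd.DataFrame:
    """Per-gene translation-state table from a log2 signal matrix.

    Columns
    -------
    ``tl.<genotype>.<rep>``
        Replicate log2 TL (log2 PL - log2 NP, replicate-matched).
    ``mean_tl.<genotype>``
        Mean over available replicates (genes with a missing replicate
        use the remaining ones; all-missing genes stay missing).
    ``delta_tl.<mutant>`` / ``delta_tc.<mutant>``
        mean log2 TL (or TC) of the mutant minus the wild-type.
    """
    if not signals.log2:
        raise ValueError("translation-state table requires log2 signals; "
                         "call SignalMatrix.log2_transform() first")
    genotypes = signals.genotypes
    if wild_type not in genotypes:
        raise ValueError(f"wild-type label {wild_type!r} not found; "
                         f"genotypes present: {genotypes}")

    pieces = []
    mean_tl = {}
    mean_tc = {}
    for g in genotypes:
        tl = _replicate_tl(signals, g)
        pieces.append(tl)
        mean_tl[g] = tl.mean(axis=1, skipna=True)
        tc = signals.select(genotype=g, fraction="TC")
        if tc.shape[1]:
            mean_tc[g] = tc.mean(axis=1, skipna=True)
    table = pd.concat(pieces, axis=1)
    for g in genotypes:
        table[f"mean_tl.{g}"] = mean_tl[g]
    for g in genotypes:
        if g == wild_type:
            continue
        table[f"delta_tl.{g}"] = mean_tl[g] - mean_tl[wild_type]
        if g in mean_tc and wild_type in mean_tc:
            table[f"delta_tc.{g}"] = mean_tc[g] - mean_tc[wild_type]
    table.index.name = "gene"
    return table
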
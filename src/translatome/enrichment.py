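"""Hypergeometric functional-category enrichment.

For a gene list of size n drawn from a universe of N genes, a category
with K members and k hits in the list is scored with the upper-tail
hypergeometric probability P(X >= k), X ~ Hypergeom(N, K, n), and the
fold enrichment (k/n) / (K/N).  p-values are Benjamini-Hochberg
adjusted across the tested categories.  The category map (e.g. GO
terms with ancestors pre-propagated) is taken as given; ontology-graph
propagation is a data-preparation concern, not done here.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .dtg import bh_fdr

log = logging.getLogger(__name__)

__all__ = ["hypergeom_enrichment", "read_category_map",
           "write_category_map", "category_map_from_annotation"]


def hypergeom_enrichment(gene_list: Iterable[str],
                         category_map: Mapping[str, Iterable[str]],
                         universe: Iterable[str]) -> pd.DataFrame:
    """Enrichment of each category in ``gene_list``.

    Returns a DataFrame with one row per tested category (``category``,
    ``k``, ``n``, ``K``, ``N``, ``fold``, ``p``, ``fdr``), sorted by
    adjusted p then category id.  Categories with no members in the
    universe are skipped with a log notice; an empty gene list raises.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    stray = genes - universe
    if stray:
        raise ValueError(f"{len(stray)} listed genes missing from the "
                         f"universe, e.g. {sorted(stray)[:3]}")
    N = len(universe)
    n = len(genes)
    rows = []
    for cat, members in category_map.items():
        members = set(members) & universe
        K = len(members)
        if K == 0:
            log.info("category %s has no members in the universe; skipped",
                     cat)
            continue
        k = len(members & genes)
        fold = (k / n) / (K / N)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"category": cat, "k": k, "n": n, "K": K, "N": N,
                     "fold": fold, "p": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(columns=["category", "k", "n", "K", "N",
                                     "fold", "p", "fdr"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["fdr", "p", "category"],
                           kind="mergesort").reset_index(drop=True)


def read_category_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (category, gene) TSV into a category map."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValueError("category map TSV needs two columns "
                         "(category, gene)")
    cat_col, gene_col = df.columns[:2]
    out: dict[str, set[str]] = {}
    for cat, sub in df.groupby(cat_col, sort=True):
        out[str(cat)] = set(sub[gene_col].astype(str))
    return out


def write_category_map(category_map: Mapping[str, Iterable[str]],
                       path: str | Path) -> None:
    rows = [(cat, g) for cat in sorted(category_map)
            for g in sorted(category_map[cat])]
    pd.DataFrame(rows, columns=["category", "gene"]).to_csv(
        path, sep="\t", index=False)


def category_map_from_annotation(annotation: pd.DataFrame,
                                 column: str = "category"
                                 ) -> dict[str, set[str]]:
    """Build a category map from a label column of the transcript
    annotation table."""
    out: dict[str, set[str]] = {}
    for cat, sub in annotation.groupby(column, sort=True):
        out[str(cat)] = set(sub.index.astype(str))
    return out
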
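"""Core data containers for fraction-level expression data.

A polysome-profiling experiment hybridizes three RNA fractions per
biological replicate: polysomal (``PL``), non-polysomal (``NP``, free +
monosomal), and total, unfractionated RNA (``TC``).  Signals are stored as
a genes x arrays table whose column names encode the sample metadata as
``genotype.fraction.replicate`` (e.g. ``WT.PL.1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

FRACTIONS = ("PL", "NP", "TC")

__all__ = ["FRACTIONS", "SampleName", "SignalMatrix", "DetectionCallMatrix",
           "parse_sample_name"]


@dataclass(frozen=True)
class SampleName:
    """Parsed array identifier: genotype, fraction and replicate index."""

    genotype: str
    fraction: str
    replicate: int

    def __str__(self) -> str:  # round-trips parse_sample_name
        return f"{self.genotype}.{self.fraction}.{self.replicate}"


def parse_sample_name(name: str) -> SampleName:
    """Parse a ``genotype.fraction.replicate`` column label.

    Raises
    ------
    ValueError
        If the label does not have three dot-separated fields, the
        fraction is not one of PL/NP/TC, or the replicate index is not a
        positive integer.
    """
    parts = str(name).split(".")
    if len(parts) != 3:
        raise ValueError(
            f"array id {name!r} does not follow genotype.fraction.replicate")
    genotype, fraction, rep = parts
    if fraction not in FRACTIONS:
        raise ValueError(
            f"array id {name!r} has invalid fraction {fraction!r}; "
            f"expected one of {FRACTIONS}")
    try:
        replicate = int(rep)
    except ValueError as exc:
        raise ValueError(f"array id {name!r}: replicate {rep!r} "
                         "is not an integer") from exc
    if replicate < 1:
        raise ValueError(f"array id {name!r}: replicate must be >= 1")
    return SampleName(genotype, fraction, replicate)


@dataclass
class SignalMatrix:
    """Genes x arrays expression signals with per-array metadata.

    Parameters
    ----------
    values
        DataFrame with unique gene ids in the index and
        ``genotype.fraction.replicate`` column labels.
    log2
        Whether ``values`` are on the log2 scale.  Linear-scale signals
        must be non-negative.
    """

    values: pd.DataFrame
    log2: bool = False
    _samples: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()[:5]
            raise ValueError(f"duplicate gene ids, e.g. {dups}")
        for col in self.values.columns:
            parse_sample_name(col)
        if not self.log2:
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValueError("negative values in a linear-scale "
                                 "signal matrix")

    # -- metadata ------------------------------------------------------
    @property
    def samples(self) -> pd.DataFrame:
        """Array metadata table (genotype, fraction, replicate)."""
        if self._samples is None:
            rows = [parse_sample_name(c) for c in self.values.columns]
            self._samples = pd.DataFrame(
                {"genotype": [r.genotype for r in rows],
                 "fraction": [r.fraction for r in rows],
                 "replicate": [r.replicate for r in rows]},
                index=self.values.columns)
        return self._samples

    @property
    def genotypes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.samples["genotype"]:
            seen.setdefault(g, None)
        return list(seen)

    def select(self, genotype: str | None = None,
               fraction: str | None = None) -> pd.DataFrame:
        """Sub-matrix for one genotype and/or fraction, columns sorted by
        replicate index."""
        meta = self.samples
        mask = pd.Series(True, index=meta.index)
        if genotype is not None:
            mask &= meta["genotype"] == genotype
        if fraction is not None:
            mask &= meta["fraction"] == fraction
        cols = meta.index[mask]
        order = meta.loc[cols, "replicate"].sort_values(kind="mergesort").index
        return self.values[order]

    # -- transforms ----------------------------------------------------
    def log2_transform(self, pseudocount: float = 0.0) -> "SignalMatrix":
        """Convert linear signals to log2.  Non-positive entries become
        missing values rather than -inf."""
        if self.log2:
            return self
        arr = self.values.to_numpy(dtype=float) + pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.log2(np.where(arr > 0, arr, np.nan))
        return SignalMatrix(pd.DataFrame(out, index=self.values.index,
                                         columns=self.values.columns),
                            log2=True)

    def with_values(self, values: pd.DataFrame) -> "SignalMatrix":
        return replace(self, values=values, _samples=None)

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.values.to_csv(path, sep="\t", index_label="gene",
                           float_format=float_format)

    @classmethod
    def from_tsv(cls, path: str | Path, log2: bool = False) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, log2=log2)


@dataclass
class DetectionCallMatrix:
    """Per-gene, per-array Present/Marginal/Absent expression calls."""

    calls: pd.DataFrame

    VALID = frozenset("PMA")

    def __post_init__(self) -> None:
        vals = set(pd.unique(self.calls.to_numpy().ravel()))
        bad = vals - self.VALID
        if bad:
            raise ValueError(f"invalid detection calls {sorted(bad)!r}; "
                             "expected P, M or A")

    def matches(self, signals: SignalMatrix) -> bool:
        return (self.calls.shape == signals.values.shape
                and list(self.calls.index) == list(signals.values.index)
                and list(self.calls.columns) == list(signals.values.columns))

    def to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DetectionCallMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def check_same_genes(frames: Iterable[pd.DataFrame]) -> None:
    """Raise if the frames do not share an identical gene index."""
    frames = list(frames)
    first = frames[0].index
    for f in frames[1:]:
        if not first.equals(f.index):
            raise ValueError("gene indexes differ between matrices")
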
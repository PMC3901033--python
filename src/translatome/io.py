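"""Dataset loading, cross-file validation and pipeline configuration.

The on-disk convention is plain TSV (tab-delimited, UTF-8, '.' decimal)
for matrices and tables, multi-FASTA for transcript sequences.  Signal
and call matrices carry genes in rows and ``genotype.fraction.replicate``
column labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .containers import DetectionCallMatrix, SignalMatrix

log = logging.getLogger(__name__)

__all__ = ["Dataset", "PipelineConfig", "load_dataset", "read_annotation",
           "read_sequences", "write_table"]


def write_table(df: pd.DataFrame, path: str | Path,
                index: bool = True, float_format: str = "%.6g") -> None:
    """Write a results table as TSV with a stable float format (keeps
    reruns byte-identical)."""
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if ann.index.has_duplicates:
        raise ValueError("duplicate gene ids in the annotation table")
    return ann


def read_sequences(path: str | Path) -> dict[str, str]:
    """Multi-FASTA -> {gene id: uppercase sequence}."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


@dataclass
class Dataset:
    """Validated in-memory bundle of one experiment."""

    signals: SignalMatrix
    calls: DetectionCallMatrix | None = None
    annotation: pd.DataFrame | None = None
    sequences: dict[str, str] | None = None
    wild_type: str = "WT"

    @property
    def mutants(self) -> list[str]:
        return [g for g in self.signals.genotypes if g != self.wild_type]


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis.

    Paths may be None when a stage's inputs are unavailable (the stage
    is then skipped with a warning where optional, or raises where
    required).
    """

    signals: str | Path | None = None
    calls: str | Path | None = None
    annotation: str | Path | None = None
    sequences: str | Path | None = None
    categories: str | Path | None = None
    outdir: str | Path = "translatome_out"
    wild_type: str = "WT"
    mutants: tuple[str, ...] | None = None  # None = all non-WT
    signals_are_log2: bool = False
    # thresholds
    fold_cutoff: float = 1.0
    alpha: float = 0.05
    sd_quantile: float = 0.80
    top_fraction: float = 0.20
    adhoc_min_abs_mean: float = 0.59
    absent_threshold: float = 6.0
    marginal_threshold: float = 7.0
    long_orf_nt: int = 1086
    # clustering
    n_clusters: int = 6
    fuzzifier: float = 1.1
    cluster_max_iter: int = 5000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "mutants" in data and data["mutants"] is not None:
            data["mutants"] = tuple(data["mutants"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = {}
        for k in self.__dataclass_fields__:
            v = getattr(self, k)
            out[k] = str(v) if isinstance(v, Path) else v
        return out


def load_dataset(config: PipelineConfig) -> Dataset:
    """Load and cross-validate the files referenced by a config.

    Hard errors: duplicate gene ids, invalid fraction labels, missing
    wild-type genotype, call/signal shape mismatch.  Genes present in
    the signals but absent from the annotation are reported with a
    count and excluded from feature analyses only.
    """
    if config.signals is None:
        raise ValueError("config.signals is required")
    signals = SignalMatrix.from_tsv(config.signals,
                                    log2=config.signals_are_log2)
    if config.wild_type not in signals.genotypes:
        raise ValueError(
            f"wild-type {config.wild_type!r} absent from the signal "
            f"matrix; genotypes present: {signals.genotypes}")

    calls = None
    if config.calls is not None:
        calls = DetectionCallMatrix.from_tsv(config.calls)
        if not calls.matches(signals):
            raise ValueError("detection-call matrix does not match the "
                             "signal matrix shape/labels")

    annotation = None
    if config.annotation is not None:
        annotation = read_annotation(config.annotation)
        missing = signals.values.index.difference(annotation.index)
        if len(missing):
            log.warning(
                "%d signal genes missing from the annotation (e.g. %s); "
                "they are excluded from feature analyses only",
                len(missing), list(missing[:5]))

    sequences = None
    if config.sequences is not None:
        sequences = read_sequences(config.sequences)
        if annotation is not None:
            stray = set(sequences) - set(annotation.index)
            if stray:
                log.warning("%d FASTA ids not in the annotation",
                            len(stray))

    return Dataset(signals=signals, calls=calls, annotation=annotation,
                   sequences=sequences, wild_type=config.wild_type)
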
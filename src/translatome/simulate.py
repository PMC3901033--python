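"""Synthetic polysome-microarray data with planted ground truth.

The generator emulates the structure of a seedling polysome-profiling
microarray study: for each genotype (wild-type first) and biological
replicate it emits linear-scale signals for the polysomal (PL),
non-polysomal (NP) and total (TC) fractions of ~20,000 genes, a
Present/Marginal/Absent detection-call matrix, a transcript annotation
table (UTR/CDS lengths, uORF counts, functional categories, paralog
families, compartments), transcript sequences, and a ground-truth
table recording every planted effect for recovery testing.

Statistical model (all on the log2 scale):

* every gene has a baseline abundance a_g and baseline translation
  state b_g (log2 PL/NP in the wild-type);
* a planted coregulated regulon block shifts b_g by
  ``regulon_delta_tl`` in the regulon-affected genotypes (emulating the
  joint overtranslation of ribosomal-protein mRNAs in a ribosomal
  protein / initiation-factor mutant);
* uORF-bearing genes are shifted by ``uorf_delta_tl`` (<= 0) in the
  uORF-affected genotypes;
* one genotype may carry a CDS-length-dependent shift
  ``length_effect_slope * (cds_length - median cds_length) / 1000``
  (emulating the length-dependent translational inhibition seen in a
  poly(A)-binding-protein mutant);
* PL and NP signals each receive independent Gaussian noise of SD
  ``noise_sd``, so replicate log2 TL has SD ``noise_sd * sqrt(2)``; TC
  is generated independently of TL;
* the ``dropout_quantile`` fraction of genes sits near the detection
  floor and is Absent-prone.

All randomness derives from a single seeded generator: identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import DetectionCallMatrix, SignalMatrix
from .preprocess import detection_calls

__all__ = ["SyntheticConfig", "generate_dataset",
           "generate_transcript_sequences", "write_dataset"]

COMPARTMENTS = ("cytosolic", "organellar_nuclear_encoded",
                "organellar_organelle_encoded", "other")
BACKGROUND_CATEGORIES = ("metabolism", "transport", "signaling",
                         "stress_response", "development", "unknown")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic polysome-microarray experiment.

    Defaults mirror the reference study design: a wild-type plus a
    ribosomal-protein-like mutant (``rpl``, regulon + uORF effects) and
    a PABP-like mutant (``pab``, CDS-length effect), three biological
    replicates each, ~20,000 genes with a 200-gene regulon.
    """

    n_genes: int = 20000
    genotypes: tuple[str, ...] = ("WT", "rpl", "pab")
    replicates_per_genotype: int | tuple[int, ...] = 3
    regulon_size: int = 200
    regulon_delta_tl: float = 1.5
    uorf_gene_fraction: float = 0.25
    uorf_delta_tl: float = -1.0
    length_effect_slope: float = 0.3
    noise_sd: float = 0.3
    dropout_quantile: float = 0.15
    seed: int = 0
    # which mutants carry which planted effect (None = defaults below)
    regulon_genotypes: tuple[str, ...] | None = None
    uorf_genotypes: tuple[str, ...] | None = None
    length_effect_genotype: str | None = None
    # marginal distributions
    baseline_tl_mean: float = 1.0
    baseline_tl_sd: float = 0.8
    abundance_mean: float = 9.0
    abundance_sd: float = 1.5
    dropout_abundance_mean: float = 4.5
    dropout_abundance_sd: float = 0.8
    absent_threshold: float = 6.0
    marginal_threshold: float = 7.0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.genotypes) < 1 or len(set(self.genotypes)) \
                != len(self.genotypes):
            raise ValueError("genotypes must be non-empty and unique")
        reps = self.replicates
        if min(reps) < 2:
            raise ValueError("each genotype needs >= 2 replicates")
        if max(reps) > 12:
            raise ValueError("replicates_per_genotype capped at 12")
        if self.regulon_size + self.n_uorf_genes > self.n_genes:
            raise ValueError("regulon_size + uORF genes exceeds n_genes")
        if self.regulon_size < 0:
            raise ValueError("regulon_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.dropout_quantile < 1:
            raise ValueError("dropout_quantile must be in [0, 1)")
        if not 0 <= self.uorf_gene_fraction <= 1:
            raise ValueError("uorf_gene_fraction must be in [0, 1]")
        if self.uorf_delta_tl > 0:
            raise ValueError("uorf_delta_tl must be <= 0 (repression)")
        for g in (self.regulon_genotypes or ()):
            if g not in self.genotypes:
                raise ValueError(f"unknown regulon genotype {g!r}")
        for g in (self.uorf_genotypes or ()):
            if g not in self.genotypes:
                raise ValueError(f"unknown uORF genotype {g!r}")
        if (self.length_effect_genotype is not None
                and self.length_effect_genotype not in self.genotypes):
            raise ValueError("unknown length-effect genotype "
                             f"{self.length_effect_genotype!r}")

    @property
    def wild_type(self) -> str:
        return self.genotypes[0]

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(self.genotypes[1:])

    @property
    def replicates(self) -> tuple[int, ...]:
        r = self.replicates_per_genotype
        if isinstance(r, int):
            return (r,) * len(self.genotypes)
        if len(r) != len(self.genotypes):
            raise ValueError("replicates_per_genotype tuple must match "
                             "genotypes")
        return tuple(int(x) for x in r)

    @property
    def n_uorf_genes(self) -> int:
        return int(round(self.uorf_gene_fraction * self.n_genes))

    def effect_genotypes(self) -> tuple[tuple[str, ...], tuple[str, ...],
                                        str | None]:
        """Resolved (regulon, uORF, length-effect) genotype targets.

        Defaults: regulon and uORF effects hit the first mutant; the
        length effect hits the second mutant when one exists.
        """
        muts = self.mutants
        regulon = self.regulon_genotypes
        if regulon is None:
            regulon = muts[:1]
        uorf = self.uorf_genotypes
        if uorf is None:
            uorf = muts[:1]
        length = self.length_effect_genotype
        if length is None and len(muts) >= 2:
            length = muts[1]
        return tuple(regulon), tuple(uorf), length


def _round3(x: np.ndarray, minimum: int) -> np.ndarray:
    out = (np.round(x / 3.0).astype(int) * 3)
    return np.maximum(out, minimum)


def _annotation(cfg: SyntheticConfig, rng: np.random.Generator
                ) -> tuple[pd.DataFrame, pd.Index, pd.Index]:
    width = len(str(cfg.n_genes))
    genes = pd.Index([f"G{i + 1:0{width}d}" for i in range(cfg.n_genes)],
                     name="gene")

    perm = rng.permutation(cfg.n_genes)
    regulon_idx = pd.Index(genes[np.sort(perm[:cfg.regulon_size])])
    uorf_idx = pd.Index(genes[np.sort(
        perm[cfg.regulon_size:cfg.regulon_size + cfg.n_uorf_genes])])

    cds = _round3(rng.lognormal(np.log(1086.0), 0.6, cfg.n_genes), 30)
    utr5 = np.maximum(rng.lognormal(np.log(120.0), 0.5,
                                    cfg.n_genes).astype(int), 12)
    utr3 = np.maximum(rng.lognormal(np.log(200.0), 0.5,
                                    cfg.n_genes).astype(int), 3)

    n_uorfs = np.zeros(cfg.n_genes, dtype=int)
    is_uorf = genes.isin(uorf_idx)
    n_uorfs[is_uorf] = rng.integers(1, 4, is_uorf.sum())
    # leaders must host the planted uORFs (>= 9 nt each plus spacing)
    need = 12 * n_uorfs + 6
    utr5 = np.maximum(utr5, need)

    category = np.array(rng.choice(BACKGROUND_CATEGORIES, cfg.n_genes),
                        dtype=object)
    category[genes.isin(regulon_idx)] = "ribosome"

    # regulon genes form paralog families of 2-4 sisters, r-protein style
    paralog = np.array([""] * cfg.n_genes, dtype=object)
    fam_sizes = []
    remaining = cfg.regulon_size
    while remaining > 0:
        s = int(min(rng.integers(2, 5), remaining))
        fam_sizes.append(s)
        remaining -= s
    pos = 0
    reg_positions = np.flatnonzero(genes.isin(regulon_idx))
    for fam_no, s in enumerate(fam_sizes, start=1):
        letters = "ABCDEFG"
        for j in range(s):
            paralog[reg_positions[pos + j]] = f"RP{fam_no}{letters[j]}"
        pos += s

    compartment = np.array(rng.choice(COMPARTMENTS, cfg.n_genes,
                                      p=(0.55, 0.1, 0.05, 0.3)),
                           dtype=object)
    compartment[genes.isin(regulon_idx)] = "cytosolic"
    incomplete = rng.random(cfg.n_genes) < 0.02

    ann = pd.DataFrame({"utr5_length": utr5, "cds_length": cds,
                        "utr3_length": utr3, "n_uorfs": n_uorfs,
                        "has_uorf": n_uorfs > 0, "category": category,
                        "paralog_family": paralog,
                        "compartment": compartment,
                        "incomplete_orf": incomplete}, index=genes)
    return ann, regulon_idx, uorf_idx


def generate_dataset(config: SyntheticConfig
                     ) -> tuple[SignalMatrix, DetectionCallMatrix,
                                pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic experiment.

    Returns
    -------
    signals : SignalMatrix
        Linear-scale genes x arrays signals, columns
        ``genotype.fraction.replicate`` for all PL/NP/TC triplets.
    calls : DetectionCallMatrix
        Threshold-based P/M/A calls on the same grid.
    annotation : DataFrame
        Transcript annotation (lengths, uORFs, categories, paralog
        family, compartment).
    truth : DataFrame
        Planted ground truth: baseline log2 TL, per-mutant targeted
        effect ``true_delta_tl_<mut>`` (regulon + uORF components) and
        ``length_effect_<mut>``; realized expected Dlog2 TL is their
        sum.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ann, regulon_idx, uorf_idx = _annotation(cfg, rng)
    genes = ann.index
    n = cfg.n_genes

    baseline_tl = rng.normal(cfg.baseline_tl_mean, cfg.baseline_tl_sd, n)
    abundance = rng.normal(cfg.abundance_mean, cfg.abundance_sd, n)
    n_drop = int(round(cfg.dropout_quantile * n))
    if n_drop:
        drop_pos = np.sort(rng.permutation(n)[:n_drop])
        abundance[drop_pos] = rng.normal(cfg.dropout_abundance_mean,
                                         cfg.dropout_abundance_sd, n_drop)

    reg_gts, uorf_gts, len_gt = cfg.effect_genotypes()
    in_regulon = genes.isin(regulon_idx)
    in_uorf = genes.isin(uorf_idx)
    cds = ann["cds_length"].to_numpy(dtype=float)
    length_term = cfg.length_effect_slope * (cds - np.median(cds)) / 1000.0

    targeted = {}
    length_effects = {}
    for g in cfg.mutants:
        eff = np.zeros(n)
        if g in reg_gts:
            eff = eff + cfg.regulon_delta_tl * in_regulon
        if g in uorf_gts:
            eff = eff + cfg.uorf_delta_tl * in_uorf
        targeted[g] = eff
        length_effects[g] = length_term if g == len_gt else np.zeros(n)

    cols = {}
    for g, n_rep in zip(cfg.genotypes, cfg.replicates):
        tl = baseline_tl + targeted.get(g, 0.0) + length_effects.get(g, 0.0)
        for r in range(1, n_rep + 1):
            log_pl = abundance + tl / 2.0 \
                + rng.normal(0.0, cfg.noise_sd, n)
            log_np = abundance - tl / 2.0 \
                + rng.normal(0.0, cfg.noise_sd, n)
            log_tc = abundance + rng.normal(0.0, cfg.noise_sd, n)
            cols[f"{g}.PL.{r}"] = np.exp2(log_pl)
            cols[f"{g}.NP.{r}"] = np.exp2(log_np)
            cols[f"{g}.TC.{r}"] = np.exp2(log_tc)

    signals = SignalMatrix(pd.DataFrame(cols, index=genes), log2=False)
    calls = detection_calls(signals.log2_transform(),
                            absent_threshold=cfg.absent_threshold,
                            marginal_threshold=cfg.marginal_threshold)

    truth = pd.DataFrame({"baseline_log2_tl": baseline_tl,
                          "baseline_log2_abundance": abundance,
                          "regulon_member": in_regulon,
                          "n_uorfs_planted": ann["n_uorfs"],
                          "cds_length": ann["cds_length"],
                          "utr5_length": ann["utr5_length"],
                          "utr3_length": ann["utr3_length"],
                          "category": ann["category"]}, index=genes)
    for g in cfg.mutants:
        truth[f"true_delta_tl_{g}"] = targeted[g]
        truth[f"length_effect_{g}"] = length_effects[g]
    return signals, calls, ann, truth


# ----------------------------------------------------------------------
# transcript sequences
# ----------------------------------------------------------------------

_SAFE_CODONS = ("TTC", "CTT", "TCC", "GCT", "CCT", "GGA", "CAC", "GAG")
_UORF_NT = 9  # ATG + one coding codon + stop


def _leader(rng: np.random.Generator, length: int, n_uorfs: int) -> str:
    """5' leader of exactly ``length`` nt containing exactly
    ``n_uorfs`` ATG-initiated ORFs with in-frame stops inside the
    leader, and no other ATG anywhere (filler uses C/T only, so no ATG
    can form across junctions)."""
    if n_uorfs * _UORF_NT > length:
        raise ValueError(
            f"5' leader of {length} nt cannot host {n_uorfs} uORFs "
            f"({_UORF_NT} nt each)")
    spare = length - n_uorfs * _UORF_NT
    # distribute the filler among the n_uorfs + 1 gaps
    gap_sizes = rng.multinomial(spare, np.full(n_uorfs + 1,
                                               1.0 / (n_uorfs + 1)))
    pieces = []
    for i in range(n_uorfs):
        pieces.append("".join(rng.choice(("C", "T"), gap_sizes[i])))
        pieces.append("ATG" + str(rng.choice(_SAFE_CODONS)) + "TAA")
    pieces.append("".join(rng.choice(("C", "T"), gap_sizes[n_uorfs])))
    return "".join(pieces)


def _main_orf(rng: np.random.Generator, cds_length: int) -> str:
    if cds_length < 9 or cds_length % 3:
        raise ValueError("cds_length must be a multiple of 3 and >= 9")
    n_codons = cds_length // 3 - 2
    body = "".join(rng.choice(_SAFE_CODONS, n_codons))
    return "ATG" + body + "TGA"


def generate_transcript_sequences(annotation: pd.DataFrame,
                                  seed: int = 0) -> list[SeqRecord]:
    """Emit one transcript per annotation row as a Biopython record.

    Each sequence is 5'UTR + main ORF + 3'UTR with the annotated
    lengths; the leader holds exactly ``n_uorfs`` planted uORFs and no
    spurious ATG, so a downstream uORF scan round-trips the counts.
    """
    rng = np.random.default_rng(seed)
    records = []
    for gene, row in annotation.iterrows():
        utr5 = int(row["utr5_length"])
        cds = int(row["cds_length"])
        utr3 = int(row["utr3_length"])
        n_uorfs = int(row.get("n_uorfs", 0))
        seq = (_leader(rng, utr5, n_uorfs)
               + _main_orf(rng, cds)
               + "".join(rng.choice(("A", "C", "G", "T"), utr3)))
        records.append(SeqRecord(
            Seq(seq), id=str(gene), description=(
                f"synthetic transcript cds_start={utr5} "
                f"cds_length={cds} n_uorfs={n_uorfs}")))
    return records


# ----------------------------------------------------------------------
# on-disk bundle
# ----------------------------------------------------------------------

def write_dataset(config: SyntheticConfig, outdir: str | Path,
                  write_sequences: bool = True) -> dict[str, Path]:
    """Generate and write the full bundle as TSV + FASTA.

    Files: ``signals.tsv``, ``calls.tsv``, ``annotation.tsv``,
    ``ground_truth.tsv`` and ``transcripts.fasta``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signals, calls, ann, truth = generate_dataset(config)
    paths = {"signals": outdir / "signals.tsv",
             "calls": outdir / "calls.tsv",
             "annotation": outdir / "annotation.tsv",
             "ground_truth": outdir / "ground_truth.tsv"}
    signals.to_tsv(paths["signals"])
    calls.to_tsv(paths["calls"])
    ann.to_csv(paths["annotation"], sep="\t", index_label="gene")
    truth.to_csv(paths["ground_truth"], sep="\t", index_label="gene",
                 float_format="%.6g")
    if write_sequences:
        paths["sequences"] = outdir / "transcripts.fasta"
        SeqIO.write(generate_transcript_sequences(ann, seed=config.seed),
                    str(paths["sequences"]), "fasta")
    return paths
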
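import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from translatome import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact two-genotype experiment with a planted regulon and
    uORF repression, reused across modules."""
    cfg = SyntheticConfig(
        n_genes=400, genotypes=("WT", "mut"), replicates_per_genotype=3,
        regulon_size=40, regulon_delta_tl=1.5, uorf_gene_fraction=0.1,
        uorf_delta_tl=-1.0, noise_sd=0.2, dropout_quantile=0.1, seed=7)
    signals, calls, annotation, truth = generate_dataset(cfg)
    return {"config": cfg, "signals": signals, "calls": calls,
            "annotation": annotation, "truth": truth}


@pytest.fixture(scope="session")
def small_log2(small_dataset):
    return small_dataset["signals"].log2_transform()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_signal_frame():
    """Hand-sized linear signal matrix (3 genes, WT + mut, 2 reps)."""
    cols = {}
    for g in ("WT", "mut"):
        for r in (1, 2):
            cols[f"{g}.PL.{r}"] = [8.0, 4.0, 2.0]
            cols[f"{g}.NP.{r}"] = [2.0, 4.0, 8.0]
            cols[f"{g}.TC.{r}"] = [10.0, 8.0, 10.0]
    return pd.DataFrame(cols, index=["g1", "g2", "g3"])
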
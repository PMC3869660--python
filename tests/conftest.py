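"""Shared fixtures: small hand-made tables and one large simulated study."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import aimpanel as ap

DATA = Path(__file__).parent / "data"


@pytest.fixture
def greedy_freqs() -> ap.FreqTable:
    """Committed 3-population, 8-SNP frequency fixture for the greedy trace."""
    df = pd.read_csv(DATA / "greedy_fixture_freqs.tsv", sep="\t", index_col="snp_id")
    n_obs = pd.DataFrame(100.0, index=df.index, columns=df.columns)
    return ap.FreqTable(df, n_obs)


@pytest.fixture
def greedy_trace() -> pd.DataFrame:
    return pd.read_csv(DATA / "greedy_fixture_trace.tsv", sep="\t")


@pytest.fixture
def greedy_map(greedy_freqs) -> ap.SnpMap:
    """One chromosome, SNPs 1 kb apart (constraints disabled in trace tests)."""
    ids = greedy_freqs.snp_ids
    table = pd.DataFrame(
        {
            "chrom": "1",
            "cm": 0.0,
            "bp": [1000 * (i + 1) for i in range(len(ids))],
            "allele1": "A",
            "allele2": "G",
        },
        index=pd.Index(ids, name="snp_id"),
    )
    return ap.SnpMap(table)


def random_freq_table(rng: np.random.Generator, n_snps: int, k: int) -> ap.FreqTable:
    pops = [f"p{i + 1}" for i in range(k)]
    idx = pd.Index([f"s{i + 1}" for i in range(n_snps)], name="snp_id")
    freq = pd.DataFrame(rng.random((n_snps, k)), index=idx, columns=pops)
    n_obs = pd.DataFrame(
        rng.integers(10, 200, size=(n_snps, k)).astype(float), index=idx, columns=pops
    )
    return ap.FreqTable(freq, n_obs)


@pytest.fixture(scope="session")
def big_study() -> ap.SimStudy:
    """The reference simulation scenario: five sources at ordered divergence,
    genome-density map, 200 admixed individuals with known truth."""
    return ap.simulate_study(
        n_snps=20_000,
        k=5,
        fst=(0.20, 0.15, 0.12, 0.10, 0.08),
        n_admixed=200,
        n_per_pop=40,
        dirichlet_alpha=(3.1, 2.6, 1.8, 1.2, 0.7),
        seed=1,
    )


@pytest.fixture(scope="session")
def big_panel_500(big_study) -> ap.SelectionResult:
    """A 500-marker panel selected once; smaller panels are its prefixes."""
    cfg = ap.SelectionConfig(n_aims=500)
    return ap.select_aims(big_study.freq_table, big_study.snp_map, big_study.admixed, cfg)
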
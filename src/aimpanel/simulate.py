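"""Synthetic cohorts for panel design and evaluation.

Source populations diverge from a shared ancestral population under the
Balding-Nichols model: at a SNP with ancestral allele-1 frequency p, the
frequency in a population with drift parameter F (its Fst from the ancestor)
is Beta(p(1-F)/F, (1-p)(1-F)/F), giving mean p and variance F*p*(1-p).  The
populations drift independently (a star phylogeny, with no shared branches
or LD), which is the simplest forward model producing controllable,
unequal pairwise divergences between sources.

Admixed individuals draw ancestry proportions from a Dirichlet distribution
and each of their two allele copies independently picks an ancestral
population from those proportions, then an allele from that population's
frequency.  The default Dirichlet concentration (3.1, 2.6, 1.8, 1.2, 0.7)
reproduces the median five-way ancestry profile of a Cape Town admixed
cohort (approximately 0.31/0.26/0.18/0.12/0.07 for San, African non-San,
European, South Asian and East Asian ancestry) while its total (~9.4) gives
realistic inter-individual spread.

All draws flow from a single integer seed via numpy Generators.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AncestryMatrix,
    DataError,
    FreqTable,
    GenotypeMatrix,
    SnpMap,
    SourceFreqs,
    pair_label,
)

__all__ = [
    "SimTruth",
    "SimStudy",
    "DEFAULT_FST",
    "DEFAULT_ALPHA",
    "DEFAULT_POPULATIONS",
    "simulate_source_freqs",
    "simulate_snp_map",
    "simulate_reference_panel",
    "simulate_admixed",
    "simulate_study",
    "inject_duplicates",
    "pairwise_fst",
]

#: Per-population drift (Fst from the shared ancestor) for the default
#: five-way scenario: divergences ordered San > African non-San > European >
#: South Asian > East Asian.
DEFAULT_FST = (0.20, 0.15, 0.12, 0.10, 0.08)

#: Dirichlet concentration mimicking the Cape Town median ancestry profile.
DEFAULT_ALPHA = (3.1, 2.6, 1.8, 1.2, 0.7)

DEFAULT_POPULATIONS = ("san", "afr", "eur", "sas", "eas")

#: Rough human autosome lengths (Mb) used to lay simulated SNPs out on a map.
_CHROM_MB = (
    249, 243, 198, 191, 181, 171, 159, 146, 141, 136, 135, 134,
    115, 107, 102, 90, 81, 78, 59, 63, 48, 51,
)

_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass
class SimTruth:
    """Ground truth of a simulated scenario."""

    ancestral_freqs: np.ndarray
    fst: np.ndarray
    source_freqs: SourceFreqs
    dirichlet_alpha: np.ndarray | None
    q_true: AncestryMatrix | None
    seed: int


def _check_fst(fst: Sequence[float], k: int) -> np.ndarray:
    arr = np.asarray(fst, dtype=float)
    if arr.ndim == 0:
        arr = np.repeat(arr, k)
    if arr.shape != (k,):
        raise DataError(f"need one fst per population ({k}), got shape {arr.shape}")
    if ((arr <= 0) | (arr >= 1)).any():
        raise DataError("each fst must lie strictly in (0, 1)")
    return arr


def simulate_source_freqs(
    n_snps: int,
    k: int = 5,
    fst: Sequence[float] | float | None = None,
    populations: Sequence[str] | None = None,
    ancestral_low: float = 0.05,
    ancestral_high: float = 0.95,
    seed: int = 1,
) -> tuple[SourceFreqs, SimTruth]:
    """Draw per-population allele frequencies under Balding-Nichols drift.

    Ancestral frequencies are i.i.d. Uniform(ancestral_low, ancestral_high);
    each population then drifts independently by its fst.
    """
    if n_snps < 1 or k < 2:
        raise DataError("need n_snps >= 1 and k >= 2")
    if fst is None:
        fst = DEFAULT_FST[:k] if k <= len(DEFAULT_FST) else 0.1
    fst_arr = _check_fst(fst, k)
    if populations is None:
        populations = (
            list(DEFAULT_POPULATIONS[:k])
            if k <= len(DEFAULT_POPULATIONS)
            else [f"pop{i + 1}" for i in range(k)]
        )
    rng = np.random.default_rng(seed)
    p = rng.uniform(ancestral_low, ancestral_high, size=n_snps)
    freqs = np.empty((n_snps, k))
    for j in range(k):
        f = fst_arr[j]
        a = p * (1.0 - f) / f
        b = (1.0 - p) * (1.0 - f) / f
        freqs[:, j] = rng.beta(a, b)
    idx = pd.Index([f"snp{i + 1}" for i in range(n_snps)], name="snp_id")
    source = SourceFreqs(pd.DataFrame(freqs, index=idx, columns=list(populations)))
    truth = SimTruth(p, fst_arr, source, None, None, seed)
    return source, truth


def simulate_snp_map(n_snps: int, seed: int = 1) -> SnpMap:
    """Lay SNPs across the 22 autosomes with uniform random positions.

    Chromosomes receive SNP counts proportional to their physical length, so
    typical inter-marker spacing matches a genome-wide chip at the requested
    density.
    """
    rng = np.random.default_rng(seed)
    lengths = np.asarray(_CHROM_MB, dtype=float) * 1_000_000
    counts = np.maximum(1, np.round(n_snps * lengths / lengths.sum()).astype(int))
    # adjust rounding drift so counts sum to n_snps exactly
    while counts.sum() > n_snps:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < n_snps:
        counts[np.argmin(counts)] += 1
    rows = []
    i = 0
    for c, (count, length) in enumerate(zip(counts, lengths), start=1):
        pos = np.sort(rng.choice(int(length), size=count, replace=False)) + 1
        for bp in pos:
            a1, a2 = _ALLELE_PAIRS[rng.integers(len(_ALLELE_PAIRS))]
            rows.append((f"snp{i + 1}", str(c), 0.0, int(bp), a1, a2))
            i += 1
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "cm", "bp", "allele1", "allele2"])
    return SnpMap(table.set_index("snp_id"))


def simulate_reference_panel(
    source: SourceFreqs, n_per_pop: int, seed: int = 1
) -> GenotypeMatrix:
    """Reference individuals: dosage ~ Binomial(2, f) per SNP, labelled by
    population."""
    if n_per_pop < 1:
        raise DataError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    F = source.freq.to_numpy(dtype=float)
    m, k = F.shape
    blocks = []
    ids = []
    labels = []
    for j, pop in enumerate(source.populations):
        blocks.append(rng.binomial(2, F[:, j], size=(n_per_pop, m)).astype(float))
        ids.extend(f"{pop}_{i + 1}" for i in range(n_per_pop))
        labels.extend([pop] * n_per_pop)
    return GenotypeMatrix(
        np.vstack(blocks), ids, source.snp_ids, np.asarray(labels, dtype=object)
    )


def simulate_admixed(
    source: SourceFreqs,
    n_ind: int,
    dirichlet_alpha: Sequence[float] | None = None,
    seed: int = 1,
) -> tuple[GenotypeMatrix, AncestryMatrix]:
    """Admixed cohort with known ancestry truth.

    Each individual draws q ~ Dirichlet(alpha); each of the two allele
    copies at every SNP draws an ancestral population from q, then an allele
    from that population's frequency.
    """
    F = source.freq.to_numpy(dtype=float)
    m, k = F.shape
    alpha = np.asarray(
        dirichlet_alpha if dirichlet_alpha is not None else DEFAULT_ALPHA[:k], dtype=float
    )
    if alpha.shape != (k,):
        raise DataError(f"alpha must have length {k}")
    if (alpha <= 0).any():
        raise DataError("alpha must be positive")
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(alpha, size=n_ind)
    dosage = np.zeros((n_ind, m))
    for i in range(n_ind):
        cum = np.cumsum(Q[i])
        cum[-1] = 1.0
        for _copy in range(2):
            pop = np.searchsorted(cum, rng.random(m), side="right")
            dosage[i] += rng.random(m) < F[np.arange(m), pop]
    ids = [f"adm_{i + 1}" for i in range(n_ind)]
    q = AncestryMatrix(
        pd.DataFrame(Q, index=pd.Index(ids, name="individual_id"), columns=source.populations)
    )
    return GenotypeMatrix(dosage, ids, source.snp_ids), q


@dataclass
class SimStudy:
    """A complete simulated study: map, source frequencies (true and
    estimated from the reference panel), reference individuals, admixed
    cohort and its ancestry truth."""

    snp_map: SnpMap
    source_freqs: SourceFreqs
    freq_table: FreqTable
    reference: GenotypeMatrix
    admixed: GenotypeMatrix
    q_true: AncestryMatrix
    truth: SimTruth


def simulate_study(
    n_snps: int,
    k: int = 5,
    fst: Sequence[float] | None = None,
    n_admixed: int = 200,
    n_per_pop: int = 40,
    dirichlet_alpha: Sequence[float] | None = None,
    seed: int = 1,
) -> SimStudy:
    """Bundle generator: one call yields every input the pipeline needs.

    Sub-seeds for the map, reference panel and admixed cohort are derived
    from ``seed`` so the pieces are independent but jointly reproducible.
    """
    from .informativeness import allele_freqs

    ss = np.random.SeedSequence(seed)
    s_freq, s_map, s_ref, s_adm = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4))
    source, truth = simulate_source_freqs(n_snps, k, fst, seed=s_freq)
    snp_map = simulate_snp_map(n_snps, seed=s_map)
    reference = simulate_reference_panel(source, n_per_pop, seed=s_ref)
    admixed, q_true = simulate_admixed(source, n_admixed, dirichlet_alpha, seed=s_adm)
    freq_table = allele_freqs(reference)
    truth.q_true = q_true
    truth.dirichlet_alpha = np.asarray(
        dirichlet_alpha if dirichlet_alpha is not None else DEFAULT_ALPHA[:k], dtype=float
    )
    return SimStudy(snp_map, source, freq_table, reference, admixed, q_true, truth)


def inject_duplicates(
    study: SimStudy, snp_ids: Sequence[str], seed: int = 1
) -> SimStudy:
    """Clone the given SNPs as exact-duplicate markers (new ids, positions on
    other chromosomes) to exercise the LD acceptance check."""
    rng = np.random.default_rng(seed)
    map_t = study.snp_map.table.copy()
    freq = study.freq_table.freq.copy()
    n_obs = study.freq_table.n_obs.copy()
    src = study.source_freqs.freq.copy()
    adm_cols = {s: study.admixed.column(s).copy() for s in snp_ids}
    ref_cols = {s: study.reference.column(s).copy() for s in snp_ids}
    new_rows = []
    for s in snp_ids:
        dup = f"{s}_dup"
        orig = map_t.loc[s]
        other = [c for c in map_t["chrom"].unique() if c != orig["chrom"]]
        chrom = other[rng.integers(len(other))] if other else orig["chrom"]
        new_rows.append((dup, chrom, 0.0, int(rng.integers(1, 200_000_000)), orig["allele1"], orig["allele2"]))
        freq.loc[dup] = freq.loc[s]
        n_obs.loc[dup] = n_obs.loc[s]
        src.loc[dup] = src.loc[s]
    add = pd.DataFrame(
        new_rows, columns=["snp_id", "chrom", "cm", "bp", "allele1", "allele2"]
    ).set_index("snp_id")
    new_map = SnpMap(pd.concat([map_t, add]))
    dup_ids = list(add.index)
    adm = GenotypeMatrix(
        np.hstack([study.admixed.dosage] + [adm_cols[s][:, None] for s in snp_ids]),
        study.admixed.individual_ids,
        study.admixed.snp_ids + dup_ids,
        study.admixed.pop_labels,
    )
    ref = GenotypeMatrix(
        np.hstack([study.reference.dosage] + [ref_cols[s][:, None] for s in snp_ids]),
        study.reference.individual_ids,
        study.reference.snp_ids + dup_ids,
        study.reference.pop_labels,
    )
    return SimStudy(
        new_map,
        SourceFreqs(src),
        FreqTable(freq, n_obs),
        ref,
        adm,
        study.q_true,
        study.truth,
    )


def pairwise_fst(source: SourceFreqs | pd.DataFrame) -> pd.Series:
    """Empirical pairwise Fst between source populations from frequencies.

    Ratio-of-averages estimator: Fst(a,b) = mean((pa-pb)^2) / mean(pa(1-pb)
    + pb(1-pa)); under independent Balding-Nichols drift its expectation is
    (Fa+Fb)/2, monotone in the configured per-population drift.
    """
    freq = source.freq if isinstance(source, SourceFreqs) else source
    out = {}
    for a, b in combinations(sorted(freq.columns), 2):
        pa = freq[a].to_numpy(dtype=float)
        pb = freq[b].to_numpy(dtype=float)
        num = np.mean((pa - pb) ** 2)
        den = np.mean(pa * (1 - pb) + pb * (1 - pa))
        out[pair_label(a, b)] = num / den if den > 0 else np.nan
    return pd.Series(out, name="fst")
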
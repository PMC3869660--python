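"""Rosenberg's informativeness-for-assignment statistic and related filters.

For a biallelic SNP with allele-1 frequency ``p_i`` in each of K populations,
the informativeness for assignment is

    In = sum over alleles j in {1,2} of
         ( -pbar_j * ln(pbar_j)  +  sum_i (p_ij / K) * ln(p_ij) )

where ``pbar_j`` is the unweighted mean of ``p_ij`` over the K populations
(the frequency in the "average population") and ``0 * ln 0`` is defined as 0.
``In`` is the expected log-likelihood ratio for assigning a random allele to
its population of origin versus the average population: 0 when every
population shares the same frequency, and at most ``ln 2`` for biallelic
markers (attained when an allele is fixed in one population and absent in the
other).  Natural logarithms throughout; rankings are base-invariant.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .datamodel import DataError, FreqTable, GenotypeMatrix, pair_label

__all__ = [
    "allele_freqs",
    "informativeness",
    "pairwise_informativeness",
    "heterogeneity_filter",
]

#: Upper bound of In for biallelic markers.
LN2 = float(np.log(2.0))


def allele_freqs(genotypes: GenotypeMatrix, labels: Sequence[str] | None = None) -> FreqTable:
    """Per-population allele-1 frequencies from dosages, with pairwise deletion.

    ``freq = (sum of observed dosages) / (2 * number of non-missing
    individuals)`` per population; ``n_obs`` is the number of observed allele
    copies.  A population with zero observed copies at a SNP yields a missing
    frequency, flagging the SNP unusable there.
    """
    if labels is None:
        labels = genotypes.pop_labels
    if labels is None:
        raise DataError("allele_freqs requires population labels")
    labels = np.asarray(labels, dtype=object)
    pops = list(dict.fromkeys(labels))
    for pop in pops:
        if not (labels == pop).any():
            raise DataError(f"empty population group {pop!r}")
    freq = {}
    n_obs = {}
    D = genotypes.dosage
    for pop in pops:
        rows = labels == pop
        sub = D[rows]
        observed = ~np.isnan(sub)
        copies = 2.0 * observed.sum(axis=0)
        total = np.nansum(sub, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(copies > 0, total / np.maximum(copies, 1e-300), np.nan)
        freq[pop] = f
        n_obs[pop] = copies
    idx = pd.Index(genotypes.snp_ids, name="snp_id")
    return FreqTable(pd.DataFrame(freq, index=idx), pd.DataFrame(n_obs, index=idx))


def _in_from_matrix(P: np.ndarray) -> np.ndarray:
    """Vectorized In over a SNPs x K allele-1 frequency matrix."""
    k = P.shape[1]
    total = np.zeros(P.shape[0])
    for A in (P, 1.0 - P):  # the two alleles of a biallelic marker
        abar = A.mean(axis=1)
        total += -xlogy(abar, abar) + xlogy(A, A).sum(axis=1) / k
    # exact-tie inputs can land an epsilon below zero in floating point
    return np.maximum(total, 0.0)


def informativeness(freqs: FreqTable, subset: Sequence[str] | None = None) -> pd.Series:
    """In per SNP over ``subset`` populations (default: all populations).

    Raises for subsets smaller than two populations; SNPs with a missing
    frequency in any subset population get a missing In.
    """
    pops = list(subset) if subset is not None else freqs.populations
    if len(pops) < 2:
        raise DataError("informativeness requires at least 2 populations")
    P = freqs.freq[pops].to_numpy(dtype=float)
    missing = np.isnan(P).any(axis=1)
    vals = np.full(P.shape[0], np.nan)
    if (~missing).any():
        vals[~missing] = _in_from_matrix(P[~missing])
    return pd.Series(vals, index=freqs.freq.index, name="in_value")


def pairwise_informativeness(freqs: FreqTable) -> pd.DataFrame:
    """In per SNP for every unordered population pair.

    Returns a SNPs x C(K,2) frame whose columns are canonical pair labels
    (lexicographically sorted, colon-joined).
    """
    cols = {}
    for a, b in combinations(sorted(freqs.populations), 2):
        cols[pair_label(a, b)] = informativeness(freqs, [a, b])
    return pd.DataFrame(cols, index=freqs.freq.index)


def _pearson_chi2(counts: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared statistic and df for an R x C contingency table."""
    counts = np.asarray(counts, dtype=float)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    grand = counts.sum()
    expected = row @ col / grand
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return stat, df


def heterogeneity_filter(
    subgroup_freqs: FreqTable,
    grouping: Mapping[str, str],
    alpha: float = 0.05,
) -> tuple[set, pd.DataFrame]:
    """Chi-squared screen for allele-frequency heterogeneity within sources.

    ``subgroup_freqs`` holds frequencies per *subgroup* (e.g. the individual
    cohorts pooled into one source population); ``grouping`` maps each
    subgroup label to its source population.  For every source with >= 2
    subgroups a Pearson chi-squared test (df = S - 1) compares the 2 x S
    allele-count table against the null of equal frequencies; a SNP is
    discarded if any source's test has p < ``alpha``.

    A source whose table is degenerate (monomorphic across subgroups, or
    fewer than two subgroups with observed alleles) is skipped and the SNP
    kept for that source.

    Returns the kept snp_id set and a per-(SNP, source) report with the
    statistic, df, p-value and decision.
    """
    sources: dict[str, list[str]] = {}
    for sub, src in grouping.items():
        sources.setdefault(src, []).append(sub)
    unknown = [s for s in grouping if s not in subgroup_freqs.populations]
    if unknown:
        raise DataError(f"grouping names unknown subgroup(s): {unknown}")

    records = []
    discarded: set = set()
    freq = subgroup_freqs.freq
    n_obs = subgroup_freqs.n_obs
    for snp_id in subgroup_freqs.snp_ids:
        for src in sorted(sources):
            subs = sorted(sources[src])
            if len(subs) < 2:
                records.append((snp_id, src, np.nan, 0, np.nan, "single-subgroup"))
                continue
            f = freq.loc[snp_id, subs].to_numpy(dtype=float)
            n = n_obs.loc[snp_id, subs].to_numpy(dtype=float)
            usable = (~np.isnan(f)) & (n > 0)
            if usable.sum() < 2:
                records.append((snp_id, src, np.nan, 0, np.nan, "skipped"))
                continue
            a1 = f[usable] * n[usable]
            a2 = (1.0 - f[usable]) * n[usable]
            table = np.vstack([a1, a2])
            if (table.sum(axis=1) == 0).any():
                # one allele absent everywhere: expected counts of zero
                records.append((snp_id, src, np.nan, 0, np.nan, "skipped"))
                continue
            stat, df = _pearson_chi2(table)
            p = float(chi2.sf(stat, df))
            decision = "discard" if p < alpha else "keep"
            records.append((snp_id, src, stat, df, p, decision))
            if decision == "discard":
                discarded.add(snp_id)
    report = pd.DataFrame(
        records, columns=["snp_id", "source", "chi2", "df", "p", "decision"]
    )
    kept = set(subgroup_freqs.snp_ids) - discarded
    return kept, report
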
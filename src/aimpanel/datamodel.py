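"""Core in-memory containers for AIM panel design.

The pipeline moves five kinds of tabular data around:

* :class:`SnpMap` — marker locations and alleles (PLINK ``.bim`` dialect);
* :class:`FreqTable` — per-population allele-1 frequencies with allele-copy
  counts (PLINK ``.frq.strat`` dialect);
* :class:`GenotypeMatrix` — individuals x SNPs allele-1 dosages (PLINK
  ``.traw`` dialect);
* :class:`PanelTable` — an ordered panel of selected ancestry informative
  markers together with the population pair each marker was selected for;
* :class:`AncestryMatrix` — individuals x K ancestry-proportion rows on the
  probability simplex.

All containers are thin dataclass wrappers around pandas/numpy objects and
validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "SnpMap",
    "FreqTable",
    "GenotypeMatrix",
    "PanelTable",
    "AncestryMatrix",
    "SourceFreqs",
    "pair_label",
    "canonical_pairs",
]


class DataError(ValueError):
    """Raised when an input file or container violates a structural invariant."""


def pair_label(pop_a: str, pop_b: str) -> str:
    """Canonical label for an unordered population pair (sorted, colon-joined)."""
    a, b = sorted((str(pop_a), str(pop_b)))
    return f"{a}:{b}"


def canonical_pairs(populations: Sequence[str]) -> list[tuple[str, str]]:
    """All C(K,2) unordered pairs, each sorted, in lexicographic order."""
    pops = sorted(str(p) for p in populations)
    return [(pops[i], pops[j]) for i in range(len(pops)) for j in range(i + 1, len(pops))]


@dataclass
class SnpMap:
    """Marker map: one row per SNP.

    ``table`` is indexed by snp_id with columns ``chrom`` (opaque string
    label), ``cm`` (genetic position, may be 0), ``bp`` (1-based base-pair
    position), ``allele1``, ``allele2``.
    """

    table: pd.DataFrame

    REQUIRED = ("chrom", "cm", "bp", "allele1", "allele2")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DataError(f"SnpMap missing columns: {missing}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate snp_id(s) in map: {dups[:5]}")
        if len(t) and (t["bp"] <= 0).any():
            bad = t.index[t["bp"] <= 0].tolist()
            raise DataError(f"non-positive bp position for {bad[:5]}")
        if len(t) and (t["allele1"].astype(str) == t["allele2"].astype(str)).any():
            bad = t.index[t["allele1"].astype(str) == t["allele2"].astype(str)].tolist()
            raise DataError(f"allele1 == allele2 for {bad[:5]}")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.table.index

    def subset(self, snp_ids: Iterable[str]) -> "SnpMap":
        ids = [s for s in snp_ids if s in self.table.index]
        return SnpMap(self.table.loc[ids])

    def alleles(self, snp_id: str) -> tuple[str, str]:
        row = self.table.loc[snp_id]
        return str(row["allele1"]), str(row["allele2"])


@dataclass
class FreqTable:
    """Per-SNP, per-population allele-1 frequencies.

    ``freq`` and ``n_obs`` are SNPs x populations frames sharing index and
    columns; ``n_obs`` counts observed allele copies (2 per genotyped
    individual).  A NaN frequency marks a SNP unusable in that population
    (zero observed copies).  ``alleles`` optionally records the (allele1,
    allele2) pair each frequency refers to, for cross-dataset harmonization.
    """

    freq: pd.DataFrame
    n_obs: pd.DataFrame
    alleles: pd.DataFrame | None = None  # columns allele1, allele2

    def __post_init__(self) -> None:
        if list(self.freq.columns) != list(self.n_obs.columns) or not self.freq.index.equals(
            self.n_obs.index
        ):
            raise DataError("freq and n_obs must share index and columns")
        if self.freq.shape[1] < 2:
            raise DataError(f"FreqTable needs K >= 2 populations, got {self.freq.shape[1]}")
        vals = self.freq.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any((vals < 0) | (vals > 1)):
                raise DataError("frequencies must lie in [0, 1]")
        if (self.n_obs.to_numpy(dtype=float) < 0).any():
            raise DataError("n_obs must be non-negative")
        if self.alleles is not None and not self.alleles.index.equals(self.freq.index):
            raise DataError("alleles index must match freq index")

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.freq.index)

    @property
    def k(self) -> int:
        return self.freq.shape[1]

    def unusable_snps(self) -> list[str]:
        """SNPs with a missing frequency in any population."""
        mask = self.freq.isna().any(axis=1)
        return list(self.freq.index[mask])

    def restrict(self, snp_ids: Iterable[str]) -> "FreqTable":
        ids = [s for s in snp_ids if s in self.freq.index]
        al = self.alleles.loc[ids] if self.alleles is not None else None
        return FreqTable(self.freq.loc[ids], self.n_obs.loc[ids], al)


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-1 dosage matrix.

    ``dosage`` is a float array with values in {0, 1, 2} and NaN for missing.
    ``pop_labels`` optionally assigns each individual to a population or
    subgroup.
    """

    dosage: np.ndarray
    individual_ids: list[str]
    snp_ids: list[str]
    pop_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise DataError("dosage must be 2-D (individuals x SNPs)")
        n, m = self.dosage.shape
        if n != len(self.individual_ids) or m != len(self.snp_ids):
            raise DataError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals / {len(self.snp_ids)} SNPs"
            )
        vals = self.dosage[~np.isnan(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise DataError("dosages must be in {0, 1, 2} or missing")
        if self.pop_labels is not None:
            self.pop_labels = np.asarray(self.pop_labels, dtype=object)
            if self.pop_labels.shape != (n,):
                raise DataError("pop_labels length must equal number of individuals")
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self._snp_index[snp_id]]

    def restrict(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self._snp_index[s] for s in snp_ids if s in self._snp_index]
        kept = [self.snp_ids[j] for j in idx]
        return GenotypeMatrix(self.dosage[:, idx], list(self.individual_ids), kept, self.pop_labels)

    def take_individuals(self, rows: Sequence[int]) -> "GenotypeMatrix":
        rows = list(rows)
        labels = self.pop_labels[rows] if self.pop_labels is not None else None
        return GenotypeMatrix(
            self.dosage[rows, :],
            [self.individual_ids[i] for i in rows],
            list(self.snp_ids),
            labels,
        )


#: Fixed column order of the panel TSV, before the per-population frequency
#: block (``freq_<pop>`` columns) and the trailing bookkeeping columns.
PANEL_FIXED_COLS = ("rank", "snp_id", "chrom", "bp", "allele1", "allele2")
PANEL_TRAIL_COLS = ("selected_for", "in_value")


@dataclass
class PanelTable:
    """Ordered table of selected AIMs (selection rank 1..M)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for c in PANEL_FIXED_COLS + PANEL_TRAIL_COLS:
            if c not in t.columns:
                raise DataError(f"PanelTable missing column {c!r}")
        ranks = t["rank"].to_numpy()
        if len(t) and not np.array_equal(ranks, np.arange(1, len(t) + 1)):
            raise DataError("panel ranks must be contiguous 1..M in order")
        if t["snp_id"].duplicated().any():
            raise DataError("panel snp_ids must be unique")
        if len(t) and (t["in_value"].to_numpy(dtype=float) < 0).any():
            raise DataError("in_value must be non-negative")

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    def __len__(self) -> int:
        return len(self.table)

    def head(self, m: int) -> "PanelTable":
        return PanelTable(self.table.iloc[:m].reset_index(drop=True))

    @property
    def freq_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith("freq_")]


@dataclass
class AncestryMatrix:
    """Individuals x K ancestry proportions (rows on the simplex).

    Rows of all-NaN are permitted and mark individuals whose proportions
    could not be estimated (no observed genotypes).
    """

    q: pd.DataFrame  # index individual_id, columns ancestry labels

    SIMPLEX_TOL = 1e-9

    def __post_init__(self) -> None:
        vals = self.q.to_numpy(dtype=float)
        nan_rows = np.isnan(vals).all(axis=1)
        ok = vals[~nan_rows]
        if ok.size:
            if (ok < -self.SIMPLEX_TOL).any():
                raise DataError("ancestry proportions must be non-negative")
            sums = ok.sum(axis=1)
            if np.abs(sums - 1.0).max() > self.SIMPLEX_TOL:
                raise DataError("ancestry rows must sum to 1")

    @property
    def populations(self) -> list[str]:
        return list(self.q.columns)

    @property
    def individual_ids(self) -> list[str]:
        return list(self.q.index)

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class SourceFreqs:
    """Reference allele-1 frequencies per source population, clamped away
    from 0/1 so the admixture likelihood never evaluates log(0) at fixed
    reference alleles."""

    freq: pd.DataFrame  # SNPs x K, values in (0, 1) after clamping
    EPS = 1e-6

    def __post_init__(self) -> None:
        vals = self.freq.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise DataError("SourceFreqs cannot contain missing frequencies")
        if ((vals < 0) | (vals > 1)).any():
            raise DataError("frequencies must lie in [0, 1]")
        self.freq = self.freq.clip(self.EPS, 1.0 - self.EPS)

    @classmethod
    def from_freq_table(cls, freqs: FreqTable, populations: Sequence[str] | None = None) -> "SourceFreqs":
        cols = list(populations) if populations is not None else freqs.populations
        f = freqs.freq[cols].dropna()
        return cls(f.copy())

    @property
    def populations(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.freq.index)

    @property
    def k(self) -> int:
        return self.freq.shape[1]

    def restrict(self, snp_ids: Iterable[str]) -> "SourceFreqs":
        ids = [s for s in snp_ids if s in self.freq.index]
        return SourceFreqs(self.freq.loc[ids].copy())
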
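"""Greedy AIM selection by balancing pairwise informativeness.

The selector works in two stages.  Stage 1 (optional) takes a configurable
proportion of the panel in decreasing order of the multi-population In
statistic.  Stage 2 repeatedly identifies the population pair whose running
In total is smallest — every pair starts at zero — and adds the best
remaining marker for that pair, crediting the marker's pairwise In to the
pair's total.  Because the least-served pair is always fed next, the panel
ends up roughly equally informative for every pair of source populations,
which would not happen if markers were ranked by the multi-population
statistic alone (that statistic is dominated by the most diverged
populations).

Before any marker is accepted it must pass three checks against the panel so
far: it is not already selected, it is not in linkage disequilibrium with any
selected marker (genotypic r-squared), and it is not within a minimum
base-pair distance of any selected marker on the same chromosome.  Since the
panel only ever grows, a marker that fails a check can never become
acceptable later, so rejections are permanent.

Ties are resolved deterministically: among tied least-total pairs, the
(pair, SNP) combination with the highest pairwise In wins; remaining SNP
ties break by (chromosome, position, snp_id) ascending and remaining pair
ties by canonical pair order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    DataError,
    FreqTable,
    GenotypeMatrix,
    PanelTable,
    SnpMap,
    canonical_pairs,
    pair_label,
)
from .informativeness import heterogeneity_filter, informativeness, pairwise_informativeness

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionConfig",
    "PairLedger",
    "SelectionResult",
    "genotype_r2",
    "dosage_r2",
    "candidate_acceptable",
    "select_aims",
    "ld_prune",
]


@dataclass
class SelectionConfig:
    """Knobs of the greedy selector.

    min_distance_bp and ld_r2_max default to 100 000 bp and 0.2; either check
    is disabled by setting it to None.  proportion_multi is the fraction of
    the panel taken by multi-population In rank before pairwise balancing
    starts (rounded half away from zero to a marker count).
    """

    n_aims: int
    proportion_multi: float = 0.0
    min_distance_bp: int | None = 100_000
    ld_r2_max: float | None = 0.2
    het_filter: bool = False
    het_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_aims < 0:
            raise DataError("n_aims must be >= 0")
        if not 0.0 <= self.proportion_multi <= 1.0:
            raise DataError("proportion_multi must lie in [0, 1]")
        if self.min_distance_bp is not None and self.min_distance_bp < 0:
            raise DataError("min_distance_bp must be >= 0")
        if self.ld_r2_max is not None and not 0.0 <= self.ld_r2_max <= 1.0:
            raise DataError("ld_r2_max must lie in [0, 1]")
        if not 0.0 < self.het_alpha < 1.0:
            raise DataError("het_alpha must lie in (0, 1)")

    @property
    def n_multi(self) -> int:
        # round half away from zero, e.g. 0.1 * 25 = 2.5 -> 3
        return int(math.floor(self.proportion_multi * self.n_aims + 0.5))


@dataclass
class PairLedger:
    """Running In totals per population pair plus the append-only pick log."""

    totals: dict[str, float]
    log: pd.DataFrame  # rank, snp_id, selected_for, in_value

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pair": list(self.totals), "total_in": [self.totals[p] for p in self.totals]}
        )

    def pair_counts(self) -> pd.Series:
        """Number of Stage-2 markers credited to each pair."""
        stage2 = self.log[self.log["selected_for"] != "multi"]
        counts = stage2["selected_for"].value_counts()
        return counts.reindex(list(self.totals), fill_value=0)


@dataclass
class SelectionResult:
    panel: PanelTable
    ledger: PairLedger
    warnings: list[str] = field(default_factory=list)
    starved_pairs: list[str] = field(default_factory=list)


def dosage_r2(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation of two dosage vectors (composite LD, the
    PLINK ``--r2`` convention), over individuals with both observed.

    Returns None (undefined) with fewer than two complete pairs or zero
    variance in either vector; downstream an undefined r2 counts as "not in
    LD".
    """
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return None
    xs, ys = x[ok], y[ok]
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    ssx = float(xc @ xc)
    ssy = float(yc @ yc)
    if ssx == 0.0 or ssy == 0.0:
        return None
    cov = float(xc @ yc)
    return cov * cov / (ssx * ssy)


def genotype_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float | None:
    """r-squared between two SNPs of a genotype matrix (see :func:`dosage_r2`)."""
    return dosage_r2(genotypes.column(snp_a), genotypes.column(snp_b))


def candidate_acceptable(
    candidate: str,
    selected: Sequence[str],
    snp_map: SnpMap,
    genotypes: GenotypeMatrix | None,
    cfg: SelectionConfig,
) -> tuple[bool, str | None]:
    """Check a candidate against the panel so far.

    Accept iff the candidate (i) is not already selected, (ii) has
    r2 <= ld_r2_max against every selected SNP (undefined r2 passes), and
    (iii) lies more than min_distance_bp from every selected SNP on the same
    chromosome.  Returns (accepted, rejection_reason).
    """
    if candidate in set(selected):
        return False, "duplicate"
    row = snp_map.table.loc[candidate]
    chrom, bp = row["chrom"], int(row["bp"])
    if cfg.min_distance_bp is not None:
        for s in selected:
            srow = snp_map.table.loc[s]
            if srow["chrom"] == chrom and abs(int(srow["bp"]) - bp) <= cfg.min_distance_bp:
                return False, "distance"
    if cfg.ld_r2_max is not None and genotypes is not None:
        x = genotypes.column(candidate)
        for s in selected:
            r2 = dosage_r2(x, genotypes.column(s))
            if r2 is not None and r2 > cfg.ld_r2_max:
                return False, "ld"
    return True, None


def _sort_key_frame(snp_map: SnpMap, snp_ids: Sequence[str]) -> pd.DataFrame:
    t = snp_map.table.loc[list(snp_ids)]
    return pd.DataFrame(
        {"chrom": t["chrom"].astype(str), "bp": t["bp"].astype(int)},
        index=t.index,
    )


def _ranked_candidates(values: pd.Series, keys: pd.DataFrame) -> list[str]:
    """SNP ids ordered by value descending, ties by (chrom, bp, snp_id)."""
    df = keys.copy()
    df["val"] = values
    df = df[df["val"].notna()]
    df["sid"] = df.index.astype(str)
    df = df.reset_index(drop=True).sort_values(
        ["val", "chrom", "bp", "sid"], ascending=[False, True, True, True], kind="mergesort"
    )
    return list(df["sid"])


def select_aims(
    freqs: FreqTable,
    snp_map: SnpMap,
    genotypes: GenotypeMatrix | None,
    cfg: SelectionConfig,
    subgroup_freqs: FreqTable | None = None,
    grouping: Mapping[str, str] | None = None,
) -> SelectionResult:
    """Run the two-stage greedy selection; deterministic given its inputs.

    ``genotypes`` (typically the admixed study cohort) supplies dosages for
    the LD check; pass None to disable it.  With ``cfg.het_filter`` on,
    ``subgroup_freqs``/``grouping`` drive the subgroup-heterogeneity screen
    before selection starts.
    """
    warnings_list: list[str] = []
    candidates = [s for s in freqs.snp_ids if s in snp_map]
    if genotypes is not None:
        present = set(genotypes.snp_ids)
        candidates = [s for s in candidates if s in present]
    unusable = set(freqs.unusable_snps())
    candidates = [s for s in candidates if s not in unusable]

    if cfg.het_filter:
        if subgroup_freqs is None or grouping is None:
            raise DataError("het_filter requires subgroup_freqs and grouping")
        kept, _report = heterogeneity_filter(subgroup_freqs, grouping, cfg.het_alpha)
        before = len(candidates)
        candidates = [s for s in candidates if s in kept]
        logger.info("heterogeneity filter: %d -> %d candidates", before, len(candidates))

    sub = freqs.restrict(candidates)
    pairs = [pair_label(a, b) for a, b in canonical_pairs(freqs.populations)]
    keys = _sort_key_frame(snp_map, candidates)

    selected: list[str] = []
    log_rows: list[tuple[int, str, str, float]] = []
    totals: dict[str, float] = {p: 0.0 for p in pairs}
    excluded: set = set()  # permanently rejected or already selected

    # cached per-selected-SNP state for the fast acceptance check
    chrom_arr = keys["chrom"].to_dict()
    bp_arr = keys["bp"].to_dict()
    sel_chrom: list[str] = []
    sel_bp: list[int] = []
    sel_dosage: list[np.ndarray] = []

    def try_accept(snp_id: str) -> bool:
        # same rule as candidate_acceptable, with cached panel state
        if cfg.min_distance_bp is not None:
            c, bp = chrom_arr[snp_id], bp_arr[snp_id]
            for sc, sb in zip(sel_chrom, sel_bp):
                if sc == c and abs(sb - bp) <= cfg.min_distance_bp:
                    excluded.add(snp_id)
                    return False
        if cfg.ld_r2_max is not None and genotypes is not None:
            x = genotypes.column(snp_id)
            for y in sel_dosage:
                r2 = dosage_r2(x, y)
                if r2 is not None and r2 > cfg.ld_r2_max:
                    excluded.add(snp_id)
                    return False
        return True

    def commit(snp_id: str) -> None:
        selected.append(snp_id)
        excluded.add(snp_id)
        sel_chrom.append(chrom_arr[snp_id])
        sel_bp.append(bp_arr[snp_id])
        if cfg.ld_r2_max is not None and genotypes is not None:
            sel_dosage.append(genotypes.column(snp_id))

    # ---- Stage 1: multi-population In ----
    n_multi = min(cfg.n_multi, cfg.n_aims)
    if n_multi > 0:
        multi_in = informativeness(sub)
        order = _ranked_candidates(multi_in, keys)
        taken = 0
        for snp_id in order:
            if taken >= n_multi:
                break
            if snp_id in excluded:
                continue
            if try_accept(snp_id):
                commit(snp_id)
                log_rows.append((len(selected), snp_id, "multi", float(multi_in[snp_id])))
                taken += 1
        if taken < n_multi:
            warnings_list.append(
                f"multi-In stage exhausted after {taken}/{n_multi} markers"
            )

    # ---- Stage 2: pairwise balancing ----
    if len(selected) < cfg.n_aims:
        pw = pairwise_informativeness(sub)
        ranked: dict[str, list[str]] = {
            p: _ranked_candidates(pw[p], keys) for p in pairs
        }
        pw_lookup = {p: pw[p] for p in pairs}
        pointer: dict[str, int] = {p: 0 for p in pairs}
        starved: set = set()

        while len(selected) < cfg.n_aims:
            active = [p for p in pairs if p not in starved]
            if not active:
                warnings_list.append(
                    "candidate pool exhausted: all pairs starved at "
                    f"{len(selected)}/{cfg.n_aims} markers"
                )
                break
            min_total = min(totals[p] for p in active)
            tied = [p for p in active if totals[p] == min_total]

            # best acceptable candidate per tied pair
            best: tuple[float, str, int, str, str] | None = None
            # tuple: (-in, chrom, bp, snp_id, pair) for lexicographic best
            for p in tied:
                lst = ranked[p]
                i = pointer[p]
                found = None
                while i < len(lst):
                    snp_id = lst[i]
                    if snp_id in excluded:
                        i += 1
                        continue
                    if try_accept(snp_id):
                        found = snp_id
                        break
                    i += 1
                pointer[p] = i
                if found is None:
                    starved.add(p)
                    continue
                row = keys.loc[found]
                cand = (
                    -float(pw_lookup[p][found]),
                    str(row["chrom"]),
                    int(row["bp"]),
                    found,
                    p,
                )
                if best is None or cand < best:
                    best = cand
            if best is None:
                continue  # tied pairs all starved; re-evaluate remaining pairs
            neg_in, _, _, snp_id, p = best
            in_value = -neg_in
            commit(snp_id)
            totals[p] += in_value
            log_rows.append((len(selected), snp_id, p, in_value))

        if starved:
            warnings_list.append("starved pairs: " + ", ".join(sorted(starved)))
    else:
        starved = set()

    for w in warnings_list:
        logger.warning(w)

    panel = _build_panel(selected, log_rows, freqs, snp_map)
    ledger = PairLedger(
        totals,
        pd.DataFrame(log_rows, columns=["rank", "snp_id", "selected_for", "in_value"]),
    )
    return SelectionResult(panel, ledger, warnings_list, sorted(starved))


def _build_panel(
    selected: Sequence[str],
    log_rows: Sequence[tuple[int, str, str, float]],
    freqs: FreqTable,
    snp_map: SnpMap,
) -> PanelTable:
    rows = []
    for rank, snp_id, sel_for, in_value in log_rows:
        m = snp_map.table.loc[snp_id]
        row = {
            "rank": rank,
            "snp_id": snp_id,
            "chrom": str(m["chrom"]),
            "bp": int(m["bp"]),
            "allele1": str(m["allele1"]),
            "allele2": str(m["allele2"]),
        }
        for pop in freqs.populations:
            row[f"freq_{pop}"] = float(freqs.freq.loc[snp_id, pop])
        row["selected_for"] = sel_for
        row["in_value"] = float(in_value)
        rows.append(row)
    cols = (
        ["rank", "snp_id", "chrom", "bp", "allele1", "allele2"]
        + [f"freq_{p}" for p in freqs.populations]
        + ["selected_for", "in_value"]
    )
    table = pd.DataFrame(rows, columns=cols)
    return PanelTable(table)


def ld_prune(
    genotypes: GenotypeMatrix,
    snp_map: SnpMap,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.2,
) -> list[str]:
    """Sliding-window LD pruning (window 50 SNPs, shift 10 by default).

    Within each window, whenever a kept pair has r2 > ``r2_max`` the
    later-positioned SNP of the pair is removed; the window then slides by
    ``step_snps``.  Windows run within chromosomes over SNPs sorted by
    (chromosome, bp).  Returns the kept snp_ids in map order.
    """
    present = [s for s in genotypes.snp_ids if s in snp_map]
    t = snp_map.table.loc[present]
    order = t.sort_values(["chrom", "bp"], kind="mergesort")
    removed: set = set()
    for chrom in order["chrom"].unique():
        ids = list(order.index[order["chrom"] == chrom])
        n = len(ids)
        start = 0
        while start < n:
            window = ids[start : start + window_snps]
            alive = [s for s in window if s not in removed]
            for i in range(len(alive)):
                a = alive[i]
                if a in removed:
                    continue
                for b in alive[i + 1 :]:
                    if b in removed:
                        continue
                    r2 = genotype_r2(genotypes, a, b)
                    if r2 is not None and r2 > r2_max:
                        removed.add(b)  # later-positioned SNP goes
            if start + window_snps >= n:
                break
            start += step_snps
    return [s for s in order.index if s not in removed]
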
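"""Readers/writers for the PLINK text dialects and the panel table.

Formats handled (all plain text, UTF-8, whitespace/tab delimited):

* ``.bim``       — six columns: chrom, snp_id, cM, bp, allele1, allele2;
* ``.frq.strat`` — stratified frequencies: CHR SNP CLST A1 A2 MAF MAC NCHROBS,
  where MAF is read as the A1 (allele-1) frequency;
* ``.traw``      — transposed dosages: CHR SNP (C)M POS COUNTED ALT followed by
  one column per individual, values 0/1/2/NA counting COUNTED-allele copies;
* panel TSV      — the ordered AIM panel with one row per selected marker.

Also provides :func:`intersect_snps`, which harmonizes SNP sets across
datasets genotyped against possibly swapped allele orderings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    PANEL_FIXED_COLS,
    PANEL_TRAIL_COLS,
    DataError,
    FreqTable,
    GenotypeMatrix,
    PanelTable,
    SnpMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_snp_map",
    "write_snp_map",
    "read_freq_strat",
    "write_freq_strat",
    "read_genotypes",
    "write_genotypes",
    "read_panel",
    "write_panel",
    "intersect_snps",
    "IntersectResult",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = (frozenset("AT"), frozenset("CG"))


def read_snp_map(path: Union[str, Path]) -> SnpMap:
    """Parse a ``.bim``-dialect map file (no header)."""
    rows = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise DataError(f"{path}: line {lineno}: expected 6 columns, got {len(parts)}")
            chrom, snp_id, cm, bp, a1, a2 = parts
            try:
                bp_val = int(bp)
                cm_val = float(cm)
            except ValueError as exc:
                raise DataError(f"{path}: line {lineno}: bad numeric field ({exc})") from None
            rows.append((snp_id, chrom, cm_val, bp_val, a1, a2))
    if not rows:
        table = pd.DataFrame(columns=["chrom", "cm", "bp", "allele1", "allele2"])
        table.index.name = "snp_id"
        return SnpMap(table)
    table = pd.DataFrame(rows, columns=["snp_id", "chrom", "cm", "bp", "allele1", "allele2"])
    if table["snp_id"].duplicated().any():
        dups = table.loc[table["snp_id"].duplicated(), "snp_id"].unique().tolist()
        raise DataError(f"{path}: duplicate snp_id(s): {dups[:5]}")
    return SnpMap(table.set_index("snp_id"))


def write_snp_map(snp_map: SnpMap, path: Union[str, Path]) -> None:
    t = snp_map.table
    with open(path, "wt", encoding="utf-8") as fh:
        for snp_id, row in t.iterrows():
            cm = row["cm"]
            cm_str = str(int(cm)) if float(cm) == int(cm) else repr(float(cm))
            fh.write(
                f"{row['chrom']}\t{snp_id}\t{cm_str}\t{int(row['bp'])}\t"
                f"{row['allele1']}\t{row['allele2']}\n"
            )


def read_freq_strat(path: Union[str, Path]) -> FreqTable:
    """Parse a ``.frq.strat``-dialect stratified frequency file.

    Populations are ordered by first appearance of their CLST label; the MAF
    column is interpreted as the frequency of the A1 allele.  Every SNP must
    appear for every cluster.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str, "SNP": str, "CLST": str})
    required = {"CHR", "SNP", "CLST", "A1", "A2", "MAF", "NCHROBS"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    pops = list(dict.fromkeys(df["CLST"]))
    bad = df[(df["MAF"].notna()) & ((df["MAF"] < 0) | (df["MAF"] > 1))]
    if len(bad):
        snp = bad.iloc[0]
        raise DataError(f"{path}: frequency {snp['MAF']} outside [0,1] for SNP {snp['SNP']}")
    freq = df.pivot(index="SNP", columns="CLST", values="MAF")
    n_obs = df.pivot(index="SNP", columns="CLST", values="NCHROBS")
    # pivot introduces NaN where a SNP x cluster combination is absent; a NaN
    # in n_obs therefore flags a structurally missing record (a NaN freq with
    # a present n_obs is a legitimate zero-observation record).
    if n_obs.isna().any().any():
        missing_snps = n_obs.index[n_obs.isna().any(axis=1)].tolist()
        raise DataError(f"{path}: SNP(s) missing in some cluster: {missing_snps[:5]}")
    snp_order = list(dict.fromkeys(df["SNP"]))
    freq = freq.loc[snp_order, pops]
    n_obs = n_obs.loc[snp_order, pops].astype(float)
    freq.index.name = n_obs.index.name = "snp_id"
    alleles = (
        df.drop_duplicates("SNP").set_index("SNP")[["A1", "A2"]].rename(
            columns={"A1": "allele1", "A2": "allele2"}
        )
    ).loc[snp_order]
    alleles.index.name = "snp_id"
    return FreqTable(freq, n_obs, alleles)


def write_freq_strat(freqs: FreqTable, path: Union[str, Path], snp_map: SnpMap | None = None) -> None:
    """Write a FreqTable in ``.frq.strat`` layout (MAC = MAF * NCHROBS, rounded)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("CHR\tSNP\tCLST\tA1\tA2\tMAF\tMAC\tNCHROBS\n")
        for snp_id in freqs.snp_ids:
            if snp_map is not None and snp_id in snp_map:
                chrom = snp_map.table.loc[snp_id, "chrom"]
                a1, a2 = snp_map.alleles(snp_id)
            elif freqs.alleles is not None:
                chrom = "0"
                a1, a2 = freqs.alleles.loc[snp_id, ["allele1", "allele2"]]
            else:
                chrom, a1, a2 = "0", "A", "B"
            for pop in freqs.populations:
                maf = freqs.freq.loc[snp_id, pop]
                n = freqs.n_obs.loc[snp_id, pop]
                mac = "" if pd.isna(maf) else str(int(round(maf * n)))
                maf_str = "NA" if pd.isna(maf) else f"{maf:.6g}"
                fh.write(f"{chrom}\t{snp_id}\t{pop}\t{a1}\t{a2}\t{maf_str}\t{mac}\t{int(n)}\n")


def read_genotypes(path: Union[str, Path]) -> GenotypeMatrix:
    """Parse a ``.traw``-dialect transposed dosage file.

    Returns dosages transposed to individuals x SNPs; the COUNTED allele is
    the allele whose copies the dosage counts (allele 1 downstream).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) < 6:
            raise DataError(f"{path}: truncated header")
        fixed = header[:6]
        indiv_ids = header[6:]
        if not indiv_ids:
            raise DataError(f"{path}: no individual columns in header")
        snp_ids: list[str] = []
        cols: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + len(indiv_ids):
                raise DataError(
                    f"{path}: line {lineno}: expected {6 + len(indiv_ids)} fields, got {len(parts)}"
                )
            snp_ids.append(parts[1])
            row = np.empty(len(indiv_ids), dtype=float)
            for i, tok in enumerate(parts[6:]):
                if tok == "NA":
                    row[i] = np.nan
                elif tok in ("0", "1", "2", "0.0", "1.0", "2.0"):
                    row[i] = float(tok)
                else:
                    raise DataError(f"{path}: line {lineno}: bad dosage token {tok!r}")
            cols.append(row)
    dosage = np.vstack(cols).T if cols else np.empty((len(indiv_ids), 0))
    return GenotypeMatrix(dosage, indiv_ids, snp_ids)


def write_genotypes(
    genotypes: GenotypeMatrix, path: Union[str, Path], snp_map: SnpMap | None = None
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("CHR\tSNP\t(C)M\tPOS\tCOUNTED\tALT\t" + "\t".join(genotypes.individual_ids) + "\n")
        for j, snp_id in enumerate(genotypes.snp_ids):
            if snp_map is not None and snp_id in snp_map:
                row = snp_map.table.loc[snp_id]
                chrom, cm, pos = row["chrom"], row["cm"], int(row["bp"])
                a1, a2 = row["allele1"], row["allele2"]
            else:
                chrom, cm, pos, a1, a2 = "0", 0, j + 1, "A", "B"
            toks = [
                "NA" if np.isnan(v) else str(int(v)) for v in genotypes.dosage[:, j]
            ]
            fh.write(f"{chrom}\t{snp_id}\t{cm}\t{pos}\t{a1}\t{a2}\t" + "\t".join(toks) + "\n")


def write_panel(panel: PanelTable, path: Union[str, Path]) -> None:
    """Write the panel as a TSV with a fixed, diffable column order."""
    cols = list(PANEL_FIXED_COLS) + panel.freq_columns + list(PANEL_TRAIL_COLS)
    out = panel.table[cols].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel(path: Union[str, Path]) -> PanelTable:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "selected_for": str})
    if df.empty and "rank" not in df.columns:
        raise DataError(f"{path}: not a panel file (missing header)")
    return PanelTable(df)


# ---------------------------------------------------------------------------
# SNP-set intersection / allele harmonization


@dataclass
class IntersectResult:
    """Outcome of harmonizing SNP sets across datasets.

    ``snp_ids`` is the surviving intersection; ``maps``/``tables`` are
    harmonized copies of the inputs restricted to those SNPs (dosages and
    frequencies complemented where an input's alleles were recorded in
    swapped order relative to the reference map); ``dropped`` logs every
    excluded SNP with its reason.
    """

    snp_ids: set
    maps: list = field(default_factory=list)
    tables: list = field(default_factory=list)
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "dataset", "reason"])
    )


def _classify_alleles(ref: tuple[str, str], other: tuple[str, str]) -> str:
    """Classify an allele pair against the reference: 'match', 'swap',
    'ambiguous', 'flip', or 'incompatible'."""
    ra1, ra2 = (x.upper() for x in ref)
    oa1, oa2 = (x.upper() for x in other)
    ambiguous = frozenset((ra1, ra2)) in _AMBIGUOUS
    if (oa1, oa2) == (ra1, ra2):
        return "match"
    if (oa1, oa2) == (ra2, ra1):
        # For A/T and C/G SNPs a swap is indistinguishable from a strand
        # flip, so the conservative call is to drop the marker.
        return "ambiguous" if ambiguous else "swap"
    f1, f2 = _COMPLEMENT.get(ra1), _COMPLEMENT.get(ra2)
    if f1 and f2 and (oa1, oa2) in ((f1, f2), (f2, f1)):
        return "flip"
    return "incompatible"


def _dataset_alleles(ds) -> pd.DataFrame | None:
    if isinstance(ds, SnpMap):
        return ds.table[["allele1", "allele2"]]
    if isinstance(ds, FreqTable):
        return ds.alleles
    return None  # GenotypeMatrix carries no redundant allele record


def _dataset_ids(ds) -> set:
    return set(ds.snp_ids)


def intersect_snps(maps: Sequence[SnpMap], tables: Sequence = ()) -> IntersectResult:
    """Intersect SNP sets across maps and frequency/genotype tables.

    The first map is the allele reference.  An input whose (allele1, allele2)
    pair is the swap of the reference is kept with its frequencies (1 - p) /
    dosages (2 - d) complemented; strand flips are never attempted, and
    strand-ambiguous A/T and C/G markers whose alleles do not match the
    reference exactly are dropped and logged.
    """
    if not maps and not tables:
        raise DataError("intersect_snps needs at least one input")
    datasets = list(maps) + list(tables)
    common = set.intersection(*(_dataset_ids(d) for d in datasets))

    ref = maps[0] if maps else None
    drops: list[tuple[str, int, str]] = []
    actions: list[dict[str, str]] = []  # per dataset: snp_id -> 'swap'
    for di, ds in enumerate(datasets):
        acts: dict[str, str] = {}
        alleles = _dataset_alleles(ds)
        if ref is not None and alleles is not None and ds is not ref:
            for snp_id in sorted(common & set(alleles.index) & set(ref.table.index)):
                verdict = _classify_alleles(
                    ref.alleles(snp_id),
                    (str(alleles.loc[snp_id, "allele1"]), str(alleles.loc[snp_id, "allele2"])),
                )
                if verdict == "swap":
                    acts[snp_id] = "swap"
                elif verdict != "match":
                    drops.append((snp_id, di, verdict))
        actions.append(acts)

    dropped_ids = {d[0] for d in drops}
    kept = common - dropped_ids
    for snp_id, di, reason in drops:
        logger.info("intersect_snps: dropping %s from dataset %d (%s)", snp_id, di, reason)

    out_maps: list[SnpMap] = []
    out_tables: list = []
    kept_sorted = sorted(kept)
    for ds, acts in zip(datasets, actions):
        swapped = [s for s in kept_sorted if acts.get(s) == "swap"]
        if isinstance(ds, SnpMap):
            ids = [s for s in ds.snp_ids if s in kept]
            t = ds.table.loc[ids].copy()
            if swapped:
                sw = [s for s in swapped if s in t.index]
                t.loc[sw, ["allele1", "allele2"]] = t.loc[sw, ["allele2", "allele1"]].to_numpy()
            out_maps.append(SnpMap(t))
        elif isinstance(ds, FreqTable):
            ids = [s for s in ds.snp_ids if s in kept]
            sub = ds.restrict(ids)
            freq = sub.freq.copy()
            al = sub.alleles.copy() if sub.alleles is not None else None
            sw = [s for s in swapped if s in freq.index]
            if sw:
                freq.loc[sw] = 1.0 - freq.loc[sw]
                if al is not None:
                    al.loc[sw, ["allele1", "allele2"]] = al.loc[sw, ["allele2", "allele1"]].to_numpy()
            out_tables.append(FreqTable(freq, sub.n_obs.copy(), al))
        else:  # GenotypeMatrix
            ids = [s for s in ds.snp_ids if s in kept]
            sub = ds.restrict(ids)
            out_tables.append(sub)

    dropped_df = pd.DataFrame(drops, columns=["snp_id", "dataset", "reason"])
    return IntersectResult(kept, out_maps, out_tables, dropped_df)
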
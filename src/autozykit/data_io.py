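"""Genotype, pedigree, map and annotation I/O.

The central container is :class:`GenotypeMatrix`: individuals x biallelic
SNPs, stored as alternate-allele dosages (0/1/2) with ``-1`` marking missing
genotypes.  Genotypes can be read from VCF (``GT`` field, via cyvcf2) or from
a plain TSV dosage table; both produce identical matrices.  Coordinates are
1-based bp as in VCF; all windowed operations elsewhere in the package use
half-open ``[start, end)`` intervals in bp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_META_COLUMNS = ["chrom", "bp", "cm", "ref", "alt", "af"]

FUNCTIONAL_CLASSES = (
    "synonymous",
    "tolerated_missense",
    "deleterious_missense",
    "other",
)


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alternate-allele dosage matrix.

    Parameters
    ----------
    dosages
        ``(n_individuals, n_snps)`` integer matrix with values in
        ``{0, 1, 2, MISSING}``.
    snp_meta
        Per-SNP metadata with columns ``chrom, bp, cm, ref, alt, af`` where
        ``af`` is the alternate-allele frequency among non-missing genotypes.
    sample_ids
        Ordered individual identifiers (rows of ``dosages``).
    """

    dosages: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D matrix")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise DataError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.snp_meta):
            raise DataError("snp_meta length does not match dosage columns")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def af(self) -> np.ndarray:
        """Alternate-allele frequencies (one per SNP)."""
        return self.snp_meta["af"].to_numpy(dtype=float)

    @property
    def maf(self) -> np.ndarray:
        a = self.af
        return np.minimum(a, 1.0 - a)

    def validate(self) -> None:
        """Check container invariants; raise :class:`DataError` on violation."""
        d = self.dosages
        if not np.isin(d, (0, 1, 2, MISSING)).all():
            raise DataError("dosages outside {0,1,2,missing}")
        af = self.af
        if ((af < 0) | (af > 1)).any():
            raise DataError("allele frequency outside [0,1]")
        for _, grp in self.snp_meta.groupby("chrom", sort=False):
            bp = grp["bp"].to_numpy()
            if (np.diff(bp) <= 0).any():
                raise DataError("bp not strictly increasing within chromosome")
            cm = grp["cm"].to_numpy(dtype=float)
            finite = np.isfinite(cm)
            if finite.all() and (np.diff(cm) < 0).any():
                raise DataError("cM not non-decreasing within chromosome")

    def compute_af(self, freq_samples: list[str] | None = None) -> np.ndarray:
        """Alternate-allele frequency from non-missing genotypes.

        ``freq_samples`` restricts the frequency-reference sample set;
        the default uses every individual in the matrix.
        """
        d = self.dosages
        if freq_samples is not None:
            idx = [self.sample_ids.index(s) for s in freq_samples]
            d = d[idx]
        ok = d != MISSING
        n = ok.sum(axis=0)
        alt = np.where(ok, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / (2.0 * np.maximum(n, 1)), np.nan)

    def refresh_af(self, freq_samples: list[str] | None = None) -> "GenotypeMatrix":
        meta = self.snp_meta.copy()
        meta["af"] = self.compute_af(freq_samples)
        return GenotypeMatrix(self.dosages, meta, list(self.sample_ids))

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.dosages[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            list(self.sample_ids),
        )

    def subset_samples(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in ids]
        return GenotypeMatrix(self.dosages[idx], self.snp_meta.copy(), list(ids))

    def snp_ids(self) -> pd.Series:
        return self.snp_meta["chrom"].astype(str) + ":" + self.snp_meta["bp"].astype(str)


@dataclass
class AnnotationTable:
    """Per-SNP functional class, private flag and (optional) allele age.

    ``table`` columns: ``chrom, bp, func_class, private, age`` with
    ``func_class`` one of :data:`FUNCTIONAL_CLASSES` (mutually exclusive) and
    ``age`` in generations (NaN when unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        bad = ~t["func_class"].isin(FUNCTIONAL_CLASSES)
        if bad.any():
            raise DataError(f"unknown functional class: {t.loc[bad, 'func_class'].iloc[0]}")
        if t.duplicated(["chrom", "bp"]).any():
            raise DataError("duplicate annotation records for one SNP")
        self.table = t.reset_index(drop=True)

    def aligned_to(self, g: GenotypeMatrix) -> pd.DataFrame:
        """Annotation rows aligned to the SNPs of ``g`` (NaN where absent)."""
        key = g.snp_meta[["chrom", "bp"]]
        return key.merge(self.table, on=["chrom", "bp"], how="left")


UNKNOWN_PARENT = "0"


@dataclass
class Pedigree:
    """Topologically ordered pedigree records.

    ``ids`` lists individuals with parents preceding offspring; ``sire`` and
    ``dam`` map each id to a parent id or :data:`UNKNOWN_PARENT`.
    """

    ids: list[str]
    sire: dict[str, str]
    dam: dict[str, str]
    _order: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._order = {x: i for i, x in enumerate(self.ids)}

    def __contains__(self, x: str) -> bool:
        return x in self._order

    def __len__(self) -> int:
        return len(self.ids)

    def topo_index(self, x: str) -> int:
        return self._order[x]

    def parents(self, x: str) -> tuple[str, str]:
        return self.sire[x], self.dam[x]

    def is_founder(self, x: str) -> bool:
        return self.sire[x] == UNKNOWN_PARENT and self.dam[x] == UNKNOWN_PARENT

    def founders(self) -> list[str]:
        return [x for x in self.ids if self.is_founder(x)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.ids,
             "sire": [self.sire[x] for x in self.ids],
             "dam": [self.dam[x] for x in self.ids]}
        )


def build_pedigree(records: list[tuple[str, str, str]]) -> Pedigree:
    """Build a :class:`Pedigree` from (id, sire, dam) records.

    Unknown parents may be coded ``"0"``, ``""`` or ``None``.  Parents that
    never appear as individuals are added as founders.  Raises on duplicated
    ids and on cycles (one cycle is listed in the message).
    """
    norm = lambda p: UNKNOWN_PARENT if p in (None, "", "0", 0) else str(p)
    seen: set[str] = set()
    sire: dict[str, str] = {}
    dam: dict[str, str] = {}
    for iid, s, d in records:
        iid = str(iid)
        if iid in seen:
            raise DataError(f"duplicated individual id: {iid}")
        seen.add(iid)
        sire[iid] = norm(s)
        dam[iid] = norm(d)
    # implicit founders
    for p in list(sire.values()) + list(dam.values()):
        if p != UNKNOWN_PARENT and p not in seen:
            seen.add(p)
            sire[p] = UNKNOWN_PARENT
            dam[p] = UNKNOWN_PARENT

    # Kahn topological sort, deterministic order
    children: dict[str, list[str]] = {x: [] for x in seen}
    indeg = {x: 0 for x in seen}
    for x in seen:
        for p in (sire[x], dam[x]):
            if p != UNKNOWN_PARENT:
                children[p].append(x)
                indeg[x] += 1
    ready = sorted(x for x in seen if indeg[x] == 0)
    order: list[str] = []
    while ready:
        x = ready.pop(0)
        order.append(x)
        for c in sorted(children[x]):
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(seen):
        cyc = _find_cycle(sire, dam, seen - set(order))
        raise DataError(f"pedigree contains a cycle: {' -> '.join(cyc)}")
    return Pedigree(order, sire, dam)


def _find_cycle(sire: dict, dam: dict, candidates: set[str]) -> list[str]:
    start = sorted(candidates)[0]
    path, seen = [start], {start}
    x = start
    while True:
        nxt = sire[x] if sire[x] in candidates else dam[x]
        if nxt in seen:
            return path[path.index(nxt):] + [nxt]
        path.append(nxt)
        seen.add(nxt)
        x = nxt


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_genotypes(
    path: str,
    region: str | None = None,
    freq_samples: list[str] | None = None,
    skip_multiallelic: bool = True,
    sort: bool = False,
) -> GenotypeMatrix:
    """Read a VCF (``.vcf``/``.vcf.gz``) or a TSV dosage table.

    Alternate-allele frequencies are computed from the non-missing genotypes
    of all samples read (or of ``freq_samples``).  SNPs arrive sorted by
    (chrom, bp); unsorted input raises unless ``sort=True``.
    """
    if not os.path.exists(path):
        raise DataError(f"no such file: {path}")
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        g = _read_vcf(path, region, skip_multiallelic)
    else:
        g = _read_dosage_tsv(path, region)
    g = _ensure_sorted(g, sort)
    g = g.refresh_af(freq_samples)
    g.validate()
    return g


def _parse_region(region: str) -> tuple[str, int, int]:
    chrom, _, rng = region.partition(":")
    if rng:
        lo, _, hi = rng.partition("-")
        return chrom, int(lo), int(hi)
    return chrom, 0, np.iinfo(np.int64).max


def _read_vcf(path: str, region: str | None, skip_multiallelic: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, meta = [], []
    rc = _parse_region(region) if region else None
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if skip_multiallelic:
                continue
            raise DataError(f"non-biallelic-SNV record at line-record {i}: "
                            f"{var.CHROM}:{var.POS}")
        if rc and not (var.CHROM == rc[0] and rc[1] <= var.POS <= rc[2]):
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
        cm = var.INFO.get("CM")
        meta.append((var.CHROM, var.POS, np.nan if cm is None else float(cm),
                     var.REF, var.ALT[0]))
    if not rows:
        raise DataError(f"no biallelic SNP records read from {path}")
    dos = np.asarray(rows, dtype=np.int8).T
    sm = pd.DataFrame(meta, columns=["chrom", "bp", "cm", "ref", "alt"])
    sm["af"] = np.nan
    return GenotypeMatrix(dos, sm, samples)


def _read_dosage_tsv(path: str, region: str | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    fixed = ["chrom", "bp", "cm", "ref", "alt"]
    if list(df.columns[:5]) != fixed:
        raise DataError(f"dosage table must start with columns {fixed}")
    samples = list(df.columns[5:])
    if not samples:
        raise DataError("dosage table has no sample columns")
    dos = df[samples].to_numpy()
    try:
        dos = np.where(pd.isna(dos), MISSING, dos).astype(np.int8)
    except (TypeError, ValueError) as exc:
        raise DataError(f"malformed dosage value in {path}: {exc}") from exc
    bad = ~np.isin(dos, (0, 1, 2, MISSING))
    if bad.any():
        r = int(np.argwhere(bad)[0][0])
        raise DataError(f"invalid dosage at data line {r + 1} of {path}")
    sm = df[fixed].copy()
    sm["bp"] = sm["bp"].astype(np.int64)
    sm["af"] = np.nan
    g = GenotypeMatrix(dos.T, sm, samples)
    if region:
        chrom, lo, hi = _parse_region(region)
        keep = (sm["chrom"] == chrom) & (sm["bp"] >= lo) & (sm["bp"] <= hi)
        g = g.subset_snps(keep.to_numpy())
    return g


def _ensure_sorted(g: GenotypeMatrix, sort: bool) -> GenotypeMatrix:
    order = np.lexsort((g.snp_meta["bp"].to_numpy(),
                        g.snp_meta["chrom"].astype(str).to_numpy()))
    if (order == np.arange(g.n_snps)).all():
        return g
    if not sort:
        raise DataError("input SNPs are not sorted by (chrom, bp); pass sort=True")
    return g.subset_snps(order)


def filter_markers(
    g: GenotypeMatrix,
    drop_monomorphic: bool = False,
    keep_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Drop monomorphic SNPs and/or subset to ``keep_ids`` (chrom:bp ids)."""
    keep = np.ones(g.n_snps, dtype=bool)
    if drop_monomorphic:
        af = g.af
        keep &= (af > 0) & (af < 1)
    if keep_ids is not None:
        keep &= g.snp_ids().isin(set(keep_ids)).to_numpy()
    if not keep.any():
        raise DataError("no SNPs left after filtering")
    return g.subset_snps(keep)


def read_pedigree(path: str) -> Pedigree:
    """Read a 3-column TSV (id, sire, dam); unknown parents coded 0 or empty."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    need = ["id", "sire", "dam"]
    if list(df.columns[:3]) != need:
        raise DataError(f"pedigree file must have columns {need}")
    return build_pedigree(list(df[need].itertuples(index=False, name=None)))


def read_genetic_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if list(df.columns[:3]) != ["chrom", "bp", "cm"]:
        raise DataError("genetic map must have columns chrom, bp, cm")
    return df


def read_annotations(path: str) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = ["chrom", "bp", "func_class", "private"]
    if list(df.columns[: len(need)]) != need:
        raise DataError(f"annotation table must have columns {need} (+ optional age)")
    if "age" not in df.columns:
        df["age"] = np.nan
    df["private"] = df["private"].astype(bool)
    return AnnotationTable(df[need + ["age"]])


def attach_map(g: GenotypeMatrix, genetic_map: pd.DataFrame | None = None,
               cm_per_mb: float = 1.0) -> GenotypeMatrix:
    """Fill the ``cm`` column by piecewise-linear interpolation of a map.

    Without a map, a uniform ``cm_per_mb`` rate is applied (logged choice;
    1 cM/Mb is the usual mammalian fallback).
    """
    meta = g.snp_meta.copy()
    if genetic_map is None:
        meta["cm"] = meta["bp"] * (cm_per_mb / 1e6)
    else:
        cm = np.empty(len(meta))
        for chrom, grp in meta.groupby("chrom", sort=False):
            sub = genetic_map[genetic_map["chrom"] == chrom]
            if sub.empty:
                cm[grp.index] = grp["bp"] * (cm_per_mb / 1e6)
                continue
            cm[grp.index] = np.interp(grp["bp"], sub["bp"], sub["cm"])
        meta["cm"] = cm
    return GenotypeMatrix(g.dosages, meta, list(g.sample_ids))


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------


def write_dosage_tsv(g: GenotypeMatrix, path: str) -> None:
    sm = g.snp_meta[["chrom", "bp", "cm", "ref", "alt"]].copy()
    body = pd.DataFrame(g.dosages.T, columns=g.sample_ids)
    body = body.where(body != MISSING, other=pd.NA)
    pd.concat([sm.reset_index(drop=True), body], axis=1).to_csv(
        path, sep="\t", index=False
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF (GT only; cM carried in INFO/CM)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in g.snp_meta["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        meta = g.snp_meta
        for j in range(g.n_snps):
            cm = meta["cm"].iat[j]
            info = "." if pd.isna(cm) else f"CM={cm:.8g}"
            gts = "\t".join(_GT[int(x)] for x in g.dosages[:, j])
            fh.write(f"{meta['chrom'].iat[j]}\t{meta['bp'].iat[j]}\t.\t"
                     f"{meta['ref'].iat[j]}\t{meta['alt'].iat[j]}\t.\t.\t{info}\tGT\t{gts}\n")


def write_pedigree(ped: Pedigree, path: str) -> None:
    ped.to_frame().to_csv(path, sep="\t", index=False)


def write_genetic_map(g: GenotypeMatrix, path: str) -> None:
    g.snp_meta[["chrom", "bp", "cm"]].to_csv(path, sep="\t", index=False)


def write_annotations(ann: AnnotationTable, path: str) -> None:
    ann.table.to_csv(path, sep="\t", index=False)
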
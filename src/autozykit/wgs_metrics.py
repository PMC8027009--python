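"""Evaluation scores computed from dense (WGS-like) genotypes.

These scores are the yardsticks against which inbreeding estimators are
compared: homozygosity of alternate alleles per allele-frequency class,
marker homozygosity per MAF class, whole-genome homozygosity, homozygous
mutation load (HML, optionally 1/AF-weighted and stratified by functional
class or private flag) and regional per-window versions with exclusion
filters.

Conventions: AF classes are half-open (lo, hi], MAF classes partition
(0, 0.5]; HML counts homozygosity of the *alternate* (rare) allele only;
windows tile each chromosome from 0 as half-open [k Mb, (k+1) Mb) intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MISSING, AnnotationTable, GenotypeMatrix

MB = 1_000_000


@dataclass
class ScoreMatrix:
    """Individuals x score columns with per-column metadata.

    ``values`` rows are individuals; ``meta`` (indexed like the columns)
    records class bounds / thresholds / window coordinates, the number of
    SNPs used, and exclusion flags with the failing rule named.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def columns(self):
        return self.values.columns

    def retained(self) -> "ScoreMatrix":
        keep = ~self.meta["excluded"].fillna(False).astype(bool)
        return ScoreMatrix(self.values.loc[:, keep.to_numpy()],
                           self.meta.loc[keep.to_numpy()])


def _hom_alt_counts(g: GenotypeMatrix, snp_mask: np.ndarray):
    d = g.dosages[:, snp_mask]
    ok = d != MISSING
    return (d == 2).sum(axis=1), ok.sum(axis=1)


def _hom_any_counts(g: GenotypeMatrix, snp_mask: np.ndarray):
    d = g.dosages[:, snp_mask]
    ok = d != MISSING
    return ((d == 0) | (d == 2)).sum(axis=1), ok.sum(axis=1)


def _class_edges(n_classes: int, top: float) -> np.ndarray:
    return np.linspace(0.0, top, n_classes + 1)


def _ratio(num, den):
    return np.where(den > 0, num / np.maximum(den, 1), np.nan)


def af_class_homozygosity(g: GenotypeMatrix, n_classes: int = 20) -> ScoreMatrix:
    """Hom-alt proportion per allele-frequency class (classes partition (0,1])."""
    edges = _class_edges(n_classes, 1.0)
    af = g.af
    cols, meta = {}, []
    for i in range(n_classes):
        lo, hi = edges[i], edges[i + 1]
        mask = (af > lo) & (af <= hi)
        hom, n_ok = _hom_alt_counts(g, mask)
        name = f"af_({lo:.2f},{hi:.2f}]"
        cols[name] = _ratio(hom, n_ok)
        meta.append((name, "af_hom", lo, hi, int(mask.sum()),
                     mask.sum() == 0, "no SNPs in class" if mask.sum() == 0 else ""))
    return _pack(g, cols, meta)


def maf_class_marker_homozygosity(g: GenotypeMatrix, n_classes: int = 10) -> ScoreMatrix:
    """Homozygosity at either allele per minor-allele-frequency class (0, 0.5]."""
    edges = _class_edges(n_classes, 0.5)
    maf = g.maf
    cols, meta = {}, []
    for i in range(n_classes):
        lo, hi = edges[i], edges[i + 1]
        mask = (maf > lo) & (maf <= hi)
        hom, n_ok = _hom_any_counts(g, mask)
        name = f"maf_({lo:.2f},{hi:.2f}]"
        cols[name] = _ratio(hom, n_ok)
        meta.append((name, "maf_hom", lo, hi, int(mask.sum()),
                     mask.sum() == 0, "no SNPs in class" if mask.sum() == 0 else ""))
    return _pack(g, cols, meta)


def _pack(g, cols, meta):
    values = pd.DataFrame(cols, index=g.sample_ids)
    meta = pd.DataFrame(meta, columns=["name", "kind", "lo", "hi", "n_snps",
                                       "excluded", "exclude_reason"]).set_index("name")
    return ScoreMatrix(values, meta)


def wgs_homozygosity(g: GenotypeMatrix) -> pd.Series:
    """Proportion of all non-missing genotypes that are homozygous."""
    hom, n_ok = _hom_any_counts(g, np.ones(g.n_snps, dtype=bool))
    return pd.Series(_ratio(hom, n_ok), index=g.sample_ids, name="wgs_homozygosity")


def _stratum_mask(g: GenotypeMatrix, stratum, annotations: AnnotationTable | None):
    if stratum is None:
        return np.ones(g.n_snps, dtype=bool)
    if annotations is None:
        raise ValueError("stratified HML needs an annotation table")
    ann = annotations.aligned_to(g)
    kind, value = stratum
    if kind == "class":
        return (ann["func_class"] == value).to_numpy()
    if kind == "private":
        return (ann["private"] == value).fillna(False).to_numpy()
    raise ValueError(f"unknown stratum kind: {kind}")


def hml(g: GenotypeMatrix, threshold: float, weights: str = "none",
        stratum: tuple[str, object] | None = None,
        annotations: AnnotationTable | None = None) -> ScoreMatrix:
    """Homozygous mutation load: homozygosity of low-frequency alternate alleles.

    Counts (``weights='none'``) or 1/AF-weights (``weights='inverse_af'``)
    the hom-alt genotypes at SNPs with alternate frequency <= ``threshold``,
    optionally restricted to a stratum such as ``("class",
    "deleterious_missense")`` or ``("private", True)``.
    """
    if not 0.0 < threshold <= 0.5:
        raise ValueError("HML threshold must lie in (0, 0.5]")
    if weights not in ("none", "inverse_af"):
        raise ValueError(f"unknown weights: {weights}")
    af = g.af
    mask = (af > 0) & (af <= threshold) & _stratum_mask(g, stratum, annotations)
    d = g.dosages[:, mask]
    homalt = d == 2
    if weights == "none":
        score = homalt.sum(axis=1).astype(float)
    else:
        w = 1.0 / af[mask]
        score = (homalt * w).sum(axis=1)
    name = f"hml_{weights}_le{threshold:g}" + (
        "" if stratum is None else f"_{stratum[0]}={stratum[1]}")
    values = pd.DataFrame({name: score}, index=g.sample_ids)
    meta = pd.DataFrame(
        [(name, "hml", np.nan, threshold, int(mask.sum()), False, "")],
        columns=["name", "kind", "lo", "hi", "n_snps", "excluded",
                 "exclude_reason"]).set_index("name")
    return ScoreMatrix(values, meta)


def hml_profile(g: GenotypeMatrix, thresholds=(0.05, 0.10, 0.15),
                weights=("none", "inverse_af"),
                strata=(None,), annotations: AnnotationTable | None = None
                ) -> ScoreMatrix:
    """HML across thresholds x weightings x strata, as one ScoreMatrix."""
    parts = [hml(g, t, w, s, annotations)
             for t in thresholds for w in weights for s in strata]
    return ScoreMatrix(pd.concat([p.values for p in parts], axis=1),
                       pd.concat([p.meta for p in parts]))


# ---------------------------------------------------------------------------
# Regional (1 Mb) scores
# ---------------------------------------------------------------------------


def make_windows(snp_meta: pd.DataFrame, window_bp: int = MB) -> pd.DataFrame:
    """Half-open windows [k*w, (k+1)*w) tiling each chromosome from 0."""
    rows = []
    for chrom, grp in snp_meta.groupby("chrom", sort=False):
        last = int(grp["bp"].max())
        for k in range(last // window_bp + 1):
            rows.append((chrom, k * window_bp, (k + 1) * window_bp))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def window_index(snp_meta: pd.DataFrame, windows: pd.DataFrame) -> list[np.ndarray]:
    """SNP index arrays per window (bp in [start, end))."""
    chrom = snp_meta["chrom"].to_numpy()
    bp = snp_meta["bp"].to_numpy()
    out = []
    for w in windows.itertuples():
        out.append(np.flatnonzero((chrom == w.chrom) & (bp >= w.start) & (bp < w.end)))
    return out


def regional_scores(
    g_wgs: GenotypeMatrix,
    g_array: GenotypeMatrix,
    window_bp: int = MB,
    hml_threshold: float = 0.15,
    hml_weights: str = "none",
    min_array_snps: int = 5,
    min_wgs_snps: int = 2000,
    min_nonzero_individuals: int = 8,
) -> tuple[ScoreMatrix, ScoreMatrix]:
    """Per-window homozygosity and HML with the exclusion filters.

    Regional homozygosity is excluded where the window holds fewer than
    ``min_array_snps`` array SNPs; regional HML additionally where it holds
    fewer than ``min_wgs_snps`` WGS SNPs or fewer than
    ``min_nonzero_individuals`` individuals with a non-zero score.  Excluded
    windows keep their values but are flagged with the failing rule(s).
    """
    windows = make_windows(g_wgs.snp_meta, window_bp)
    wgs_idx = window_index(g_wgs.snp_meta, windows)
    arr_idx = window_index(g_array.snp_meta, windows)
    af = g_wgs.af
    d = g_wgs.dosages

    hom_cols, hom_meta, hml_cols, hml_meta = {}, [], {}, []
    for j, w in enumerate(windows.itertuples()):
        name = f"{w.chrom}:{w.start // window_bp}"
        idx = wgs_idx[j]
        sub = d[:, idx]
        ok = sub != MISSING
        hom = ((sub == 0) | (sub == 2)).sum(axis=1)
        hom_cols[name] = _ratio(hom, ok.sum(axis=1))

        rare = idx[(af[idx] > 0) & (af[idx] <= hml_threshold)]
        homalt = d[:, rare] == 2
        if hml_weights == "inverse_af":
            score = (homalt * (1.0 / af[rare])).sum(axis=1)
        else:
            score = homalt.sum(axis=1).astype(float)
        hml_cols[name] = score

        n_arr, n_wgs = len(arr_idx[j]), len(idx)
        hom_rules = []
        if n_arr < min_array_snps:
            hom_rules.append(f"<{min_array_snps} array SNPs")
        hml_rules = list(hom_rules)
        if n_wgs < min_wgs_snps:
            hml_rules.append(f"<{min_wgs_snps} WGS SNPs")
        if int((score > 0).sum()) < min_nonzero_individuals:
            hml_rules.append(f"<{min_nonzero_individuals} nonzero individuals")
        base = (name, w.chrom, w.start, w.end, n_wgs, n_arr)
        hom_meta.append(base + (bool(hom_rules), "; ".join(hom_rules)))
        hml_meta.append(base + (bool(hml_rules), "; ".join(hml_rules)))

    idx_ids = g_wgs.sample_ids
    cols = ["name", "chrom", "start", "end", "n_snps", "n_array_snps",
            "excluded", "exclude_reason"]
    hom_sm = ScoreMatrix(pd.DataFrame(hom_cols, index=idx_ids),
                         pd.DataFrame(hom_meta, columns=cols).set_index("name"))
    hml_sm = ScoreMatrix(pd.DataFrame(hml_cols, index=idx_ids),
                         pd.DataFrame(hml_meta, columns=cols).set_index("name"))
    return hom_sm, hml_sm
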
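"""PLINK-style runs-of-homozygosity (ROH) detection and F_ROH.

A ROH is a maximal run of homozygous genotypes, split wherever the spacing
between consecutive SNPs reaches the maximum gap, then filtered on SNP
count, physical length (strict >) and SNP density.  Segment length is the
distance from the first to the last SNP of the run, as in PLINK.  With the
zero-heterozygote setting used throughout (the strictest PLINK
configuration), the sliding-window vote reduces to these maximal-run
semantics, so no window machinery is applied unless heterozygotes are
allowed (not implemented; see ROHParams).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MISSING

MB = 1_000_000


@dataclass
class ROHParams:
    """Scanner thresholds; the defaults are the strict zero-het settings
    commonly used for WGS-era cattle data (50 SNPs, >2 Mb, <500 kb gaps,
    at least 1 SNP per 100 kb)."""

    min_snps: int = 50
    min_length_bp: int = 2 * MB
    max_gap_bp: int = 500_000
    density_bp_per_snp: int = 100_000
    window_snps: int = 50
    allowed_het: int = 0
    max_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.min_snps, self.min_length_bp, self.max_gap_bp,
               self.density_bp_per_snp, self.window_snps) <= 0:
            raise ValueError("ROH parameters must be positive")
        if self.allowed_het < 0 or self.max_missing < 0:
            raise ValueError("allowed_het and max_missing must be >= 0")
        if self.allowed_het > 0:
            raise NotImplementedError(
                "heterozygote-tolerant window voting is not implemented; "
                "use allowed_het=0")


@dataclass
class ROHSegment:
    chrom: object
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _passes(params: ROHParams, start: int, end: int, n: int) -> bool:
    length = end - start
    if n < params.min_snps:
        return False
    if length <= params.min_length_bp:
        return False
    return n >= length / params.density_bp_per_snp


def detect_roh(dosages, chrom, bp, params: ROHParams | None = None) -> list[ROHSegment]:
    """Detect ROH in one individual's genotypes.

    ``dosages`` is a 1-D vector over SNPs ordered by (chrom, bp); positions
    must be sorted within chromosomes.  Missing genotypes are run-compatible
    up to ``params.max_missing`` per candidate run; a run exceeding that
    budget is split at every missing site.
    """
    params = params or ROHParams()
    d = np.asarray(dosages)
    chrom = np.asarray(chrom)
    bp = np.asarray(bp, dtype=np.int64)
    if d.ndim != 1:
        raise ValueError("detect_roh expects one individual (1-D dosages)")
    segs: list[ROHSegment] = []
    for c in pd.unique(chrom):
        m = chrom == c
        pos = bp[m]
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"positions not sorted within chromosome {c}")
        segs.extend(_scan_chrom(d[m], pos, c, params))
    return segs


def _scan_chrom(d, pos, c, params):
    compat = (d == 0) | (d == 2) | (d == MISSING)
    # break before SNP i when incompatible or when gap >= max_gap
    brk = np.flatnonzero(~compat)
    gap_break = np.flatnonzero(np.diff(pos) >= params.max_gap_bp) + 1
    bounds = np.concatenate([[0], brk, brk + 1, gap_break, [len(d)]])
    bounds = np.unique(bounds)
    out = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        idx = np.arange(lo, hi)
        idx = idx[compat[idx]]
        if len(idx) == 0:
            continue
        for run in _apply_missing_budget(d, idx, params.max_missing):
            if len(run) == 0:
                continue
            s, e = int(pos[run[0]]), int(pos[run[-1]])
            n = len(run)
            if _passes(params, s, e, n):
                out.append(ROHSegment(c, s, e, n))
    return out


def _apply_missing_budget(d, idx, budget):
    miss = d[idx] == MISSING
    if miss.sum() <= budget:
        yield idx
        return
    # over budget: split at every missing site (documented greedy rule)
    start = 0
    for j in np.flatnonzero(miss):
        yield idx[start:j]
        start = j + 1
    yield idx[start:]


DEFAULT_LENGTH_CLASSES = (2 * MB, 5 * MB, 10 * MB)


def _class_label(lo: int, hi: float) -> str:
    if np.isinf(hi):
        return f">{lo // MB}Mb"
    return f"{lo // MB}-{hi // MB}Mb"


def f_roh(segments: list[ROHSegment], genome_extent_bp: float,
          length_classes=DEFAULT_LENGTH_CLASSES) -> pd.Series:
    """Proportion of the genome in ROH, total and per length class.

    ``genome_extent_bp`` is the summed (last SNP - first SNP) span over
    chromosomes.  Length classes are half-open [lo, hi) bins built from the
    given breakpoints (defaults: [2,5), [5,10), [10,inf) Mb); their values
    sum exactly to the total.
    """
    if genome_extent_bp <= 0:
        raise ValueError("genome extent must be positive")
    edges = list(length_classes) + [np.inf]
    labels = [_class_label(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    vals = dict.fromkeys(labels, 0.0)
    total = 0.0
    for s in segments:
        total += s.length_bp
        for i, lab in enumerate(labels):
            if edges[i] <= s.length_bp < edges[i + 1]:
                vals[lab] += s.length_bp
                break
    out = pd.Series({"total": total, **vals}) / genome_extent_bp
    return out


def genome_extent(chrom, bp) -> float:
    """Sum over chromosomes of (last SNP bp - first SNP bp)."""
    chrom = np.asarray(chrom)
    bp = np.asarray(bp)
    return float(sum(bp[chrom == c].max() - bp[chrom == c].min()
                     for c in pd.unique(chrom)))


def locus_roh(segments: list[ROHSegment], chrom, bp) -> np.ndarray:
    """Per-SNP 0/1 ROH status (segment endpoints inclusive)."""
    chrom = np.asarray(chrom)
    bp = np.asarray(bp)
    out = np.zeros(len(bp), dtype=np.int8)
    for s in segments:
        out[(chrom == s.chrom) & (bp >= s.start_bp) & (bp <= s.end_bp)] = 1
    return out


def detect_roh_matrix(g, params: ROHParams | None = None):
    """ROH per individual of a GenotypeMatrix: (list of segment lists,
    per-individual locus status matrix)."""
    chrom = g.snp_meta["chrom"].to_numpy()
    bp = g.snp_meta["bp"].to_numpy()
    seg_lists, status = [], np.zeros(g.dosages.shape, dtype=np.int8)
    for i in range(g.n_individuals):
        segs = detect_roh(g.dosages[i], chrom, bp, params)
        seg_lists.append(segs)
        status[i] = locus_roh(segs, chrom, bp)
    return seg_lists, status
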
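"""Synthetic pedigreed genotype data with known autozygosity.

The generator produces everything the evaluation framework consumes, with
the statistical structure real data would have, plus the ground truth real
data lacks:

* a founder haplotype pool from a forward Wright-Fisher burn-in with
  recombination and recurrent mutation, giving a low-frequency-heavy allele
  frequency spectrum, linkage disequilibrium from the finite pool size, and
  a recorded origin generation (age) per allele;
* a held-out second population, split off before the end of the burn-in,
  whose sampled haplotypes define "private" alleles (alternate alleles
  absent from the held-out sample);
* a multi-generation pedigree with a configurable fraction of close matings
  (full sib / half sib / first cousin), so inbreeding varies widely;
* gene dropping: founder haplotypes are transmitted through the pedigree
  with crossovers sampled as a Poisson process on the genetic map (no
  interference, matching the exponential segment-length assumption of the
  HBD model), with founder-tract labels propagated so per-locus autozygosity
  is known exactly;
* an ascertained "array" marker subset (founder-generation MAF cutoff,
  evenly spaced), and functional-class labels whose frequency spectrum is
  tilted toward rare/young alleles for deleterious classes.

Genotyping error, when configured, is applied to emitted genotypes only,
never to the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data_io import (AnnotationTable, GenotypeMatrix, Pedigree,
                      build_pedigree)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Desk-scale defaults mimic a livestock WGS pedigree study: a genome of
    10 x 1 Morgan / 50 Mb chromosomes, a founder pool of 200 haplotypes with
    a 200-generation burn-in, and a 5-generation pedigree whose last
    generation has 100 offspring with 20% close matings."""

    # founder pool
    n_founder_haplotypes: int = 200
    burnin_generations: int = 200
    mutation_rate: float = 20.0          # new mutations per haplotype per generation
    # genome
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0
    chrom_length_bp: int = 50_000_000
    # held-out population (for the private-allele flag)
    split_generations: int = 50
    heldout_pool_size: int = 100
    heldout_sample_haplotypes: int = 100
    # pedigree design: the last two adult generations (2 x 75) form the
    # "parent" cohort above the 100 final offspring
    pedigree_founders: int = 60
    pedigree_generations: int = 5
    generation_size: int = 75
    final_generation_size: int = 100
    close_mating_fraction: float = 0.20
    # marker panels and noise
    array_maf_cutoff: float = 0.05
    array_target: int = 8000
    genotyping_error: float = 0.0
    # annotation model
    all_neutral_annotations: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.close_mating_fraction <= 1.0:
            raise ValueError("close_mating_fraction must lie in [0, 1]")
        for name in ("n_founder_haplotypes", "mutation_rate", "n_chromosomes",
                     "chrom_length_morgans", "chrom_length_bp",
                     "pedigree_founders", "pedigree_generations",
                     "generation_size", "final_generation_size",
                     "array_target"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burnin_generations < 0 or self.split_generations < 0:
            raise ValueError("generation counts must be non-negative")
        if 2 * self.pedigree_founders > self.n_founder_haplotypes:
            raise ValueError("founder pool too small for the pedigree founders")

    @property
    def cm_per_bp(self) -> float:
        return 100.0 * self.chrom_length_morgans / self.chrom_length_bp

    @property
    def chrom_length_cm(self) -> float:
        return 100.0 * self.chrom_length_morgans


# ---------------------------------------------------------------------------
# Founder pool: forward Wright-Fisher burn-in
# ---------------------------------------------------------------------------


@dataclass
class FounderPool:
    """Haploid pool at the end of the burn-in, sites sorted by (chrom, bp)."""

    haplotypes: np.ndarray        # (n_haplotypes, n_sites) bool
    chrom: np.ndarray             # (n_sites,) int
    bp: np.ndarray                # (n_sites,) int
    age: np.ndarray               # generations since origin, at pedigree start
    heldout_present: np.ndarray   # alt allele observed in the held-out sample
    config: SimConfig

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def cm(self) -> np.ndarray:
        return self.bp * self.config.cm_per_bp

    @property
    def af(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    @property
    def maf(self) -> np.ndarray:
        a = self.af
        return np.minimum(a, 1.0 - a)


def _gkey(chrom, bp, cfg):
    return chrom.astype(np.int64) * (cfg.chrom_length_bp + 1) + bp


def _chrom_starts(chrom):
    s = np.zeros(len(chrom), dtype=bool)
    if len(chrom):
        s[0] = True
        s[1:] = chrom[1:] != chrom[:-1]
    return s


def _recombine(H, chrom, bp, pa, pb, cfg, rng):
    """One generation of offspring haplotypes from parent rows pa / pb.

    The source-haplotype mask is built from crossover toggles: each
    crossover flips the mask for all downstream sites of its chromosome (an
    odd toggle count means a switch, so the Poisson/Haldane model is exact),
    and an independent fair toggle at every chromosome start re-randomizes
    the starting parent.
    """
    n, S = len(pa), H.shape[1]
    if S == 0:
        return H[pa]
    toggles = np.zeros((n, S), dtype=bool)
    starts = np.flatnonzero(_chrom_starts(chrom))
    toggles[:, starts] = rng.random((n, len(starts))) < 0.5
    total_m = cfg.n_chromosomes * cfg.chrom_length_morgans
    k = rng.poisson(n * total_m)
    if k:
        child = rng.integers(0, n, k)
        xc = rng.integers(0, cfg.n_chromosomes, k)
        xbp = rng.integers(0, cfg.chrom_length_bp, k)
        gk = _gkey(chrom, bp, cfg)
        idx = np.searchsorted(gk, xc.astype(np.int64) * (cfg.chrom_length_bp + 1) + xbp)
        ok = (idx < S) & (chrom[np.minimum(idx, S - 1)] == xc)
        np.logical_xor.at(toggles, (child[ok], idx[ok]), True)
    mask = np.logical_xor.accumulate(toggles, axis=1)
    return np.where(mask, H[pa], H[pb])


def _add_mutations(H, chrom, bp, origin, cfg, rng, gen):
    """Add Poisson(n * mu) new singleton sites originating in ``gen``."""
    n = H.shape[0]
    m = rng.poisson(n * cfg.mutation_rate)
    if not m:
        return H, chrom, bp, origin
    mc = rng.integers(0, cfg.n_chromosomes, m).astype(np.int16)
    mbp = rng.integers(1, cfg.chrom_length_bp, m)
    newk = _gkey(mc, mbp, cfg)
    fresh = ~np.isin(newk, _gkey(chrom, bp, cfg))
    _, keep_first = np.unique(newk[fresh], return_index=True)
    mc, mbp = mc[fresh][keep_first], mbp[fresh][keep_first]
    cols = np.zeros((n, len(mc)), dtype=bool)
    cols[rng.integers(0, n, len(mc)), np.arange(len(mc))] = True
    H = np.concatenate([H, cols], axis=1)
    chrom = np.concatenate([chrom, mc])
    bp = np.concatenate([bp, mbp])
    origin = np.concatenate([origin, np.full(len(mc), gen, dtype=origin.dtype)])
    order = np.argsort(_gkey(chrom, bp, cfg), kind="stable")
    return H[:, order], chrom[order], bp[order], origin[order]


def _evolve(H, chrom, bp, origin, gens, cfg, rng, gen0, mutate=True, prune=True):
    """Run the Wright-Fisher pool forward; returns updated state arrays."""
    n = H.shape[0]
    for g in range(gens):
        pa = rng.integers(0, n, n)
        pb = rng.integers(0, n, n)
        H = _recombine(H, chrom, bp, pa, pb, cfg, rng)
        if mutate:
            H, chrom, bp, origin = _add_mutations(H, chrom, bp, origin, cfg,
                                                  rng, gen0 + g + 1)
        if prune:
            cnt = H.sum(axis=0)
            keep = (cnt > 0) & (cnt < n)
            if not keep.all():
                H, chrom, bp, origin = H[:, keep], chrom[keep], bp[keep], origin[keep]
    return H, chrom, bp, origin


def simulate_founders(config: SimConfig, rng=None) -> FounderPool:
    """Burn in the founder pool and flag held-out-population presence.

    The held-out population splits off ``split_generations`` before the end
    of the burn-in and evolves independently (drift only); alleles absent
    from a sample of its haplotypes are "private" to the main population.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_founder_haplotypes
    H = np.zeros((n, 0), dtype=bool)
    chrom = np.zeros(0, dtype=np.int16)
    bp = np.zeros(0, dtype=np.int64)
    origin = np.zeros(0, dtype=np.int32)
    # fresh mutations of the starting generation (with a 0-generation burn-in
    # the pool holds only these: age-0 singletons at frequency 1/n)
    H, chrom, bp, origin = _add_mutations(H, chrom, bp, origin, config, rng, 0)

    pre = max(config.burnin_generations - config.split_generations, 0)
    H, chrom, bp, origin = _evolve(H, chrom, bp, origin, pre, config, rng, 0)

    # split: the held-out pool drifts without further mutation or pruning
    nh = config.heldout_pool_size
    Hh = H[rng.integers(0, n, nh)].copy()
    chrom_h, bp_h = chrom.copy(), bp.copy()
    rng_h = np.random.default_rng(rng.integers(0, 2**31 - 1))
    Hh, _, _, _ = _evolve(Hh, chrom_h, bp_h, origin.copy(),
                          config.burnin_generations - pre, config, rng_h,
                          pre, mutate=False, prune=False)

    H, chrom, bp, origin = _evolve(H, chrom, bp, origin,
                                   config.burnin_generations - pre,
                                   config, rng, pre)
    if H.shape[1] == 0:
        raise RuntimeError("no polymorphic sites after burn-in; "
                           "increase mutation_rate or burnin_generations")

    sample = Hh[rng.integers(0, nh, config.heldout_sample_haplotypes)]
    present_by_key = dict(zip(_gkey(chrom_h, bp_h, config),
                              sample.any(axis=0)))
    heldout = np.array([present_by_key.get(k, False)
                        for k in _gkey(chrom, bp, config)])
    age = (config.burnin_generations - origin).astype(np.int32)
    return FounderPool(H, chrom, bp, age, heldout, config)


# ---------------------------------------------------------------------------
# Pedigree design
# ---------------------------------------------------------------------------


def build_sim_pedigree(config: SimConfig, rng) -> tuple[Pedigree, dict]:
    """Random multi-generation pedigree with a set fraction of close matings.

    Close matings are drawn evenly from full-sib, half-sib and first-cousin
    pairs available in the previous generation (falling back to a random
    pair when none exists); other matings pair individuals that share no
    parent.  Returns the pedigree and the per-generation id lists.
    """
    records: list[tuple[str, str, str]] = []
    parents_of: dict[str, tuple[str, str]] = {}
    gen_ids: dict[int, list[str]] = {}

    g0 = [f"F{i}" for i in range(config.pedigree_founders)]
    for x in g0:
        records.append((x, "0", "0"))
        parents_of[x] = ("0", "0")
    gen_ids[0] = g0

    def share_parent(a, b):
        pa, pb = parents_of[a], parents_of[b]
        return any(p != "0" and p in pb for p in pa)

    def full_sib_pairs(pool):
        groups: dict[tuple, list[str]] = {}
        for x in pool:
            if parents_of[x] != ("0", "0"):
                groups.setdefault(parents_of[x], []).append(x)
        return [(a, b) for grp in groups.values() if len(grp) > 1
                for i, a in enumerate(grp) for b in grp[i + 1:]]

    def half_sib_pairs(pool):
        out = []
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                pa, pb = parents_of[a], parents_of[b]
                shared = sum(1 for p in pa if p != "0" and p in pb)
                if shared == 1:
                    out.append((a, b))
        return out

    def cousin_pairs(pool):
        out = []
        for i, a in enumerate(pool):
            for b in pool[i + 1:]:
                if share_parent(a, b):
                    continue
                pa = [p for p in parents_of[a] if p != "0"]
                pb = [p for p in parents_of[b] if p != "0"]
                if any(u != v and parents_of.get(u, ("0", "0")) != ("0", "0")
                       and parents_of[u] == parents_of.get(v)
                       for u in pa for v in pb):
                    out.append((a, b))
        return out

    counter = 0
    for t in range(1, config.pedigree_generations):
        prev = gen_ids[t - 1]
        size = (config.final_generation_size
                if t == config.pedigree_generations - 1
                else config.generation_size)
        closes = {"full_sib": full_sib_pairs(prev),
                  "half_sib": half_sib_pairs(prev),
                  "cousin": cousin_pairs(prev)}
        ids = []
        for _ in range(size):
            pair = None
            if rng.random() < config.close_mating_fraction:
                kind = ("full_sib", "half_sib", "cousin")[rng.integers(0, 3)]
                pool_pairs = closes[kind] or sum(closes.values(), [])
                if pool_pairs:
                    pair = pool_pairs[rng.integers(0, len(pool_pairs))]
            if pair is None:
                for _ in range(50):
                    a, b = rng.choice(len(prev), 2, replace=False)
                    a, b = prev[a], prev[b]
                    if not share_parent(a, b):
                        pair = (a, b)
                        break
                else:
                    a, b = rng.choice(len(prev), 2, replace=False)
                    pair = (prev[a], prev[b])
            x = f"G{t}_{counter}"
            counter += 1
            records.append((x, pair[0], pair[1]))
            parents_of[x] = (pair[0], pair[1])
            ids.append(x)
        gen_ids[t] = ids
    return build_pedigree(records), gen_ids


# ---------------------------------------------------------------------------
# Gene dropping with founder-tract tracking
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Founder-tract labels and realized autozygosity for every individual.

    ``tracts[iid]`` holds, per chromosome, the two haplotypes as
    (breaks_cm, labels) pairs: ``labels[j]`` is the founder-haplotype id on
    [breaks_cm[j], breaks_cm[j+1]); breaks end at the chromosome length.
    ``autozygous[iid]`` holds per-chromosome bp intervals where the two
    labels coincide.
    """

    sample_ids: list[str]
    tracts: dict
    autozygous: dict
    config: SimConfig

    def site_autozygosity(self, chrom, bp) -> np.ndarray:
        """Per-SNP 0/1 true autozygosity matrix (individuals x SNPs)."""
        chrom = np.asarray(chrom)
        bp = np.asarray(bp)
        out = np.zeros((len(self.sample_ids), len(bp)), dtype=np.int8)
        for i, iid in enumerate(self.sample_ids):
            for c, intervals in self.autozygous[iid].items():
                m = chrom == c
                pos = bp[m]
                flags = np.zeros(len(pos), dtype=np.int8)
                for lo, hi in intervals:
                    flags[(pos >= lo) & (pos < hi)] = 1
                out[i, m] = flags
        return out


def _tract_template(cfg):
    return [(np.array([0.0, cfg.chrom_length_cm]), None)]


def _meiosis(hap_a, hap_b, cfg, rng):
    """Recombine two parental haplotypes (per-chromosome tract lists).

    Crossover count per chromosome is Poisson(length in Morgans) with
    positions uniform in cM (no interference); the starting parent is fair.
    """
    child = []
    for (br_a, lab_a), (br_b, lab_b) in zip(hap_a, hap_b):
        k = rng.poisson(cfg.chrom_length_morgans)
        cuts = np.sort(rng.random(k)) * cfg.chrom_length_cm
        use_a = bool(rng.integers(0, 2))
        segments = []  # (end_cm, label)
        lo = 0.0
        for hi in np.append(cuts, cfg.chrom_length_cm):
            if hi > lo:
                br, lab = (br_a, lab_a) if use_a else (br_b, lab_b)
                j = int(np.searchsorted(br, lo, side="right")) - 1
                pos = lo
                while pos < hi:
                    seg_end = min(float(br[j + 1]), hi)
                    segments.append((seg_end, lab[j]))
                    pos = seg_end
                    j += 1
                lo = hi
            use_a = not use_a
        # merge adjacent identical labels
        mb, ml = [0.0], []
        for end, l in segments:
            if ml and ml[-1] == l:
                mb[-1] = end
            else:
                ml.append(l)
                mb.append(end)
        child.append((np.asarray(mb), np.asarray(ml, dtype=np.int32)))
    return child


def _autozygous_intervals(hap1, hap2, cfg):
    """bp intervals where the two haplotypes carry the same founder label."""
    out = {}
    for c, ((b1, l1), (b2, l2)) in enumerate(zip(hap1, hap2)):
        cuts = np.unique(np.concatenate([b1, b2]))
        ivals = []
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            j1 = np.searchsorted(b1, lo, side="right") - 1
            j2 = np.searchsorted(b2, lo, side="right") - 1
            if l1[j1] == l2[j2]:
                lo_bp = lo / cfg.cm_per_bp
                hi_bp = hi / cfg.cm_per_bp
                if ivals and abs(ivals[-1][1] - lo_bp) < 1e-6:
                    ivals[-1] = (ivals[-1][0], hi_bp)
                else:
                    ivals.append((lo_bp, hi_bp))
        out[c] = ivals
    return out


def _paint(hap, pool, site_slices):
    """Allele vector for one haplotype from its founder tracts."""
    S = pool.n_sites
    alleles = np.zeros(S, dtype=np.int8)
    for c, (breaks, labels) in enumerate(hap):
        lo, hi, cm_chrom = site_slices[c]
        idx = lo + np.searchsorted(cm_chrom, breaks[:-1], side="left")
        idx = np.append(idx, hi)
        for j, lab in enumerate(labels):
            a, b = idx[j], idx[j + 1]
            if a < b:
                alleles[a:b] = pool.haplotypes[lab, a:b]
    return alleles


def gene_drop(ped: Pedigree, pool: FounderPool, rng,
              genotyping_error: float | None = None
              ) -> tuple[GenotypeMatrix, SimTruth]:
    """Drop founder haplotypes through the pedigree.

    Founders receive two distinct pool haplotypes; every meiosis samples
    crossovers as a Poisson process on the genetic map.  Returns the emitted
    genotype matrix (with genotyping error applied after the truth is
    recorded) and the :class:`SimTruth` tract bookkeeping.
    """
    cfg = pool.config
    err = cfg.genotyping_error if genotyping_error is None else genotyping_error
    founders = ped.founders()
    if 2 * len(founders) > pool.haplotypes.shape[0]:
        raise ValueError("founder pool has too few haplotypes for this pedigree")
    perm = rng.permutation(pool.haplotypes.shape[0])

    site_slices = []
    for c in range(cfg.n_chromosomes):
        m = pool.chrom == c
        lo = int(np.argmax(m)) if m.any() else 0
        hi = lo + int(m.sum())
        site_slices.append((lo, hi, pool.cm[m]))

    haps: dict[str, tuple] = {}
    for i, f in enumerate(founders):
        h1 = [(np.array([0.0, cfg.chrom_length_cm]),
               np.array([perm[2 * i]], dtype=np.int32))
              for _ in range(cfg.n_chromosomes)]
        h2 = [(np.array([0.0, cfg.chrom_length_cm]),
               np.array([perm[2 * i + 1]], dtype=np.int32))
              for _ in range(cfg.n_chromosomes)]
        haps[f] = (h1, h2)
    for x in ped.ids:
        if x in haps:
            continue
        s, d = ped.parents(x)
        hs = _meiosis(*haps[s], cfg, rng)
        hd = _meiosis(*haps[d], cfg, rng)
        haps[x] = (hs, hd)

    dos = np.empty((len(ped.ids), pool.n_sites), dtype=np.int8)
    tracts, autoz = {}, {}
    for i, x in enumerate(ped.ids):
        h1, h2 = haps[x]
        dos[i] = _paint(h1, pool, site_slices) + _paint(h2, pool, site_slices)
        tracts[x] = haps[x]
        autoz[x] = _autozygous_intervals(h1, h2, cfg)
    truth = SimTruth(list(ped.ids), tracts, autoz, cfg)

    if err and err > 0:
        flip = rng.random(dos.shape) < err
        shift = rng.integers(1, 3, size=dos.shape)
        dos = np.where(flip, (dos + shift) % 3, dos).astype(np.int8)

    meta = pd.DataFrame({
        "chrom": pool.chrom, "bp": pool.bp,
        "cm": pool.cm, "ref": "A", "alt": "C", "af": np.nan,
    })
    g = GenotypeMatrix(dos, meta, list(ped.ids)).refresh_af()
    return g, truth


def true_f(truth: SimTruth, region: tuple | None = None) -> pd.Series:
    """Realized autozygosity: fraction of bp with identical founder labels.

    ``region`` is an optional (chrom, start_bp, end_bp) half-open window;
    the default is genome-wide.
    """
    cfg = truth.config
    out = {}
    for iid in truth.sample_ids:
        num = 0.0
        for c, intervals in truth.autozygous[iid].items():
            for lo, hi in intervals:
                if region is not None:
                    rc, rlo, rhi = region
                    if c != rc:
                        continue
                    lo, hi = max(lo, rlo), min(hi, rhi)
                num += max(hi - lo, 0.0)
        denom = (cfg.n_chromosomes * cfg.chrom_length_bp if region is None
                 else region[2] - region[1])
        out[iid] = num / denom
    return pd.Series(out, name="true_f")


def true_f_windows(truth: SimTruth, windows: pd.DataFrame) -> pd.DataFrame:
    """Per-individual x per-window realized autozygosity."""
    cols = {}
    for w in windows.itertuples():
        name = f"{w.chrom}:{int(w.start) // (w.end - w.start)}"
        cols[name] = true_f(truth, (w.chrom, w.start, w.end))
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Array ascertainment and annotations
# ---------------------------------------------------------------------------


def ascertain_array(pool_maf: np.ndarray, maf_cutoff: float, target: int,
                    rng=None) -> np.ndarray:
    """Index of "array" SNPs: founder-generation MAF >= cutoff, evenly
    thinned across the (sorted) map.  Deterministic given the inputs."""
    if not 0.0 < maf_cutoff < 0.5:
        raise ValueError("maf_cutoff must lie in (0, 0.5)")
    qual = np.flatnonzero(np.asarray(pool_maf) >= maf_cutoff)
    if len(qual) <= target:
        if len(qual) < target:
            import warnings

            warnings.warn(f"only {len(qual)} SNPs pass the array MAF cutoff "
                          f"(target {target}); returning all of them")
        return qual
    pick = np.unique(np.round(np.linspace(0, len(qual) - 1, target)).astype(int))
    return qual[pick]


def assign_annotations(pool: FounderPool, rng,
                       all_neutral: bool | None = None) -> AnnotationTable:
    """Sample functional classes with deleterious classes tilted toward
    rare, young alleles; the private flag marks alleles absent from the
    held-out population sample."""
    cfg = pool.config
    neutral = cfg.all_neutral_annotations if all_neutral is None else all_neutral
    af = pool.af
    age = pool.age.astype(float)
    age_scale = max(cfg.burnin_generations / 4.0, 1.0)
    base = np.array([0.90, 0.04, 0.03, 0.03])  # other, syn, tol, del
    if neutral:
        w_tol = np.ones_like(af)
        w_del = np.ones_like(af)
    else:
        w_tol = np.exp(-af / 0.3)
        w_del = np.exp(-af / 0.1) * np.exp(-age / age_scale)
    w = np.stack([np.full_like(af, base[0]),
                  np.full_like(af, base[1]),
                  base[2] * w_tol,
                  base[3] * w_del], axis=1)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(len(af))
    cls_idx = (u[:, None] > w.cumsum(axis=1)).sum(axis=1)
    classes = np.array(["other", "synonymous", "tolerated_missense",
                        "deleterious_missense"])[cls_idx]
    table = pd.DataFrame({
        "chrom": pool.chrom, "bp": pool.bp,
        "func_class": classes,
        "private": ~pool.heldout_present,
        "age": pool.age,
    })
    return AnnotationTable(table)


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------


@dataclass
class SimDataset:
    """Everything one study-scale replicate provides."""

    config: SimConfig
    pool: FounderPool
    pedigree: Pedigree
    generations: dict
    wgs: GenotypeMatrix
    array_index: np.ndarray
    annotations: AnnotationTable
    truth: SimTruth

    @property
    def offspring_ids(self) -> list[str]:
        return self.generations[max(self.generations)]

    @property
    def parent_ids(self) -> list[str]:
        last = set(self.offspring_ids)
        ids = {p for x in last for p in self.pedigree.parents(x) if p != "0"}
        return [x for x in self.pedigree.ids if x in ids]

    @property
    def cohort_ids(self) -> list[str]:
        """The genotyped study cohort: the two adult generations above the
        final offspring, plus the offspring themselves."""
        top = max(self.generations)
        return (self.generations[top - 2] + self.generations[top - 1]
                + self.generations[top])

    def array_matrix(self, samples: list[str] | None = None) -> GenotypeMatrix:
        """Polymorphic array-SNP matrix (frequencies from its own samples)."""
        g = self.wgs.subset_snps(self.array_index)
        if samples is not None:
            g = g.subset_samples(samples)
        g = g.refresh_af()
        af = g.af
        return g.subset_snps((af > 0) & (af < 1))


def simulate_dataset(config: SimConfig | None = None,
                     seed: int | None = None) -> SimDataset:
    """Run the full generator: burn-in, pedigree, gene drop, ascertainment,
    annotation.  Fully reproducible from (config, seed)."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    pool = simulate_founders(config, rng)
    ped, gens = build_sim_pedigree(config, rng)
    wgs, truth = gene_drop(ped, pool, rng)
    array_index = ascertain_array(pool.maf, config.array_maf_cutoff,
                                  config.array_target, rng)
    ann = assign_annotations(pool, rng)
    return SimDataset(config, pool, ped, gens, wgs, array_index, ann, truth)
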
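import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from autozykit.data_io import build_pedigree
from autozykit.simulate import (SimConfig, ascertain_array,
                                assign_annotations, build_sim_pedigree,
                                gene_drop, simulate_dataset,
                                simulate_founders, true_f, true_f_windows)
from autozykit.pedigree import inbreeding_pedigree

from conftest import SMALL_CONFIG


TINY = SimConfig(seed=5, n_founder_haplotypes=60, burnin_generations=25,
                 mutation_rate=6.0, n_chromosomes=3, chrom_length_bp=20_000_000,
                 split_generations=10, heldout_pool_size=30,
                 heldout_sample_haplotypes=30, pedigree_founders=10,
                 pedigree_generations=3, generation_size=12,
                 final_generation_size=12, array_target=400)


def test_zero_burnin_gives_fresh_singletons():
    cfg = replace(TINY, burnin_generations=0, split_generations=0)
    pool = simulate_founders(cfg)
    assert (pool.age == 0).all()
    np.testing.assert_allclose(pool.af, 1 / cfg.n_founder_haplotypes)


def test_burnin_determinism():
    a = simulate_founders(TINY)
    b = simulate_founders(TINY)
    np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
    np.testing.assert_array_equal(a.bp, b.bp)
    np.testing.assert_array_equal(a.age, b.age)


def test_dataset_determinism():
    a = simulate_dataset(TINY)
    b = simulate_dataset(TINY)
    np.testing.assert_array_equal(a.wgs.dosages, b.wgs.dosages)
    np.testing.assert_array_equal(a.array_index, b.array_index)
    assert a.pedigree.ids == b.pedigree.ids
    pd.testing.assert_frame_equal(a.annotations.table, b.annotations.table)


def test_older_alleles_are_more_frequent(small_dataset):
    pool = small_dataset.pool
    rho = stats.spearmanr(pool.af, pool.age).statistic
    assert rho > 0.3  # frequency rises with age <=> falls with recency


def test_sites_sorted_and_spectrum_rare_heavy(small_dataset):
    pool = small_dataset.pool
    key = pool.chrom.astype(np.int64) * 10**9 + pool.bp
    assert (np.diff(key) > 0).all()
    af = pool.af
    assert (af <= 0.05).mean() > 0.4  # low-frequency-heavy spectrum


def test_tracts_tile_chromosomes_exactly(small_dataset):
    cfg = small_dataset.config
    truth = small_dataset.truth
    for iid in truth.sample_ids[:40]:
        for hap in truth.tracts[iid]:
            for breaks, labels in hap:
                assert breaks[0] == 0.0
                assert breaks[-1] == pytest.approx(cfg.chrom_length_cm)
                assert (np.diff(breaks) > 0).all()
                assert len(labels) == len(breaks) - 1


def test_founder_offspring_has_zero_autozygosity():
    pool = simulate_founders(TINY)
    ped = build_pedigree([("A", "0", "0"), ("B", "0", "0"), ("X", "A", "B")])
    _, truth = gene_drop(ped, pool, np.random.default_rng(0))
    assert true_f(truth)["X"] == 0.0
    assert true_f(truth)["A"] == 0.0


def test_close_mating_truth_expectations():
    """Replicate full-sib and cousin families recover the textbook means.

    Each family draws fresh sib (and cousin) pairs, so the family-mean
    realized autozygosity values are independent draws around 1/4 and 1/16.
    """
    pool = simulate_founders(TINY)
    recs = [(f"F{i}", "0", "0") for i in range(4)]
    fam, kids = 60, 20
    for f in range(fam):
        recs += [(f"S{f}a", "F0", "F1"), (f"S{f}b", "F0", "F1")]
        recs += [(f"FS{f}_{k}", f"S{f}a", f"S{f}b") for k in range(kids)]
        recs += [(f"C{f}a", f"S{f}a", "F2"), (f"C{f}b", f"S{f}b", "F3")]
        recs += [(f"CZ{f}_{k}", f"C{f}a", f"C{f}b") for k in range(kids)]
    ped = build_pedigree(recs)
    _, truth = gene_drop(ped, pool, np.random.default_rng(1))
    tf = true_f(truth)
    for prefix, expect in (("FS", 0.25), ("CZ", 0.0625)):
        fm = np.array([tf[[f"{prefix}{f}_{k}" for k in range(kids)]].mean()
                       for f in range(fam)])
        se = fm.std(ddof=1) / np.sqrt(fam)
        assert abs(fm.mean() - expect) < 3 * se


def test_crossover_count_matches_map_length():
    pool = simulate_founders(TINY)
    recs = [("A", "0", "0"), ("B", "0", "0")]
    n = 700
    recs += [(f"X{k}", "A", "B") for k in range(n)]
    ped = build_pedigree(recs)
    _, truth = gene_drop(ped, pool, np.random.default_rng(2))
    # founder parents carry single-label haplotypes, so every crossover that
    # switches source shows up as a tract boundary; per 1-Morgan chromosome
    # the expected number of boundaries is E[#odd-split crossovers] ~ 1
    counts = [len(hap[c][1]) - 1
              for k in range(n) for hap in truth.tracts[f"X{k}"]
              for c in range(TINY.n_chromosomes)]
    mean = np.mean(counts)
    se = np.std(counts) / np.sqrt(len(counts))
    assert abs(mean - TINY.chrom_length_morgans) < 4 * se


def test_true_f_window_additivity(small_dataset):
    truth = small_dataset.truth
    cfg = small_dataset.config
    w = cfg.chrom_length_bp // 20
    windows = pd.DataFrame([(c, k * w, (k + 1) * w)
                            for c in range(cfg.n_chromosomes) for k in range(20)],
                           columns=["chrom", "start", "end"])
    per_win = true_f_windows(truth, windows)
    genome = true_f(truth)
    np.testing.assert_allclose(per_win.mean(axis=1), genome, atol=1e-9)
    # some window of some inbred individual sits fully inside a shared tract
    assert (per_win.to_numpy() > 1 - 1e-9).any()


def test_pedigree_design_close_matings(rng):
    ped, gens = build_sim_pedigree(SMALL_CONFIG, rng)
    f = inbreeding_pedigree(ped)
    last = gens[max(gens)]
    assert len(last) == SMALL_CONFIG.final_generation_size
    # close matings create substantially inbred offspring; outbred ones exist
    assert (f[last] >= 0.0625).any()
    assert (f[last] < 0.01).any()


def test_ascertainment_rules(small_dataset):
    pool = small_dataset.pool
    idx = small_dataset.array_index
    assert (pool.maf[idx] >= small_dataset.config.array_maf_cutoff).all()
    assert len(idx) == small_dataset.config.array_target
    idx2 = ascertain_array(pool.maf, small_dataset.config.array_maf_cutoff,
                           small_dataset.config.array_target)
    np.testing.assert_array_equal(idx, idx2)  # deterministic
    with pytest.warns(UserWarning):
        few = ascertain_array(pool.maf, 0.49, 10**7)
    assert (pool.maf[few] >= 0.49).all()


def test_annotation_frequency_and_age_tilts(small_dataset):
    ann = small_dataset.annotations.table
    pool = small_dataset.pool
    af = pd.Series(pool.af, index=ann.index)
    mean_af = af.groupby(ann["func_class"]).mean()
    assert mean_af["deleterious_missense"] < mean_af["synonymous"]
    # private alleles are younger on average
    assert (ann.loc[ann.private, "age"].mean()
            < ann.loc[~ann.private, "age"].mean())


def test_all_neutral_annotations_have_matched_spectra(small_dataset):
    rng = np.random.default_rng(0)
    ann = assign_annotations(small_dataset.pool, rng, all_neutral=True).table
    af = small_dataset.pool.af
    a = af[(ann["func_class"] == "deleterious_missense").to_numpy()]
    b = af[(ann["func_class"] == "synonymous").to_numpy()]
    assert stats.ks_2samp(a, b).pvalue > 0.01


def test_genotyping_error_touches_genotypes_not_truth():
    cfg = replace(TINY, genotyping_error=0.05)
    clean = simulate_dataset(TINY)
    noisy = simulate_dataset(cfg)
    assert (clean.wgs.dosages != noisy.wgs.dosages).mean() > 0.02
    pd.testing.assert_series_equal(true_f(clean.truth), true_f(noisy.truth))
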
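import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autozykit.data_io import build_pedigree
from autozykit.evaluation import (correlation_profile, pearson_ci,
                                  predict_offspring_f,
                                  regional_correlation_distribution,
                                  regional_estimators)
from autozykit.simulate import SimConfig, gene_drop, simulate_founders, true_f
from autozykit.snp_estimators import f_grm, f_uni
from autozykit.wgs_metrics import ScoreMatrix, make_windows, window_index


def test_pearson_matches_scipy(rng):
    for _ in range(20):
        n = int(rng.integers(5, 200))
        x, y = rng.normal(size=n), rng.normal(size=n)
        res = pearson_ci(x, y)
        r_ref = stats.pearsonr(x, y).statistic
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.n == n


def test_fisher_interval_closed_form():
    # r = 0 at n = 103: SE(z) = 0.1, CI = tanh(+-1.96 * 0.1)
    x = np.arange(103.0)
    y = np.concatenate([np.ones(51), [0.0], np.ones(51)])  # orthogonal to x - mean
    y = y - np.polyval(np.polyfit(x, y, 1), x) + y.mean()  # force r = 0
    res = pearson_ci(x, y)
    assert res.r == pytest.approx(0.0, abs=1e-12)
    assert res.se == pytest.approx(0.1)
    assert res.ci_lo == pytest.approx(-0.19367, abs=1e-3)
    assert res.ci_hi == pytest.approx(0.19367, abs=1e-3)


def test_degenerate_and_error_cases(rng):
    x = rng.normal(size=50)
    res = pearson_ci(x, 2 * x + 1)
    assert res.r == 1.0 and res.degenerate and res.ci_lo == res.ci_hi == 1.0
    assert pearson_ci(x, -x).r == -1.0
    with pytest.raises(ValueError):
        pearson_ci(x, np.zeros(50))
    with pytest.raises(ValueError):
        pearson_ci([1, 2, 3], [3, 2, 1])
    # missing pairs dropped pairwise
    y = x.copy()
    y[0] = np.nan
    assert pearson_ci(x, y).n == 49


def _scores(values: pd.DataFrame) -> ScoreMatrix:
    meta = pd.DataFrame({"name": values.columns, "excluded": False,
                         "exclude_reason": ""}).set_index("name")
    return ScoreMatrix(values, meta)


def test_correlation_profile_basics(rng):
    f = pd.Series(rng.normal(size=40), index=[f"i{k}" for k in range(40)])
    sm = _scores(pd.DataFrame({"same": f, "noisy": f + rng.normal(size=40),
                               "const": 1.0}, index=f.index))
    prof = correlation_profile(f, sm)
    assert prof.loc["same", "r"] == pytest.approx(1.0)
    assert prof.loc["noisy", "r"] > 0.3
    assert "zero variance" in prof.loc["const", "skip_reason"]


def test_correlation_profile_null_coverage(rng):
    """Permuted scores: the Fisher CI covers 0 at close to nominal rate."""
    n, n_perm = 60, 1000
    f = pd.Series(rng.normal(size=n), index=[f"i{k}" for k in range(n)])
    covered = 0
    for _ in range(n_perm):
        y = f.to_numpy()[rng.permutation(n)]
        res = pearson_ci(f.to_numpy(), y)
        covered += res.ci_lo <= 0.0 <= res.ci_hi
    assert covered / n_perm >= 0.93


def test_regional_estimator_additivity(small_dataset):
    """SNP-count-weighted window F_UNI terms rebuild the genome-wide value."""
    ga = small_dataset.array_matrix()
    reg = regional_estimators(ga, window_bp=5_000_000, min_array_snps=1)
    widx = window_index(ga.snp_meta, reg["windows"].reset_index())
    counts = np.array([len(i) for i in widx], float)
    vals = reg["f_uni"].to_numpy()
    ok = counts > 0
    agg = np.nansum(vals[:, ok] * counts[ok], axis=1) / counts[ok].sum()
    np.testing.assert_allclose(agg, f_uni(ga), atol=1e-10)


def test_regional_correlation_distribution(rng):
    ids = [f"i{k}" for k in range(20)]
    f = pd.DataFrame(rng.normal(size=(20, 30)), index=ids)
    rs, summary = regional_correlation_distribution(f, f.copy())
    assert summary["n_windows"] == 30 and summary["mean"] == pytest.approx(1.0)
    # independent scores: mean r near 0
    g = pd.DataFrame(rng.normal(size=(20, 200)), index=ids)
    h = pd.DataFrame(rng.normal(size=(20, 200)), index=ids)
    _, s0 = regional_correlation_distribution(g, h)
    assert abs(s0["mean"]) < 3 / np.sqrt(20 * 200) * 10
    # windows failing the individual filter are absent
    f2 = f.copy()
    f2.iloc[5:, 0] = np.nan
    rs2, _ = regional_correlation_distribution(f2, f)
    assert f.columns[0] not in rs2.index


def test_predict_offspring_pedigree_mode():
    ped = build_pedigree([("A", "0", "0"), ("B", "0", "0"),
                          ("C", "A", "B"), ("D", "A", "B")])
    assert predict_offspring_f(pedigree=ped, sire_id="C", dam_id="D") == 0.25
    with pytest.raises(ValueError):
        predict_offspring_f(pedigree=ped, sire_id="C")


def test_predict_offspring_identity_pair_consistency(rng):
    p = rng.uniform(0.1, 0.9, 2000)
    x = (rng.random(2000) < p).astype(int) + (rng.random(2000) < p)
    pred = predict_offspring_f(x, x, p)
    fg = f_grm(np.array([x]), p)[0]
    assert pred == pytest.approx(0.5 * (1 + fg), abs=1e-12)


def test_predicted_f_matches_gene_dropped_offspring():
    """Mean realized autozygosity of replicate offspring tracks the genomic
    kinship of the parents: small per-mating error, no systematic bias."""
    cfg = SimConfig(seed=3, n_founder_haplotypes=64, burnin_generations=30,
                    mutation_rate=12.0, n_chromosomes=6,
                    chrom_length_bp=25_000_000, split_generations=10,
                    heldout_pool_size=30, heldout_sample_haplotypes=30,
                    pedigree_founders=16, array_target=500)
    pool = simulate_founders(cfg)
    recs = [(f"F{i}", "0", "0") for i in range(16)]
    matings = []
    for m in range(4):  # four full-sib matings
        recs += [(f"S{m}a", f"F{4 * m}", f"F{4 * m + 1}"),
                 (f"S{m}b", f"F{4 * m}", f"F{4 * m + 1}")]
        matings.append((f"S{m}a", f"S{m}b"))
    matings += [("F0", "F5"), ("F2", "F9")]  # unrelated pairs
    n_rep = 120
    for m, (s, d) in enumerate(matings):
        recs += [(f"O{m}_{k}", s, d) for k in range(n_rep)]
    ped = build_pedigree(recs)
    g, truth = gene_drop(ped, pool, np.random.default_rng(9))
    tf = true_f(truth)
    # base population = founder generation: its frequencies anchor kinship
    af = pool.af
    poly = (af > 0.02) & (af < 0.98)
    diffs = []
    for m, (s, d) in enumerate(matings):
        xs = g.dosages[g.sample_ids.index(s)][poly]
        xd = g.dosages[g.sample_ids.index(d)][poly]
        pred = predict_offspring_f(xs, xd, af[poly])
        realized = tf[[f"O{m}_{k}" for k in range(n_rep)]].mean()
        diffs.append(pred - realized)
        assert abs(pred - realized) < 0.1
    assert abs(np.mean(diffs)) < 0.04  # no systematic bias
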
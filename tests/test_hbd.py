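import numpy as np
import pytest

from autozykit.data_io import MISSING
from autozykit.hbd import (HBDModel, HBDPosterior, f_hbd, fit_mixing,
                           forward_backward, hbd_emission, hbd_transition,
                           sample_hbd_segments, simulate_hbd_genotypes)
from autozykit.snp_estimators import f_ml

from _oracles import hmm_backward_loglik, hmm_path_sum


def test_transition_identity_at_zero_distance():
    m = HBDModel(rates=[5.0, 25.0], pi=[0.2, 0.3, 0.5])
    np.testing.assert_allclose(hbd_transition(m, 0.0), np.eye(3), atol=1e-15)


def test_transition_reaches_stationarity_at_large_distance():
    m = HBDModel(rates=[5.0, 25.0], pi=[0.2, 0.3, 0.5])
    a = hbd_transition(m, 100.0)
    for row in a:
        np.testing.assert_allclose(row, m.pi, atol=1e-12)


def test_transition_persistence_hand_value():
    m = HBDModel(rates=[5.0], pi=[0.5, 0.5])
    a = hbd_transition(m, 0.1)
    stay = np.exp(-0.5)
    assert a[0, 0] == pytest.approx(stay + (1 - stay) * 0.5)
    np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
    with pytest.raises(ValueError):
        hbd_transition(m, -0.1)


def test_emission_hand_values():
    # heterozygote is impossible under HBD without genotyping error
    np.testing.assert_allclose(hbd_emission(1, 0.5, 0.0), [0.0, 0.5])
    # missing genotype carries no information
    np.testing.assert_allclose(hbd_emission(MISSING, 0.3, 0.01, n_hbd=2),
                               np.ones(3))
    # hom-alt at reference frequency 0.7
    np.testing.assert_allclose(hbd_emission(2, 0.7, 0.0), [0.3, 0.09])
    with pytest.raises(ValueError):
        hbd_emission(0, 1.0, 0.0)
    # each class's three genotype probabilities sum to one
    tot = sum(hbd_emission(g, 0.3, 0.02) for g in (0, 1, 2))
    np.testing.assert_allclose(tot, 1.0, atol=1e-12)


def _random_instance(rng, S, K):
    model = HBDModel(rates=np.sort(rng.uniform(1, 50, K)),
                     pi=rng.dirichlet(np.ones(K + 1)),
                     err=0.01)
    d = rng.integers(0, 3, S).astype(np.int8)
    d[rng.random(S) < 0.15] = MISSING
    freqs = rng.uniform(0.1, 0.9, S)
    cm = np.sort(rng.uniform(0, 50, S))
    return model, d, freqs, cm


def _oracle_parts(model, d, freqs, cm):
    b = np.stack([hbd_emission(g, 1 - p, model.err, model.n_hbd)
                  for g, p in zip(d, freqs)])
    trans = [hbd_transition(model, (cm[t] - cm[t - 1]) / 100.0)
             for t in range(1, len(d))]
    return b, trans


def test_forward_backward_matches_exhaustive_path_sum(rng):
    """Posteriors and likelihood equal brute-force path enumeration."""
    for _ in range(12):
        S = int(rng.integers(1, 9))
        K = int(rng.integers(1, 4))
        model, d, freqs, cm = _random_instance(rng, S, K)
        post = forward_backward(d, freqs, cm, np.zeros(S), model)
        b, trans = _oracle_parts(model, d, freqs, cm)
        like, gamma = hmm_path_sum(b, trans, model.pi)
        np.testing.assert_allclose(post.gamma, gamma, atol=1e-10)
        assert post.loglik[0] == pytest.approx(np.log(like), abs=1e-10)
        # likelihood from an independent backward recursion agrees too
        assert post.loglik[0] == pytest.approx(
            hmm_backward_loglik(b, trans, model.pi), rel=1e-8)


def test_posteriors_normalized_per_snp(rng):
    model = HBDModel()
    d = rng.integers(0, 3, (4, 300)).astype(np.int8)
    freqs = rng.uniform(0.1, 0.9, 300)
    cm = np.sort(rng.uniform(0, 100, 300))
    chrom = np.repeat([0, 1, 2], 100)
    post = forward_backward(d, freqs, cm, chrom, model)
    np.testing.assert_allclose(post.gamma.sum(axis=-1), 1.0, atol=1e-10)


def test_single_snp_posterior_is_weighted_emission():
    model = HBDModel(rates=[10.0], pi=[0.3, 0.7], err=0.0)
    post = forward_backward(np.array([2], dtype=np.int8), [0.4], [0.0], [0],
                            model)
    b = hbd_emission(2, 0.6, 0.0)
    expect = model.pi * b / (model.pi * b).sum()
    np.testing.assert_allclose(post.gamma[0], expect, atol=1e-12)


def test_all_het_chromosome_has_no_hbd():
    model = HBDModel(err=0.0)
    S = 200
    post = forward_backward(np.ones(S, dtype=np.int8), np.full(S, 0.5),
                            np.arange(S) * 0.5, np.zeros(S), model)
    assert post.total_hbd.max() < 1e-12


def test_em_fully_heterozygous_drives_non_hbd_to_one():
    S = 300
    pi, post, hist = fit_mixing(np.ones(S, dtype=np.int8), np.full(S, 0.5),
                                np.arange(S) * 0.5, np.zeros(S),
                                rates=(5.0, 25.0), err=0.0, max_iter=200)
    assert pi[0, -1] == pytest.approx(1.0, abs=1e-9)
    assert float(f_hbd(post)) == pytest.approx(0.0, abs=1e-9)


def test_em_loglik_monotone_on_random_data(rng):
    for _ in range(5):
        d = rng.integers(0, 3, (3, 150)).astype(np.int8)
        freqs = rng.uniform(0.1, 0.9, 150)
        cm = np.sort(rng.uniform(0, 120, 150))
        _, _, hist = fit_mixing(d, freqs, cm, np.zeros(150), max_iter=40)
        assert (np.diff(hist) >= -1e-8).all()


def test_em_recovers_simulated_hbd_mass(rng):
    """Fitting model-simulated data recovers the total HBD fraction."""
    model = HBDModel(rates=[20.0], pi=[0.3, 0.7], err=0.002)
    S_per = 400
    cm, chrom, freqs = [], [], []
    for c in range(10):
        cm.append(np.sort(rng.uniform(0, 100, S_per)))
        chrom.append(np.full(S_per, c))
        freqs.append(rng.uniform(0.1, 0.9, S_per))
    cm, chrom, freqs = map(np.concatenate, (cm, chrom, freqs))
    d, states = simulate_hbd_genotypes(model, cm, chrom, freqs, rng)
    true_frac = (states < 1).mean()
    _, post, _ = fit_mixing(d, freqs, cm, chrom, rates=(20.0,), err=0.002,
                            max_iter=200, tol=1e-8)
    assert float(f_hbd(post)) == pytest.approx(true_frac, abs=0.05)


def test_f_hbd_partitions_add_up(rng):
    gamma = rng.dirichlet(np.ones(5), size=(3, 50))
    post = HBDPosterior(gamma=gamma, loglik=np.zeros(3),
                        rates=np.array([5.0, 25.0, 125.0, 525.0]))
    total = f_hbd(post)
    parts = sum(f_hbd(post, [k]) for k in range(4))
    np.testing.assert_allclose(parts, total, atol=1e-12)
    np.testing.assert_allclose(f_hbd(post), 1 - gamma[..., -1].mean(axis=-1))
    with pytest.raises(ValueError):
        f_hbd(post, [])


def test_all_hbd_posterior_gives_one():
    gamma = np.zeros((1, 10, 2))
    gamma[..., 0] = 1.0
    post = HBDPosterior(gamma, np.zeros(1), np.array([5.0]))
    assert f_hbd(post)[0] == 1.0


def test_independent_snp_limit_equals_ml_mixture(rng):
    """With one HBD class and infinite marker spacing, the HMM's F_HBD
    coincides with the two-component ML mixture estimate."""
    S = 300
    p = rng.uniform(0.1, 0.9, S)
    cm = np.arange(S) * 1e6  # effectively independent markers
    worst = 0.0
    d = np.empty((10, S), dtype=np.int8)
    for i in range(10):
        F = rng.uniform(0, 0.5)
        ibd = rng.random(S) < F
        a1 = rng.random(S) < p
        a2 = np.where(ibd, a1, rng.random(S) < p)
        d[i] = a1.astype(np.int8) + a2.astype(np.int8)
    fml = f_ml(d, p, eps=0.001, tol=1e-9)
    _, post, _ = fit_mixing(d, p, cm, np.zeros(S), rates=(1.0,), err=0.001,
                            max_iter=5000, tol=1e-12)
    np.testing.assert_allclose(f_hbd(post), fml, atol=1e-4)


def test_segment_sampler_mean_length(rng):
    """Generated HBD segment lengths average 1/R Morgans."""
    R = 25.0
    model = HBDModel(rates=[R], pi=[0.5, 0.5])
    segs = sample_hbd_segments(model, [120.0 / R] * 10, rng)
    done = segs[(segs.state == 0) & ~segs.censored]
    lengths = (done.end_m - done.start_m).to_numpy()
    assert len(lengths) > 200
    assert lengths.mean() == pytest.approx(1.0 / R, rel=0.1)
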
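"""Multi-class homozygous-by-descent (HBD) hidden Markov model.

The chain has K HBD classes with fixed rates R_1 < ... < R_K (per Morgan)
plus one non-HBD class sharing rate R_K.  Segments of class k have
exponential length with mean 1/R_k Morgans; a class with rate R_k
corresponds to ancestors roughly 0.5 * R_k generations back.  Between
markers separated by d Morgans the chain stays in its current state with
probability exp(-R_state * d) and otherwise resets to a state drawn from the
mixing coefficients pi, so the transition matrix is

    a(k, l) = exp(-R_k d) * [k == l] + (1 - exp(-R_k d)) * pi_l.

Emissions are the same two-component model as the single-individual ML
estimator: HBD classes emit genotypes from the autozygous distribution (with
genotyping-error rate eps), the non-HBD class from Hardy-Weinberg
proportions.  Chromosomes are independent: the chain restarts from pi at the
first marker of each chromosome.

Rates are never estimated; only pi is fitted, per individual, by Baum-Welch
EM whose M-step uses the expected reset counts of the full chain.  F_HBD is
the posterior probability of being in any HBD class averaged over markers;
per-class partitions sum to the total.

Numerical scheme: per-marker scaling constants (no log space); the forward
scaling factors give the log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import MISSING
from .snp_estimators import mixture_components

DEFAULT_RATES = (5.0, 25.0, 125.0, 525.0)
_PI_FLOOR = 1e-12


@dataclass
class HBDModel:
    """Fixed rate vector, mixing coefficients and genotyping-error rate."""

    rates: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_RATES))
    pi: np.ndarray | None = None
    err: float = 0.001

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if (np.diff(self.rates) <= 0).any() or (self.rates <= 0).any():
            raise ValueError("rates must be positive and strictly increasing")
        if not 0.0 <= self.err <= 0.1:
            raise ValueError("err must lie in [0, 0.1]")
        if self.pi is None:
            self.pi = np.full(self.n_states, 1.0 / self.n_states)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (self.n_states,) or (self.pi < 0).any():
            raise ValueError("pi must be a non-negative vector over K+1 classes")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")

    @property
    def n_hbd(self) -> int:
        return len(self.rates)

    @property
    def n_states(self) -> int:
        return len(self.rates) + 1

    @property
    def state_rates(self) -> np.ndarray:
        """Per-state rates; the non-HBD class shares the largest HBD rate."""
        return np.append(self.rates, self.rates[-1])


@dataclass
class HBDPosterior:
    """Locus-resolved posterior state probabilities for one or more individuals.

    ``gamma`` has shape (n_individuals, n_snps, K+1); HBD classes come first,
    the non-HBD class is last.  ``loglik`` is per individual.
    """

    gamma: np.ndarray
    loglik: np.ndarray
    rates: np.ndarray

    @property
    def n_hbd(self) -> int:
        return len(self.rates)

    @property
    def total_hbd(self) -> np.ndarray:
        """Per-SNP probability of being in any HBD class, (n, S)."""
        return self.gamma[..., : self.n_hbd].sum(axis=-1)


def hbd_transition(model: HBDModel, d: float) -> np.ndarray:
    """(K+1) x (K+1) stochastic matrix for an inter-marker distance d (Morgans)."""
    if d < 0:
        raise ValueError("inter-marker distance must be non-negative")
    e = np.exp(-model.state_rates * d)
    return np.diag(e) + (1.0 - e)[:, None] * model.pi[None, :]


def hbd_emission(genotype: int, p: float, eps: float, n_hbd: int = 1) -> np.ndarray:
    """Emission probabilities per class for one genotype.

    ``p`` is the *reference*-allele frequency (q = 1 - p is the alternate).
    HBD classes emit (p(1-eps) + eps p^2, eps 2pq, q(1-eps) + eps q^2) for
    (hom-ref, het, hom-alt); the non-HBD class emits Hardy-Weinberg
    proportions.  A missing genotype is uninformative (all ones).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    if genotype == MISSING:
        return np.ones(n_hbd + 1)
    d = np.array([[genotype]], dtype=np.int8)
    q_alt = np.array([1.0 - p])
    ibd, hwe = mixture_components(d, q_alt, eps)
    return np.append(np.full(n_hbd, ibd[0, 0]), hwe[0, 0])


# ---------------------------------------------------------------------------
# Forward-backward machinery (vectorized across individuals)
# ---------------------------------------------------------------------------


def _prepare(dosages, freqs, cm, chrom, model):
    d = np.asarray(dosages)
    one = d.ndim == 1
    if one:
        d = d[None, :]
    p_alt = np.asarray(freqs, dtype=float)
    cm = np.asarray(cm, dtype=float)
    chrom = np.asarray(chrom)
    S = d.shape[1]
    if not (len(p_alt) == len(cm) == len(chrom) == S):
        raise ValueError("freqs, cm and chrom must match the number of SNPs")
    if ((p_alt <= 0) | (p_alt >= 1)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    start = np.zeros(S, dtype=bool)
    start[0] = True
    start[1:] = chrom[1:] != chrom[:-1]
    dist = np.zeros(S)
    dist[1:] = (cm[1:] - cm[:-1]) / 100.0
    if (dist[~start] < 0).any():
        raise ValueError("cM positions must be non-decreasing within chromosome")
    dist[start] = 0.0
    ibd, hwe = mixture_components(d, p_alt, model.err)
    K = model.n_hbd
    b = np.empty(d.shape + (K + 1,))
    b[..., :K] = ibd[..., None]
    b[..., K] = hwe
    # per-state persistence exp(-R_s * d_t); forced reset at chromosome starts
    e = np.exp(-np.outer(dist, model.state_rates))
    e[start] = 0.0
    return d, b, e, start, one


def _forward(b, e, pi, start):
    n, S, M = b.shape
    pi = np.broadcast_to(pi, (n, M))
    alpha = np.empty((S, n, M))
    c = np.empty((S, n))
    prev = np.zeros((n, M))
    for t in range(S):
        if start[t]:
            pred = pi
        else:
            reset = (prev * (1.0 - e[t])).sum(axis=1)
            pred = prev * e[t] + reset[:, None] * pi
        num = pred * b[:, t]
        c[t] = num.sum(axis=1)
        if (c[t] <= 0).any() or not np.isfinite(c[t]).all():
            bad = int(np.flatnonzero((c[t] <= 0) | ~np.isfinite(c[t]))[0])
            raise FloatingPointError(
                f"non-finite likelihood at SNP index {t} (individual {bad})")
        alpha[t] = num / c[t][:, None]
        prev = alpha[t]
    return alpha, c


def forward_backward(dosages, freqs, cm, chrom, model: HBDModel,
                     pi=None) -> HBDPosterior:
    """Scaled forward-backward posteriors for one or more individuals.

    ``dosages`` is (S,) or (n, S); ``freqs`` are alternate-allele
    frequencies; ``cm`` map positions (cM / 100 = Morgans); ``chrom`` labels
    delimit independently restarted chromosomes.  ``pi`` may be (K+1,) shared
    or (n, K+1) per individual (defaults to ``model.pi``).
    """
    d, b, e, start, one = _prepare(dosages, freqs, cm, chrom, model)
    pi = model.pi if pi is None else np.asarray(pi, dtype=float)
    gamma, loglik, _ = _fb_pass(b, e, pi, start)
    if one:
        gamma = gamma[0]
    return HBDPosterior(gamma=gamma, loglik=np.atleast_1d(loglik), rates=model.rates)


def _fb_pass(b, e, pi, start, want_reset=False):
    """One forward-backward sweep.

    Returns (gamma, loglik, rho_sum) where rho_sum (n, K+1) accumulates the
    expected reset counts landing in each state (the Baum-Welch sufficient
    statistic for pi), computed only when ``want_reset``.
    """
    n, S, M = b.shape
    pi = np.broadcast_to(pi, (n, M))
    alpha, c = _forward(b, e, pi, start)
    loglik = np.log(c).sum(axis=0)
    beta = np.ones((n, M))
    gamma = np.empty((n, S, M))
    gamma[:, S - 1] = alpha[S - 1] * beta
    rho_sum = np.zeros((n, M)) if want_reset else None
    for t in range(S - 1, 0, -1):
        u = b[:, t] * beta                       # (n, M)
        pi_u = (pi * u).sum(axis=1)              # (n,)
        if want_reset:
            if start[t]:
                rho = gamma[:, t]
            else:
                r = (alpha[t - 1] * (1.0 - e[t])).sum(axis=1)
                rho = (r / c[t])[:, None] * pi * u
            rho_sum += rho
        if start[t]:
            beta = (pi_u / c[t])[:, None] * np.ones((n, M))
        else:
            beta = (e[t] * u + (1.0 - e[t]) * pi_u[:, None]) / c[t][:, None]
        gamma[:, t - 1] = alpha[t - 1] * beta
    if want_reset:
        rho_sum += gamma[:, 0]                   # the t=0 restart
    return gamma, loglik, rho_sum


def fit_mixing(dosages, freqs, cm, chrom, rates=DEFAULT_RATES, err: float = 0.001,
               max_iter: int = 100, tol: float = 1e-4, pi0=None):
    """Baum-Welch EM for the mixing coefficients (rates stay fixed).

    Fits one pi vector per individual.  Stops when every individual's
    log-likelihood improves by less than ``tol`` or after ``max_iter``
    iterations.  Returns ``(pi, posterior, history)`` where ``pi`` is
    (n, K+1), ``posterior`` the final :class:`HBDPosterior` and ``history``
    the per-iteration total log-likelihood (non-decreasing).
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    model = HBDModel(rates=np.asarray(rates, float), err=err)
    d, b, e, start, one = _prepare(dosages, freqs, cm, chrom, model)
    n, S, M = b.shape
    pi = (np.full((n, M), 1.0 / M) if pi0 is None
          else np.broadcast_to(np.asarray(pi0, float), (n, M)).copy())
    history: list[float] = []
    prev = np.full(n, -np.inf)
    for _ in range(max_iter):
        gamma, loglik, rho = _fb_pass(b, e, pi, start, want_reset=True)
        history.append(float(loglik.sum()))
        new_pi = np.maximum(rho, _PI_FLOOR)
        pi = new_pi / new_pi.sum(axis=1, keepdims=True)
        if np.all(loglik - prev < tol):
            break
        prev = loglik
    gamma, loglik, _ = _fb_pass(b, e, pi, start)
    post = HBDPosterior(gamma=gamma[0] if one else gamma,
                        loglik=loglik, rates=model.rates)
    return pi, post, history


def f_hbd(post: HBDPosterior, classes=None) -> np.ndarray:
    """Genome-averaged posterior HBD probability.

    ``classes`` selects a subset of HBD classes by index (0-based, ordered by
    rate); the default uses all of them, which is the full F_HBD.
    """
    if classes is None:
        classes = list(range(post.n_hbd))
    classes = list(classes)
    if not classes:
        raise ValueError("empty HBD class subset")
    if any(c < 0 or c >= post.n_hbd for c in classes):
        raise ValueError("class index outside the HBD classes")
    sel = post.gamma[..., classes].sum(axis=-1)
    return sel.mean(axis=-1)


# ---------------------------------------------------------------------------
# Generative sampling (the model's own simulator, used to test recovery)
# ---------------------------------------------------------------------------


def sample_hbd_segments(model: HBDModel, chrom_lengths_m, rng) -> pd.DataFrame:
    """Sample the segment process on chromosomes of given lengths (Morgans).

    The process draws a state from pi, a sojourn from Exp(rate of the state),
    and repeats; each draw is recorded as one segment (self-transitions give
    adjacent segments of the same class, matching the event-process
    semantics of the chain).  Columns: chrom, start_m, end_m, state,
    censored (cut by the chromosome end).
    """
    rates = model.state_rates
    rows = []
    for ci, L in enumerate(np.atleast_1d(chrom_lengths_m)):
        pos = 0.0
        while pos < L:
            s = int(rng.choice(model.n_states, p=model.pi))
            length = rng.exponential(1.0 / rates[s])
            end = min(pos + length, L)
            rows.append((ci, pos, end, s, pos + length > L))
            pos = end
    return pd.DataFrame(rows, columns=["chrom", "start_m", "end_m", "state",
                                       "censored"])


def simulate_hbd_genotypes(model: HBDModel, cm, chrom, alt_freqs, rng):
    """Sample marker states and genotypes from the model's generative process.

    Returns (dosages, states) at the marker positions ``cm`` (within
    chromosomes labelled by ``chrom``), with emissions drawn from the same
    distributions the HMM assumes.
    """
    cm = np.asarray(cm, float)
    chrom = np.asarray(chrom)
    q = np.asarray(alt_freqs, float)
    states = np.empty(len(cm), dtype=np.int64)
    for c in pd.unique(chrom):
        m = chrom == c
        length = (cm[m].max() - cm[m].min()) / 100.0 + 1e-9
        segs = sample_hbd_segments(model, [length], rng)
        pos_m = (cm[m] - cm[m].min()) / 100.0
        idx = np.searchsorted(segs["end_m"].to_numpy(), pos_m, side="right")
        idx = np.minimum(idx, len(segs) - 1)
        states[m] = segs["state"].to_numpy()[idx]
    hbd = states < model.n_hbd
    p_ref = 1.0 - q
    e = model.err
    probs_ibd = np.stack([p_ref * (1 - e) + e * p_ref ** 2,
                          e * 2 * p_ref * q,
                          q * (1 - e) + e * q ** 2], axis=1)
    probs_hwe = np.stack([p_ref ** 2, 2 * p_ref * q, q ** 2], axis=1)
    probs = np.where(hbd[:, None], probs_ibd, probs_hwe)
    u = rng.random(len(cm))
    cum = probs.cumsum(axis=1)
    dos = (u[:, None] > cum).sum(axis=1).astype(np.int8)
    return dos, states
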
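"""SNP-by-SNP genomic inbreeding estimators: F_HOM, F_UNI, F_GRM, F_ML.

All estimators work on alternate-allele dosages x in {0,1,2} with per-SNP
alternate frequencies p (q = 1 - p).  Missing genotypes are excluded SNP-wise
from every sum, so each individual is evaluated on its own non-missing SNP
set.  F_HOM, F_UNI and F_GRM are moment estimators that may be negative;
F_ML is a maximum-likelihood mixture estimate constrained to [0, 1].

F_ML models the genotypes of one individual as a mixture of an autozygous
(IBD) and an allozygous (Hardy-Weinberg) component.  With genotyping-error
rate eps, the IBD component emits hom-ref / het / hom-alt with probabilities
(1-p)(1-eps) + eps(1-p)^2, eps*2p(1-p), p(1-eps) + eps*p^2; the allozygous
component uses Hardy-Weinberg proportions.  The likelihood is unimodal in F,
so a bounded scalar search finds the maximum; an EM iteration is provided as
an independent cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar

from .data_io import MISSING, GenotypeMatrix


def _as_parts(g, freqs):
    if isinstance(g, GenotypeMatrix):
        d = g.dosages
        p = g.af if freqs is None else np.asarray(freqs, float)
    else:
        d = np.asarray(g)
        if freqs is None:
            raise ValueError("freqs is required when passing a raw dosage array")
        p = np.asarray(freqs, float)
    if d.ndim == 1:
        d = d[None, :]
    return d, p


def _check_polymorphic(p, ok):
    used = ok.any(axis=0)
    if ((p <= 0) | (p >= 1))[used].any():
        raise ValueError("monomorphic SNP reached an estimator; filter upstream")


def f_hom(g, freqs=None) -> np.ndarray:
    """Excess-of-homozygosity moment estimator (O - E) / (L - E)."""
    d, p = _as_parts(g, freqs)
    ok = d != MISSING
    hom = ok & ((d == 0) | (d == 2))
    e_snp = 1.0 - 2.0 * p * (1.0 - p)
    O = hom.sum(axis=1)
    E = (ok * e_snp).sum(axis=1)
    L = ok.sum(axis=1)
    denom = L - E
    if (np.abs(denom) < 1e-12).any():
        raise ValueError("F_HOM undefined: expected homozygosity equals SNP count "
                         "(all usable SNPs monomorphic?)")
    return (O - E) / denom


def _uni_contributions(d, p):
    """Per-genotype F_UNI terms [x^2 - (1+2p)x + 2p^2] / (2pq); 0 where missing."""
    ok = d != MISSING
    x = np.where(ok, d, 0).astype(float)
    num = x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p
    with np.errstate(divide="ignore", invalid="ignore"):
        term = num / (2.0 * p * (1.0 - p))
    return np.where(ok, term, 0.0), ok


def f_uni(g, freqs=None, per_snp: bool = False):
    """Correlation-between-uniting-gametes estimator (mean of per-SNP terms).

    With ``per_snp=True`` also returns the per-SNP contribution matrix
    (zeros at missing genotypes) for regional aggregation.
    """
    d, p = _as_parts(g, freqs)
    term, ok = _uni_contributions(d, p)
    _check_polymorphic(p, ok)
    L = ok.sum(axis=1)
    if (L == 0).any():
        raise ValueError("individual with no non-missing genotypes")
    f = term.sum(axis=1) / L
    return (f, term) if per_snp else f


def f_grm(g, freqs=None, variant: str = "vanraden1") -> np.ndarray:
    """GRM-diagonal estimator.

    ``vanraden1``: sum_i (x - 2p)^2 / (2 * sum_i p q) - 1 (ratio of sums,
    VanRaden's first method).  ``per_snp``: mean_i (x - 2p)^2 / (2pq) - 1
    (GCTA-style equal SNP weighting).
    """
    d, p = _as_parts(g, freqs)
    ok = d != MISSING
    _check_polymorphic(p, ok)
    x = np.where(ok, d, 0).astype(float)
    dev2 = np.where(ok, (x - 2.0 * p) ** 2, 0.0)
    pq = p * (1.0 - p)
    if variant == "vanraden1":
        denom = 2.0 * (ok * pq).sum(axis=1)
        if (denom <= 0).any():
            raise ValueError("zero denominator in F_GRM (no polymorphic SNPs)")
        return dev2.sum(axis=1) / denom - 1.0
    if variant == "per_snp":
        with np.errstate(divide="ignore", invalid="ignore"):
            term = dev2 / (2.0 * pq)
        L = ok.sum(axis=1)
        return np.where(ok, term, 0.0).sum(axis=1) / L - 1.0
    raise ValueError(f"unknown F_GRM variant: {variant}")


# ---------------------------------------------------------------------------
# F_ML: two-component mixture maximum likelihood
# ---------------------------------------------------------------------------


def mixture_components(d: np.ndarray, p: np.ndarray, eps: float):
    """Per-genotype emission probabilities (IBD component, HWE component).

    Missing genotypes get probability 1 in both components (uninformative).
    """
    if not 0.0 <= eps <= 0.1:
        raise ValueError("eps must lie in [0, 0.1]")
    q = p            # alternate-allele frequency
    r = 1.0 - p      # reference-allele frequency
    ibd_by_gt = np.stack([r * (1 - eps) + eps * r * r,
                          eps * 2 * r * q,
                          q * (1 - eps) + eps * q * q])
    hwe_by_gt = np.stack([r * r, 2 * r * q, q * q])
    ok = d != MISSING
    idx = np.where(ok, d, 0)
    cols = np.arange(d.shape[-1])  # ibd_by_gt is (3, n_snps)
    ibd = np.where(ok, ibd_by_gt[idx, cols], 1.0)
    hwe = np.where(ok, hwe_by_gt[idx, cols], 1.0)
    return ibd, hwe


def f_ml(g, freqs=None, eps: float = 0.001, tol: float = 1e-6,
         method: str = "bounded") -> np.ndarray:
    """Single-individual ML mixture estimate of F in [0, 1].

    ``method='bounded'`` maximizes the log-likelihood by bounded scalar
    search (the likelihood is unimodal in F); ``method='em'`` runs EM to the
    same tolerance.  Estimates within ``tol`` of a boundary are snapped to
    the exact boundary value.
    """
    one = not isinstance(g, GenotypeMatrix) and np.ndim(g) == 1
    d, p = _as_parts(g, freqs)
    if (np.asarray(d != MISSING).sum(axis=1) == 0).any():
        raise ValueError("individual with no non-missing genotypes")
    ibd, hwe = mixture_components(d, p, eps)
    out = np.empty(d.shape[0])
    for i in range(d.shape[0]):
        if method == "bounded":
            out[i] = _ml_bounded(ibd[i], hwe[i], tol)
        elif method == "em":
            out[i] = _ml_em(ibd[i], hwe[i], tol)
        else:
            raise ValueError(f"unknown method: {method}")
    snapped = np.where(out < tol, 0.0, np.where(out > 1 - tol, 1.0, out))
    return float(snapped[0]) if one else snapped


def _loglik(F, ibd, hwe):
    mix = F * ibd + (1.0 - F) * hwe
    if (mix <= 0).any():
        return -np.inf
    return float(np.log(mix).sum())


def _ml_bounded(ibd, hwe, tol):
    res = minimize_scalar(lambda F: -_loglik(F, ibd, hwe),
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol * 0.1})
    best = float(res.x)
    # the bounded search can stall short of a boundary optimum
    for edge in (0.0, 1.0):
        if _loglik(edge, ibd, hwe) > -res.fun:
            best = edge
    return best


def _ml_em(ibd, hwe, tol, max_iter: int = 10_000):
    F = 0.5
    prev = -np.inf
    for _ in range(max_iter):
        mix = F * ibd + (1.0 - F) * hwe
        ll = float(np.log(mix).sum())
        resp = np.divide(F * ibd, mix, out=np.zeros_like(mix), where=mix > 0)
        F = float(resp.mean())
        if ll - prev < tol * 1e-4:
            break
        prev = ll
    return F


def estimate_all(g: GenotypeMatrix, freqs=None, eps: float = 0.001,
                 grm_variant: str = "vanraden1"):
    """Convenience: F_HOM, F_UNI, F_GRM, F_ML for every individual."""
    import pandas as pd

    return pd.DataFrame(
        {
            "f_hom": f_hom(g, freqs),
            "f_uni": f_uni(g, freqs),
            "f_grm": f_grm(g, freqs, variant=grm_variant),
            "f_ml": f_ml(g, freqs, eps=eps),
        },
        index=g.sample_ids,
    )
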
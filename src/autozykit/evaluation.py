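"""Comparison layer: correlations with Fisher-transform intervals, regional
estimator computation, per-window correlation distributions, and offspring
inbreeding prediction from parental genotypes.

Pearson correlations are computed on pairwise-complete observations; their
confidence intervals use the Fisher transformation z = atanh(r) with
SE(z) = 1 / sqrt(n - 3) and the fixed 1.96 multiplier for 95% coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeMatrix, Pedigree
from .pedigree import kinship
from .snp_estimators import f_grm, f_uni
from .wgs_metrics import MB, ScoreMatrix, make_windows, window_index


@dataclass
class CorrelationResult:
    r: float
    n: int
    z: float
    se: float
    ci_lo: float
    ci_hi: float
    degenerate: bool = False


def pearson_ci(x, y) -> CorrelationResult:
    """Sample Pearson r with a Fisher-transform 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(1.0, max(-1.0, r))
    se = 1.0 / np.sqrt(n - 3)
    if abs(r) >= 1.0 - 1e-12:
        return CorrelationResult(r, n, np.inf * np.sign(r), se, r, r,
                                 degenerate=True)
    z = np.arctanh(r)
    lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
    return CorrelationResult(r, n, float(z), se, float(lo), float(hi))


def correlation_profile(f: pd.Series, scores: ScoreMatrix) -> pd.DataFrame:
    """One CorrelationResult per score column (skips flagged/degenerate columns).

    ``f`` is indexed by individual id; only individuals present in both are
    used.  Columns marked excluded, with too few overlapping individuals or
    with zero variance are reported with a ``skip_reason``.
    """
    rows = []
    for col in scores.columns:
        meta = scores.meta.loc[col]
        y = scores.values[col]
        common = f.index.intersection(y.index)
        rec = {"column": col, "r": np.nan, "n": 0, "ci_lo": np.nan,
               "ci_hi": np.nan, "skip_reason": ""}
        if bool(meta.get("excluded", False)):
            rec["skip_reason"] = f"excluded: {meta.get('exclude_reason', '')}"
        else:
            xv, yv = f.loc[common].to_numpy(float), y.loc[common].to_numpy(float)
            okn = int((np.isfinite(xv) & np.isfinite(yv)).sum())
            if okn < 4:
                rec["skip_reason"] = "fewer than 4 overlapping individuals"
            else:
                try:
                    res = pearson_ci(xv, yv)
                    rec.update(r=res.r, n=res.n, ci_lo=res.ci_lo,
                               ci_hi=res.ci_hi)
                except ValueError as exc:
                    rec["skip_reason"] = str(exc)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("column")


# ---------------------------------------------------------------------------
# Regional estimators
# ---------------------------------------------------------------------------


def regional_estimators(
    g_array: GenotypeMatrix,
    hbd_total_posterior: np.ndarray | None = None,
    roh_status: np.ndarray | None = None,
    window_bp: int = MB,
    min_array_snps: int = 5,
    freqs=None,
) -> dict[str, pd.DataFrame]:
    """Per-individual x per-window F_UNI, F_GRM and (optionally) F_HBD, F_ROH.

    F_UNI / F_GRM are computed from the array SNPs inside each window;
    ``hbd_total_posterior`` and ``roh_status`` are (n_individuals, n_snps)
    matrices aligned to ``g_array`` whose window means give F_HBD and F_ROH.
    Windows with fewer than ``min_array_snps`` SNPs are NaN.
    """
    windows = make_windows(g_array.snp_meta, window_bp)
    idx_lists = window_index(g_array.snp_meta, windows)
    p = g_array.af if freqs is None else np.asarray(freqs, float)
    names = [f"{w.chrom}:{w.start // window_bp}" for w in windows.itertuples()]
    n = g_array.n_individuals
    out = {k: np.full((n, len(windows)), np.nan)
           for k in ("f_uni", "f_grm", "f_hbd", "f_roh")}
    _, uni_terms = f_uni(g_array, p, per_snp=True)
    for j, idx in enumerate(idx_lists):
        if len(idx) < min_array_snps:
            continue
        sub = g_array.subset_snps(idx)
        ok = sub.dosages != MISSING
        L = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            out["f_uni"][:, j] = np.where(L > 0,
                                          uni_terms[:, idx].sum(axis=1) /
                                          np.maximum(L, 1), np.nan)
        out["f_grm"][:, j] = f_grm(sub, p[idx], variant="vanraden1")
        if hbd_total_posterior is not None:
            out["f_hbd"][:, j] = hbd_total_posterior[:, idx].mean(axis=1)
        if roh_status is not None:
            out["f_roh"][:, j] = roh_status[:, idx].mean(axis=1)
    frames = {k: pd.DataFrame(v, index=g_array.sample_ids, columns=names)
              for k, v in out.items()}
    if hbd_total_posterior is None:
        frames.pop("f_hbd")
    if roh_status is None:
        frames.pop("f_roh")
    frames["windows"] = windows.assign(name=names).set_index("name")
    return frames


def regional_correlation_distribution(
    regional_f: pd.DataFrame,
    regional_scores: pd.DataFrame,
    min_individuals: int = 8,
) -> tuple[pd.Series, dict]:
    """Per-window Pearson r between a regional estimator and a regional score.

    Both frames are individuals x windows with matching columns.  Windows
    with fewer than ``min_individuals`` complete pairs or zero variance are
    dropped.  Returns the per-window r values and a summary (mean and
    quartiles over windows).
    """
    rs = {}
    for col in regional_f.columns.intersection(regional_scores.columns):
        x = regional_f[col].to_numpy(float)
        y = regional_scores[col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < max(min_individuals, 4):
            continue
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            continue
        rs[col] = pearson_ci(x[ok], y[ok]).r
    rs = pd.Series(rs, name="r")
    if len(rs):
        q1, med, q3 = np.percentile(rs, [25, 50, 75])
        summary = {"n_windows": len(rs), "mean": float(rs.mean()),
                   "q1": float(q1), "median": float(med), "q3": float(q3)}
    else:
        summary = {"n_windows": 0, "mean": np.nan, "q1": np.nan,
                   "median": np.nan, "q3": np.nan}
    return rs, summary


# ---------------------------------------------------------------------------
# Offspring prediction
# ---------------------------------------------------------------------------


def predict_offspring_f(sire_dosages=None, dam_dosages=None, freqs=None,
                        pedigree: Pedigree | None = None,
                        sire_id: str | None = None,
                        dam_id: str | None = None) -> float:
    """Predicted inbreeding of a hypothetical offspring of two parents.

    Genomic mode (dosage vectors + frequencies): half the VanRaden
    relationship of the pair, sum((x_s - 2p)(x_d - 2p)) / (2 sum(2pq)) * 2
    ... i.e. F_pred = sum((x_s-2p)(x_d-2p)) / (4 sum(pq)).  Pedigree mode:
    the Malecot kinship of the two parents.
    """
    if pedigree is not None:
        if sire_id is None or dam_id is None:
            raise ValueError("pedigree mode needs sire_id and dam_id")
        return kinship(pedigree, sire_id, dam_id)
    if sire_dosages is None or dam_dosages is None or freqs is None:
        raise ValueError("genomic mode needs both parents' dosages and freqs")
    xs = np.asarray(sire_dosages, float)
    xd = np.asarray(dam_dosages, float)
    p = np.asarray(freqs, float)
    ok = (xs >= 0) & (xd >= 0)
    num = ((xs - 2 * p) * (xd - 2 * p))[ok].sum()
    den = 2.0 * (p * (1 - p))[ok].sum()
    if den <= 0:
        raise ValueError("zero denominator (no polymorphic SNPs)")
    return float(num / den / 2.0)
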
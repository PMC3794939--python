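"""Kinship statistics: regression relatedness and effective mating frequency.

The regression relatedness estimator compares, over all within-colony
pairs, how much more often pair members share alleles than expected from
population frequencies. Allele frequencies entering each colony's terms are
bias-corrected by excluding the focal colony, and the standard error comes
from jackknifing over colonies — mirroring how the classic Relatedness
program treats small numbers of groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RelatednessEstimate",
    "regression_relatedness",
    "effective_mating_frequency",
    "t_test_vs_expectation",
]


@dataclass
class RelatednessEstimate:
    r: float
    se: float
    n_colonies: int
    jackknife_values: np.ndarray

    def __repr__(self) -> str:
        return f"<RelatednessEstimate r={self.r:.3f} se={self.se:.3f} n={self.n_colonies}>"


def _genotype_matrix(gt: pd.DataFrame, loci: list[str]):
    """Per locus: array (n, 2) of allele codes (-1 = missing), plus the
    allele code book."""
    mats, books = {}, {}
    for l in loci:
        a1 = gt[f"{l}_a1"].astype(str).to_numpy()
        a2 = gt[f"{l}_a2"].astype(str).to_numpy()
        alleles = sorted({a for a in np.concatenate([a1, a2]) if a not in ("", "nan")})
        code = {a: i for i, a in enumerate(alleles)}
        m = np.full((len(gt), 2), -1, dtype=int)
        for j, (x, y) in enumerate(zip(a1, a2)):
            if x not in ("", "nan") and y not in ("", "nan"):
                m[j, 0], m[j, 1] = code[x], code[y]
        mats[l], books[l] = m, alleles
    return mats, books


def _colony_constants(mat: np.ndarray, k: int):
    """Frequency-independent pieces of the within-colony relatedness sums
    at one locus.

    For focal individual x and its average nestmate y, each of x's allele
    positions a contributes P_y(a) - p(a) to the numerator and
    P_x(a) - p(a) to the denominator, where P_z(a) is the frequency of
    allele a within z's genotype (0, 0.5 or 1) and p the reference
    population frequency. Both sums are linear in p:
    num = P_num - c.p and den = P_den - c.p with c the colony allele-count
    vector, so they can be re-evaluated for any leave-out frequency vector
    at O(k) cost (used heavily by the jackknife).
    """
    m = mat[mat[:, 0] >= 0]
    n = len(m)
    if n < 2:
        return 0.0, 0.0, np.zeros(k)
    gfreq = np.zeros((n, k))
    np.add.at(gfreq, (np.arange(n), m[:, 0]), 0.5)
    np.add.at(gfreq, (np.arange(n), m[:, 1]), 0.5)
    gsum = gfreq.sum(axis=0)
    partners = (gsum[None, :] - gfreq) / (n - 1)  # mean nestmate profile
    rows = np.repeat(np.arange(n), 2)
    cols = m.ravel()
    p_num = float(partners[rows, cols].sum())
    p_den = float(gfreq[rows, cols].sum())
    cvec = np.bincount(cols, minlength=k).astype(float)
    return p_num, p_den, cvec


def regression_relatedness(
    gt: pd.DataFrame,
    loci: list[str] | None = None,
    castes: tuple[str, ...] = ("worker",),
) -> RelatednessEstimate:
    """Mean within-colony regression relatedness with jackknife SE.

    Uses the ratio-of-sums form pooled over colonies and loci; reference
    allele frequencies for each colony's terms exclude that colony
    (bias correction). Requires >= 2 colonies and >= 2 usable individuals
    per colony; monomorphic data leave the denominator undefined.
    """
    sub = gt[gt.caste.isin(castes)].reset_index(drop=True)
    if loci is None:
        loci = sorted({c[:-3] for c in sub.columns if c.endswith("_a1")})
    colonies = sub.colony_id.unique()
    if len(colonies) < 2:
        raise ValueError("need >= 2 colonies for bias-corrected relatedness")

    mats, books = _genotype_matrix(sub, loci)
    colony_idx = {c: (sub.colony_id == c).to_numpy() for c in colonies}
    nc = len(colonies)

    # per colony x locus: frequency-independent sums and allele counts
    consts = {}  # locus -> (p_num[nc], p_den[nc], cvec[nc, k], counts[nc, k])
    for l in loci:
        k = len(books[l])
        p_num = np.zeros(nc)
        p_den = np.zeros(nc)
        cvec = np.zeros((nc, k))
        for ci, c in enumerate(colonies):
            p_num[ci], p_den[ci], cvec[ci] = _colony_constants(mats[l][colony_idx[c]], k)
        consts[l] = (p_num, p_den, cvec)

    def totals(leave_out: int | None):
        """Pooled (num, den) over colonies and loci, with each colony's
        reference frequencies excluding itself and any jackknifed colony."""
        tot_num = tot_den = 0.0
        for l in loci:
            p_num, p_den, cvec = consts[l]
            grand = cvec.sum(axis=0)
            rest = grand[None, :] - cvec  # leave focal colony out
            if leave_out is not None:
                rest = rest - cvec[leave_out]
                rest[leave_out] = 0.0
            sums = rest.sum(axis=1)
            ok = sums > 0
            if leave_out is not None:
                ok[leave_out] = False
            corr = np.einsum("ij,ij->i", cvec[ok], rest[ok] / sums[ok, None])
            tot_num += float((p_num[ok] - corr).sum())
            tot_den += float((p_den[ok] - corr).sum())
        return tot_num, tot_den

    tot_num, tot_den = totals(None)
    if tot_den == 0:
        raise ValueError("relatedness undefined: monomorphic data (zero denominator)")
    r = tot_num / tot_den

    jack = np.full(nc, np.nan)
    for ci in range(nc):
        num, den = totals(ci)
        if den != 0:
            jack[ci] = num / den
    ok = np.isfinite(jack)
    g = ok.sum()
    se = math.sqrt((g - 1) / g * np.sum((jack[ok] - jack[ok].mean()) ** 2)) if g > 1 else float("nan")
    return RelatednessEstimate(r=float(r), se=float(se),
                               n_colonies=len(colonies), jackknife_values=jack)


def effective_mating_frequency(offspring_counts) -> float:
    """Effective queen mating frequency q_e from per-father daughter counts.

    With observed paternity proportions y_i among n genotyped daughters,
    q_e = (n - 1) / (n * sum(y_i^2) - 1) — the sample-size-corrected
    estimator, which equals 1 for a single father and approaches the
    inverse of sum(y_i^2) as n grows.
    """
    counts = np.asarray(offspring_counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 1 or np.any(counts < 0):
        raise ValueError("offspring_counts must be non-negative per-father counts")
    n = counts.sum()
    if n < 2:
        raise ValueError("need >= 2 genotyped daughters")
    y = counts / n
    denom = n * np.sum(y**2) - 1.0
    if denom <= 0:
        raise ValueError(
            f"q_e undefined: n*sum(y^2) - 1 = {denom:.4f} <= 0 "
            "(paternity too even for this sample size)"
        )
    return float((n - 1.0) / denom)


def t_test_vs_expectation(mean: float, se: float, df: int, mu0: float) -> tuple[float, float]:
    """One-sample t statistic against an expected value, two-sided p.

    Used e.g. to test observed nestmate-worker relatedness against the 0.75
    expected under one singly mated queen.
    """
    if se <= 0:
        raise ValueError("standard error must be > 0")
    if df < 1:
        raise ValueError("df must be >= 1")
    t = (mean - mu0) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)
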
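"""Sex-allocation economics and male relatedness accounting.

Colony investment in sexuals is expressed in male equivalents: one virgin
queen costs c = (f/m)^k males, where f and m are mean dry masses of mature
virgin queens and males and k is the metabolic parameter correcting for the
lower respiration rate and higher fat content of queens (across-species
average 0.7). Sexual production is then S = c*F + M and the numerical sex
ratio is F/(F+M).

Life-for-life relatedness of workers and queens to the colony's males is an
affine function of the parentage composition of those males, with the
standard haplodiploid coefficients: a worker values a brother (queen's son)
at 0.25 and a nephew (sister's or intermorph sister's son) at 0.375, while
the queen values her own son at 0.5 and a grandson at 0.25.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "cost_ratio",
    "sexual_production",
    "numerical_sex_ratio",
    "life_for_life_male_relatedness",
    "caste_summary",
    "egg_rate_ratio",
    "allocation_table",
    "plot_sex_ratio_vs_production",
]

#: life-for-life relatedness of a worker / the queen to a male, by the
#: male's mother class
LIFE_FOR_LIFE = {
    "worker_to": {"queen": 0.25, "worker": 0.375, "intermorph": 0.375},
    "queen_to": {"queen": 0.5, "worker": 0.25, "intermorph": 0.25},
}

DEFAULT_QUEEN_DRY_MASS_MG = 1.41
DEFAULT_MALE_DRY_MASS_MG = 0.09
DEFAULT_METABOLIC_K = 0.7


def cost_ratio(f: float, m: float, k: float = DEFAULT_METABOLIC_K) -> float:
    """Virgin-queen-to-male energy cost ratio c = (f/m)^k.

    f, m are mean dry masses (mg) of mature virgin queens and males;
    k in (0, 1] is the metabolic parameter.
    """
    if f <= 0 or m <= 0:
        raise ValueError("dry masses must be positive")
    if not 0 < k <= 1:
        raise ValueError("metabolic parameter k must be in (0, 1]")
    return float((f / m) ** k)


def sexual_production(F: float, M: float, c: float) -> float:
    """Sexual production S = c*F + M, in male equivalents."""
    if F < 0 or M < 0:
        raise ValueError("sexual counts must be non-negative")
    return float(c * F + M)


def numerical_sex_ratio(F: float, M: float) -> float:
    """Proportion of virgin queens among all sexuals, F / (F + M)."""
    if F < 0 or M < 0:
        raise ValueError("sexual counts must be non-negative")
    if F + M == 0:
        raise ValueError("sex ratio undefined: colony produced no sexuals")
    return float(F / (F + M))


def life_for_life_male_relatedness(
    p_queen_sons: float, p_worker_sons: float, p_intermorph_sons: float
) -> tuple[float, float]:
    """(workers-to-males, queen-to-males) life-for-life relatedness given
    the parentage composition of the colony's males.

    Both are affine in the proportions:
    r_workers = 0.25*p_q + 0.375*(p_w + p_i)
    r_queen   = 0.50*p_q + 0.25*(p_w + p_i)
    """
    p = np.array([p_queen_sons, p_worker_sons, p_intermorph_sons], dtype=float)
    if np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    w = LIFE_FOR_LIFE["worker_to"]
    q = LIFE_FOR_LIFE["queen_to"]
    r_workers = w["queen"] * p[0] + w["worker"] * p[1] + w["intermorph"] * p[2]
    r_queen = q["queen"] * p[0] + q["worker"] * p[1] + q["intermorph"] * p[2]
    return float(r_workers), float(r_queen)


def caste_summary(composition: pd.DataFrame) -> dict:
    """Descriptive statistics of colony composition.

    Returns per-caste medians/quartiles/ranges, the worker:intermorph
    median ratio, a square-root-transformed intermorph covariate (as used
    downstream as a GLM covariate), and the Spearman rank correlation
    between worker and intermorph counts.
    """
    if len(composition) == 0:
        raise ValueError("empty composition table")
    out = {"per_caste": {}}
    for col in ("workers", "intermorphs"):
        x = composition[col].astype(float)
        out["per_caste"][col] = {
            "median": float(x.median()),
            "q1": float(x.quantile(0.25)),
            "q3": float(x.quantile(0.75)),
            "min": float(x.min()),
            "max": float(x.max()),
        }
    med_i = out["per_caste"]["intermorphs"]["median"]
    out["worker_intermorph_median_ratio"] = (
        out["per_caste"]["workers"]["median"] / med_i if med_i > 0 else float("inf")
    )
    out["sqrt_intermorphs"] = np.sqrt(composition["intermorphs"].astype(float)).to_numpy()
    if len(composition) > 1:
        rho, p = stats.spearmanr(composition["workers"], composition["intermorphs"])
        out["spearman_workers_intermorphs"] = {"rho": float(rho), "p": float(p)}
    return out


def egg_rate_ratio(median_group_a: float, median_group_b: float) -> float:
    """Ratio of median egg counts between two bioassay groups (e.g. ten
    workers plus one intermorph vs eleven workers)."""
    if median_group_b <= 0:
        raise ValueError("denominator median must be > 0")
    return float(median_group_a / median_group_b)


def allocation_table(
    composition: pd.DataFrame,
    f: float = DEFAULT_QUEEN_DRY_MASS_MG,
    m: float = DEFAULT_MALE_DRY_MASS_MG,
    k: float = DEFAULT_METABOLIC_K,
) -> pd.DataFrame:
    """Augment a composition table with c, S, numerical sex ratio and the
    sqrt-intermorph covariate. Colonies without sexuals get NaN sex ratio
    (flagged, not an error)."""
    req = {"colony_id", "F", "M"}
    missing = req - set(composition.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    if len(composition) == 0:
        raise ValueError("empty composition table")
    c = cost_ratio(f, m, k)
    out = composition.copy()
    F = out["F"].astype(float)
    M = out["M"].astype(float)
    out["c"] = c
    out["S"] = c * F + M
    tot = F + M
    out["sex_ratio"] = np.where(tot > 0, F / tot.replace(0, np.nan), np.nan)
    out["sex_ratio_defined"] = tot > 0
    if "intermorphs" in out.columns:
        out["sqrt_intermorphs"] = np.sqrt(out["intermorphs"].astype(float))
    return out


def plot_sex_ratio_vs_production(allocation: pd.DataFrame, ax=None):
    """Scatter of numerical sex ratio against sexual production S; the
    split-sex-ratio pattern shows up as points piling near 0 and 1."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sub = allocation[allocation["sex_ratio_defined"]]
    ax.scatter(sub["S"], sub["sex_ratio"])
    ax.set_xlabel("Sexual production S (male equivalents)")
    ax.set_ylabel("Numerical sex ratio F/(F+M)")
    ax.set_ylim(-0.05, 1.05)
    return ax
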
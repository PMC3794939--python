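"""Simulation validation of the ML estimator and its discrete CIs.

Replicates the estimator's own calibration check: simulate a large set of
colonies with parameters drawn uniformly, push each through the two-stage
sampling/detection process, estimate, and summarise accuracy (mean of
estimate/true over colonies with at least one true non-queen son) and the
coverage of the nominal 95% confidence limits.

Also provides an exact brute-force probability oracle for the detectable
count d, independent of the likelihood code path, used to verify the
likelihood entrywise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .parentage import confidence_limits, likelihood_vector, ml_estimate

__all__ = ["ValidationConfig", "ValidationResult", "run_validation", "brute_force_pmf"]


@dataclass
class ValidationConfig:
    """Uniform parameter ranges for the simulated validation set.

    Defaults: 18450 colonies, n_t in [5, 100], n_g in [3, min(30, n_t)],
    P_d in [0.25, 0.75], true n_c in [1, n_t].
    """

    n_colonies: int = 18450
    n_t_range: tuple[int, int] = (5, 100)
    n_g_range: tuple[int, int] = (3, 30)
    p_d_range: tuple[float, float] = (0.25, 0.75)
    n_c_range: tuple[int, int] | None = None  # None -> [1, n_t] per colony
    sampling: str = "binomial"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if self.n_t_range[0] > self.n_t_range[1] or self.n_t_range[0] < 1:
            raise ValueError("invalid n_t range")
        if self.n_g_range[0] < 1 or self.n_g_range[0] > self.n_t_range[1]:
            raise ValueError("invalid n_g range")
        if not (0 < self.p_d_range[0] <= self.p_d_range[1] <= 1):
            raise ValueError("P_d range must lie in (0, 1]")


@dataclass
class ValidationResult:
    accuracy_mean: float
    accuracy_se: float
    coverage: float
    n_colonies: int
    n_accuracy: int  # colonies with true n_c >= 1 entering the accuracy mean
    config: dict = field(default_factory=dict)
    audit: "np.ndarray | None" = None  # structured per-colony table

    def to_dict(self) -> dict:
        return {
            "accuracy_mean": self.accuracy_mean,
            "accuracy_se": self.accuracy_se,
            "coverage": self.coverage,
            "n_colonies": self.n_colonies,
            "n_accuracy": self.n_accuracy,
            "config": self.config,
        }


def run_validation(cfg: ValidationConfig, keep_audit: bool = False) -> ValidationResult:
    """Run the full simulated validation.

    Per colony: draw (n_t, n_g, P_d, true n_c) uniformly; draw the number
    of non-queen sons in the genotyped sample hypergeometrically (simple
    random sampling without replacement from the colony's males); draw the
    detected count binomially with success P_d; then estimate with the
    configured likelihood and record estimate/true and whether the true
    count fell inside the CI.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_colonies
    n_t = rng.integers(cfg.n_t_range[0], cfg.n_t_range[1] + 1, size=n)
    g_hi = np.minimum(cfg.n_g_range[1], n_t)
    g_lo = np.minimum(cfg.n_g_range[0], g_hi)
    n_g = rng.integers(g_lo, g_hi + 1)
    p_d = rng.uniform(cfg.p_d_range[0], cfg.p_d_range[1], size=n)
    if cfg.n_c_range is None:
        n_c = rng.integers(1, n_t + 1)
    else:
        lo, hi = cfg.n_c_range
        n_c = rng.integers(lo, np.minimum(hi, n_t) + 1)

    n_s = rng.hypergeometric(n_c, n_t - n_c, n_g)
    d = rng.binomial(n_s, p_d)

    ratios = np.empty(n)
    inside = np.empty(n, dtype=bool)
    nhat_arr = np.empty(n, dtype=int)
    lo_arr = np.empty(n, dtype=int)
    hi_arr = np.empty(n, dtype=int)
    for i in range(n):
        pl = likelihood_vector(int(n_g[i]), int(n_t[i]), int(d[i]),
                               float(p_d[i]), sampling=cfg.sampling)
        nhat = ml_estimate(pl)
        lo, hi = confidence_limits(pl, cfg.alpha)
        nhat_arr[i], lo_arr[i], hi_arr[i] = nhat, lo, hi
        ratios[i] = nhat / n_c[i] if n_c[i] > 0 else np.nan
        inside[i] = lo <= n_c[i] <= hi

    ok = n_c >= 1
    acc = ratios[ok]
    result = ValidationResult(
        accuracy_mean=float(acc.mean()),
        accuracy_se=float(acc.std(ddof=1) / math.sqrt(len(acc))),
        coverage=float(inside.mean()),
        n_colonies=n,
        n_accuracy=int(ok.sum()),
        config=asdict(cfg),
    )
    if keep_audit:
        result.audit = np.rec.fromarrays(
            [n_t, n_g, p_d, n_c, n_s, d, nhat_arr, lo_arr, hi_arr, inside],
            names="n_t,n_g,p_d,n_c,n_s,d,n_hat,ci_lo,ci_hi,covered",
        )
    return result


# ---------------------------------------------------------------------------
# exact oracle for the distribution of the detectable count d
# ---------------------------------------------------------------------------


def brute_force_pmf(n_t: int, n_c: int, n_g: int, p_d: float,
                    mode: str = "count", n_draws: int = 100_000,
                    seed: int = 0) -> np.ndarray:
    """Exact pmf of the detectable count d given colony truth.

    ``mode="count"``: exhaustively weight every sample composition and
    detection outcome using combinatorial counting (math.comb) — exact,
    independent of the scipy pmf calls the estimator uses; capped at
    n_t <= 12. ``mode="enumerate"``: literally enumerates all
    C(n_t, n_g) genotyping subsets and all detection subsets with
    itertools (n_t <= 8), for cross-checking the counting form.
    ``mode="mc"``: Monte-Carlo above the caps.

    Returns an array of length n_g + 1 with P(d = j).
    """
    if not 0 <= n_c <= n_t or not 0 < n_g <= n_t:
        raise ValueError("need 0 <= n_c <= n_t and 0 < n_g <= n_t")
    if not 0 <= p_d <= 1:
        raise ValueError("P_d outside [0, 1]")

    if mode == "count":
        if n_t > 12:
            raise ValueError("exhaustive counting capped at n_t <= 12; use mode='mc'")
        pmf = np.zeros(n_g + 1)
        denom = math.comb(n_t, n_g)
        for n_s in range(max(0, n_g - (n_t - n_c)), min(n_c, n_g) + 1):
            w_sample = math.comb(n_c, n_s) * math.comb(n_t - n_c, n_g - n_s) / denom
            for j in range(n_s + 1):
                pmf[j] += w_sample * math.comb(n_s, j) * p_d**j * (1 - p_d) ** (n_s - j)
        return pmf

    if mode == "enumerate":
        if n_t > 8:
            raise ValueError("literal enumeration capped at n_t <= 8")
        labels = [1] * n_c + [0] * (n_t - n_c)  # 1 = non-queen son
        pmf = np.zeros(n_g + 1)
        subsets = list(itertools.combinations(range(n_t), n_g))
        w = 1.0 / len(subsets)
        for sub in subsets:
            picked = [labels[i] for i in sub]
            nq = [i for i, lab in enumerate(picked) if lab == 1]
            for outcome in itertools.product((0, 1), repeat=len(nq)):
                prob = w
                for o in outcome:
                    prob *= p_d if o else (1 - p_d)
                pmf[sum(outcome)] += prob
        return pmf

    if mode == "mc":
        rng = np.random.default_rng(seed)
        n_s = rng.hypergeometric(n_c, n_t - n_c, n_g, size=n_draws)
        d = rng.binomial(n_s, p_d)
        return np.bincount(d, minlength=n_g + 1) / n_draws

    raise ValueError(f"unknown mode {mode!r}")
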
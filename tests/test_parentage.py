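import numpy as np
import pandas as pd
import pytest

from antparentage import (
    InconsistentGenotypesError,
    ParentageModel,
    ZeroDetectionError,
    classify_males,
    confidence_limits,
    detection_probability,
    estimate_colonies,
    infer_parental_genotypes,
    likelihood_vector,
    ml_estimate,
    simulate_colony,
    sample_for_genotyping,
)
from antparentage.parentage import ParentageLikelihood, ParentalAssignment

from conftest import genotype_row


def workers_table(genotypes, loci=("L1", "L2")):
    rows = [
        genotype_row("C1", f"C1.worker.{i}", "worker", g, loci=loci)
        for i, g in enumerate(genotypes)
    ]
    return pd.DataFrame(rows)


def males_table(genotypes, loci=("L1", "L2")):
    rows = [
        genotype_row("C1", f"C1.male.{i}", "male", g, loci=loci)
        for i, g in enumerate(genotypes)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parental deduction
# ---------------------------------------------------------------------------


def test_two_worker_classes_force_queen_and_father():
    # workers {a,c} and {b,c}: only queen {a,b} with father c needs one father
    gt = workers_table([(("a", "c"), ("x", "y")), (("b", "c"), ("x", "y"))] * 5)
    best = infer_parental_genotypes(gt)[0]
    assert best.n_fathers == 1
    assert set(best.queen["L1"]) == {"a", "b"}
    assert best.fathers[0]["L1"] == "c"


def test_identical_workers_yield_full_ambiguity_set():
    gt = workers_table([(("a", "c"), ("x", "x"))] * 6)
    sols = infer_parental_genotypes(gt)
    combos = {(tuple(sorted(s.queen["L1"])), s.fathers[0]["L1"]) for s in sols}
    assert combos == {
        (("a", "a"), "c"),
        (("c", "c"), "a"),
        (("a", "c"), "a"),
        (("a", "c"), "c"),
    }
    assert all(s.ambiguous for s in sols)


def test_three_paternal_alleles_rejected_under_two_fathers():
    # queen must be {a,b}; workers then need paternal alleles c, d and e
    gt = workers_table(
        [
            (("a", "c"), ("x", "x")),
            (("b", "c"), ("x", "x")),
            (("a", "d"), ("x", "x")),
            (("b", "d"), ("x", "x")),
            (("a", "e"), ("x", "x")),
            (("b", "e"), ("x", "x")),
        ]
    )
    with pytest.raises(InconsistentGenotypesError):
        infer_parental_genotypes(gt)


def test_two_patrilines_recovered_with_counts():
    # queen {a,b}; father 1 = (c, x) with 8 daughters, father 2 = (d, y) with 2
    gt = workers_table(
        [(("a", "c"), ("x", "x"))] * 4
        + [(("b", "c"), ("x", "x"))] * 4
        + [(("a", "d"), ("y", "x"))] * 2
    )
    best = infer_parental_genotypes(gt)[0]
    assert best.n_fathers == 2
    got = {(f["L1"], f["L2"]) for f in best.fathers}
    assert got == {("c", "x"), ("d", "y")}
    assert sorted(best.offspring_counts) == [2, 8]


def test_requires_two_workers():
    gt = workers_table([(("a", "c"), ("x", "y"))])
    with pytest.raises(ValueError, match="2 genotyped workers"):
        infer_parental_genotypes(gt)


# ---------------------------------------------------------------------------
# detection probability
# ---------------------------------------------------------------------------


def assignment(queen_l1, father_l1, queen_l2, father_l2):
    return ParentalAssignment(
        queen={"L1": queen_l1, "L2": queen_l2},
        fathers=[{"L1": father_l1, "L2": father_l2}],
        offspring_counts=(10,),
        n_daughters=10,
    )


@pytest.mark.parametrize(
    "father_l1, father_l2, expected",
    [
        ("a", "x", 0.0),  # both father alleles present in queen
        ("c", "x", 0.5),  # one informative locus
        ("c", "z", 0.75),  # both loci informative
    ],
)
def test_detection_probability_unlinked_loci(father_l1, father_l2, expected):
    pa = assignment(("a", "b"), father_l1, ("x", "y"), father_l2)
    assert detection_probability(pa) == pytest.approx(expected)


def test_detection_probability_two_patrilines_needs_flag():
    pa = ParentalAssignment(
        queen={"L1": ("a", "b")},
        fathers=[{"L1": "c"}, {"L1": "a"}],
        offspring_counts=(8, 2),
        n_daughters=10,
    )
    with pytest.raises(ValueError, match="single patriline"):
        detection_probability(pa)
    # weighted average: 0.8 * 0.5 (informative) + 0.2 * 0 (uninformative)
    assert detection_probability(pa, multiple_patrilines="average") == pytest.approx(0.4)


# ---------------------------------------------------------------------------
# male classification
# ---------------------------------------------------------------------------


def test_classify_males_labels_and_counts():
    pa = assignment(("a", "b"), "c", ("x", "y"), "x")
    males = males_table(
        [
            ("c", "x"),            # father-only allele -> detectable
            ("a", "y"),            # queen alleles -> queen-compatible
            (("a", "b"), "x"),     # heterozygous -> diploid-suspect
        ]
    )
    mc = classify_males(males, pa)
    assert mc.labels.tolist() == [
        "detectable-non-queen", "queen-compatible", "diploid-suspect",
    ]
    assert mc.d == 1
    assert mc.n_classified == 2  # diploid-suspect excluded from n_g as well


def test_classify_males_flags_foreign_allele():
    pa = assignment(("a", "b"), "c", ("x", "y"), "x")
    males = males_table([("z", "x")])  # z matches neither parent
    with pytest.warns(UserWarning, match="neither queen nor"):
        mc = classify_males(males, pa)
    assert mc.labels.iloc[0] == "foreign"
    assert mc.d == 0 and mc.n_classified == 0


# ---------------------------------------------------------------------------
# likelihood vector, ML estimate, confidence limits
# ---------------------------------------------------------------------------


def test_no_detections_point_to_zero():
    pl = likelihood_vector(n_g=10, n_t=30, d=0, p_d=0.5)
    assert ml_estimate(pl) == 0
    assert np.all(np.diff(pl.values) <= 1e-15)  # non-increasing beyond 0


def test_census_perfect_detection_is_point_mass():
    pl = likelihood_vector(n_g=8, n_t=8, d=3, p_d=1.0, sampling="hypergeometric")
    assert np.flatnonzero(pl.values > 1e-15).tolist() == [3]
    assert ml_estimate(pl) == 3
    assert confidence_limits(pl) == (3, 3)


def test_worked_vector_matches_moment_argmax():
    # argmax ~ n_t * d / (n_g * P_d) = 20 * 2 / (10 * 0.5) = 8
    pl = likelihood_vector(n_g=10, n_t=20, d=2, p_d=0.5)
    assert ml_estimate(pl) == 8


def test_likelihood_rejects_bad_inputs():
    with pytest.raises(ZeroDetectionError):
        likelihood_vector(5, 10, 1, 0.0)
    with pytest.raises(ValueError):
        likelihood_vector(5, 10, 6, 0.5)  # d > n_g
    with pytest.raises(ValueError):
        likelihood_vector(11, 10, 1, 0.5)  # n_g > n_t


def test_argmax_ties_break_toward_smaller_count():
    flat = ParentageLikelihood(n_g=2, n_t=4, d=1, p_d=0.5,
                               values=np.array([0.1, 0.3, 0.3, 0.1, 0.0]))
    assert ml_estimate(flat) == 1


def test_lower_limit_zero_when_nothing_detected():
    pl = likelihood_vector(n_g=10, n_t=40, d=0, p_d=0.4)
    lo, hi = confidence_limits(pl)
    assert lo == 0
    assert hi >= 0


@pytest.mark.parametrize("sampling", ["binomial", "hypergeometric"])
def test_ci_always_brackets_ml_estimate(sampling, rng):
    for _ in range(200):
        n_t = int(rng.integers(2, 60))
        n_g = int(rng.integers(1, n_t + 1))
        d = int(rng.integers(0, n_g + 1))
        p_d = float(rng.uniform(0.05, 1.0))
        pl = likelihood_vector(n_g, n_t, d, p_d, sampling=sampling)
        nhat = ml_estimate(pl)
        lo, hi = confidence_limits(pl)
        assert 0 <= lo <= nhat <= hi <= n_t


def test_estimate_monotone_in_d_and_detection():
    n_g, n_t = 10, 50
    prev = -1
    for d in range(n_g + 1):
        nhat = ml_estimate(likelihood_vector(n_g, n_t, d, 0.5))
        assert nhat >= prev
        prev = nhat
    prev = n_t + 1
    for p_d in (0.25, 0.4, 0.6, 0.8, 1.0):
        nhat = ml_estimate(likelihood_vector(n_g, n_t, 3, p_d))
        assert nhat <= prev
        prev = nhat


def test_binomial_approaches_hypergeometric_for_large_colonies():
    """Compared as normalised vectors (the scale on which the CI uses
    them), the two sampling terms agree closely once n_t = 10 * n_g."""
    n_g = 5
    n_t = 10 * n_g
    worst = 0.0
    for d in range(n_g + 1):
        for p_d in (0.25, 0.5, 0.75, 1.0):
            b = likelihood_vector(n_g, n_t, d, p_d, "binomial").values
            h = likelihood_vector(n_g, n_t, d, p_d, "hypergeometric").values
            worst = max(worst, float(np.max(np.abs(b / b.sum() - h / h.sum()))))
    assert worst < 0.01


def test_self_consistency_of_estimate(rng):
    """Under the fitted n_hat, the observed d sits inside the central 99%
    of its sampling distribution."""
    from antparentage import brute_force_pmf

    for _ in range(30):
        n_t = int(rng.integers(4, 13))
        n_g = int(rng.integers(2, n_t + 1))
        d = int(rng.integers(0, n_g + 1))
        p_d = float(rng.choice([0.25, 0.5, 0.75, 1.0]))
        nhat = ml_estimate(likelihood_vector(n_g, n_t, d, p_d, "hypergeometric"))
        pmf = brute_force_pmf(n_t, nhat, n_g, p_d)
        cdf = np.cumsum(pmf)
        below = cdf[d] - pmf[d]  # P(D < d)
        above = 1.0 - cdf[d]     # P(D > d)
        assert below <= 0.995 and above <= 0.995


# ---------------------------------------------------------------------------
# model / results / multi-colony driver
# ---------------------------------------------------------------------------


def test_model_pipeline_recovers_zero_when_truth_is_zero(pop):
    colony = simulate_colony(pop, n_workers=40, n_males=20, p_nonqueen=0.0, seed=4)
    gt, _ = sample_for_genotyping(colony, 15, 10, seed=5)
    model = ParentageModel.from_genotypes(gt, colony.n_males)
    res = model.fit()
    assert model.n_detected == 0
    assert res.nhat == 0 and res.proportion == 0.0
    assert res.conf_int()[0] == 0
    assert "ML estimate" in res.summary()


def test_zero_detection_colony_is_refused():
    # both loci: father allele is one of the queen's -> P_d = 0
    workers = workers_table([(("a", "b"), ("x", "y")), (("b", "b"), ("y", "y"))] * 4)
    males = males_table([("a", "x"), ("b", "y")])
    gt = pd.concat([workers, males], ignore_index=True)
    with pytest.raises(ZeroDetectionError, match="P_d = 0"):
        ParentageModel.from_genotypes(gt, 10)


def test_pipeline_recovers_true_proportion_on_average(pop):
    """Across many simulated colonies with 30% non-queen sons, the full
    pipeline (parent deduction -> detection -> classification -> ML) is
    close to unbiased for the true count."""
    rng = np.random.default_rng(314)
    ratios = []
    for i in range(120):
        colony = simulate_colony(pop, colony_id=f"C{i}", n_workers=80,
                                 n_males=24, p_nonqueen=0.3, seed=rng)
        gt, _ = sample_for_genotyping(colony, 16, 16, seed=rng)
        try:
            model = ParentageModel.from_genotypes(gt, colony.n_males)
        except ZeroDetectionError:
            continue  # uninformative queen/father combination, as in the field
        ratios.append(model.fit().nhat / colony.n_nonqueen_sons)
    assert len(ratios) > 60
    assert 0.85 <= np.mean(ratios) <= 1.2


def test_estimate_colonies_reports_exclusions(pop):
    good = simulate_colony(pop, colony_id="G", n_workers=30, n_males=12,
                           p_nonqueen=0.25, seed=8)
    gt_good, _ = sample_for_genotyping(good, 12, 12, seed=9)
    workers = workers_table([(("a", "b"), ("x", "y")), (("b", "b"), ("y", "y"))] * 4)
    males = males_table([("a", "x")])
    bad = pd.concat([workers, males], ignore_index=True)
    bad["colony_id"] = "B"
    all_gt = pd.concat([gt_good, bad], ignore_index=True)
    comp = pd.DataFrame(
        {"colony_id": ["G", "B"], "year": 2005, "queens": 1, "workers": [30, 8],
         "intermorphs": 0, "F": 0, "M": [12, 10]}
    )
    est = estimate_colonies(all_gt, comp).set_index("colony_id")
    assert not est.loc["G", "excluded"]
    assert est.loc["G", "n_hat"] >= 0
    assert est.loc["B", "excluded"]
    assert "P_d = 0" in est.loc["B", "reason"]
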
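"""Synthetic haplodiploid colony generator.

Emulates the pedigree structure the downstream analysis assumes: one queen
(rarely two patrilines), unfertilised haploid males, diploid workers and
intermorphs that each carry one queen allele and one paternal allele, and a
configurable true proportion of non-queen sons (sons of workers or
intermorphs rather than the queen). Loci are unlinked and simulated
independently; mutation is ignored.

Genotype tables are plain :class:`pandas.DataFrame` objects with columns
``colony_id, individual_id, caste, ploidy, <locus>_a1, <locus>_a2``
(``<locus>_a2`` empty for haploids; missing genotypes are empty fields).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import PopulationLoci

__all__ = [
    "SimulatedColony",
    "simulate_colony",
    "sample_for_genotyping",
    "colony_genotype_table",
    "composition_row",
]

CASTES = ("queen", "worker", "intermorph", "male", "virgin_queen")


@dataclass
class SimulatedColony:
    """Full pedigree truth for one simulated colony."""

    colony_id: str
    loci: tuple[str, ...]
    queen: dict[str, tuple[str, str]]
    fathers: list[dict[str, str]]
    paternity: np.ndarray  # proportions per father, sum to 1
    workers: list[dict[str, tuple[str, str]]]
    intermorphs: list[dict[str, tuple[str, str]]]
    males: list[dict[str, str]]
    male_parent_class: list[str]  # "queen" | "worker" | "intermorph"
    n_virgin_queens: int = 0
    seed: int | None = None
    worker_patriline: list[int] = field(default_factory=list)

    @property
    def n_workers(self) -> int:
        return len(self.workers)

    @property
    def n_intermorphs(self) -> int:
        return len(self.intermorphs)

    @property
    def n_males(self) -> int:
        return len(self.males)

    @property
    def n_nonqueen_sons(self) -> int:
        """True count of males mothered by a worker or intermorph (n_c)."""
        return sum(1 for c in self.male_parent_class if c != "queen")


def _draw_diploid(rng, queen_alleles, father_allele):
    # daughter: one random queen allele + the paternal allele
    return (queen_alleles[rng.integers(2)], father_allele)


def simulate_colony(
    pop: PopulationLoci,
    *,
    colony_id: str = "C1",
    n_workers: int = 525,
    n_intermorphs: int = 4,
    n_males: int = 20,
    n_virgin_queens: int = 0,
    n_fathers: int = 1,
    paternity: tuple[float, ...] | None = None,
    p_nonqueen: float = 0.0,
    intermorph_son_share: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> SimulatedColony:
    """Simulate one colony from the population gene pool.

    Parameters
    ----------
    n_fathers : number of patrilines K (1 by default; the study queens were
        almost always singly mated).
    paternity : offspring proportions per father; defaults to (1,) for K=1
        and a 0.8/0.2 major/minor split for K=2.
    p_nonqueen : true proportion of non-queen sons among the ``n_males``
        adult males; the realised count is ``round(p * n_males)``.
    intermorph_son_share : fraction of the non-queen sons mothered by
        intermorphs (the rest by workers).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)

    if not 0.0 <= p_nonqueen <= 1.0:
        raise ValueError(f"p_nonqueen={p_nonqueen} outside [0, 1]")
    if not 0.0 <= intermorph_son_share <= 1.0:
        raise ValueError("intermorph_son_share outside [0, 1]")
    if paternity is None:
        paternity = (1.0,) if n_fathers == 1 else (0.8, 0.2) if n_fathers == 2 else None
    if paternity is None or len(paternity) != n_fathers:
        raise ValueError("paternity proportions must match n_fathers")
    pat = np.asarray(paternity, dtype=float)
    if abs(pat.sum() - 1.0) > 1e-9 or np.any(pat < 0):
        raise ValueError("paternity proportions must be non-negative and sum to 1")

    n_c = int(round(p_nonqueen * n_males))
    n_im_sons = int(round(intermorph_son_share * n_c))
    n_wk_sons = n_c - n_im_sons
    if n_wk_sons > 0 and n_workers == 0:
        raise ValueError("worker sons requested but colony has zero workers")
    if n_im_sons > 0 and n_intermorphs == 0:
        raise ValueError("intermorph sons requested but colony has zero intermorphs")

    loci = pop.names
    queen = {l.name: tuple(rng.choice(l.alleles, size=2, p=l.frequencies)) for l in pop}
    fathers = [
        {l.name: str(rng.choice(l.alleles, p=l.frequencies)) for l in pop}
        for _ in range(n_fathers)
    ]

    def daughter(father_idx: int) -> dict[str, tuple[str, str]]:
        return {
            name: _draw_diploid(rng, queen[name], fathers[father_idx][name])
            for name in loci
        }

    worker_pat = list(rng.choice(n_fathers, size=n_workers, p=pat))
    workers = [daughter(j) for j in worker_pat]
    intermorphs = [daughter(int(rng.choice(n_fathers, p=pat))) for _ in range(n_intermorphs)]

    # males: haploid, one random allele of the mother at every locus
    males: list[dict[str, str]] = []
    classes: list[str] = []
    mother_pool = (
        [("queen", queen)] * (n_males - n_c)
        + [("worker", None)] * n_wk_sons
        + [("intermorph", None)] * n_im_sons
    )
    rng.shuffle(mother_pool)
    for cls, g in mother_pool:
        if cls == "worker":
            g = workers[rng.integers(n_workers)]
        elif cls == "intermorph":
            g = intermorphs[rng.integers(n_intermorphs)]
        males.append({name: str(g[name][rng.integers(2)]) for name in loci})
        classes.append(cls)

    return SimulatedColony(
        colony_id=colony_id,
        loci=tuple(loci),
        queen=queen,
        fathers=fathers,
        paternity=pat,
        workers=workers,
        intermorphs=intermorphs,
        males=males,
        male_parent_class=classes,
        n_virgin_queens=n_virgin_queens,
        seed=seed_val,
        worker_patriline=worker_pat,
    )


def _rows(colony: SimulatedColony, caste: str, genotypes, start: int, mask_rate: float, rng):
    rows = []
    diploid = caste not in ("male",)
    for i, g in enumerate(genotypes):
        row = {
            "colony_id": colony.colony_id,
            "individual_id": f"{colony.colony_id}.{caste}.{start + i}",
            "caste": caste,
            "ploidy": 2 if diploid else 1,
        }
        for name in colony.loci:
            if mask_rate > 0 and rng is not None and rng.random() < mask_rate:
                row[f"{name}_a1"], row[f"{name}_a2"] = "", ""
                continue
            if diploid:
                a, b = sorted(g[name])
                row[f"{name}_a1"], row[f"{name}_a2"] = a, b
            else:
                row[f"{name}_a1"], row[f"{name}_a2"] = g[name], ""
        rows.append(row)
    return rows


def colony_genotype_table(colony: SimulatedColony, mask_rate: float = 0.0, rng=None) -> pd.DataFrame:
    """Full genotype table for every individual in the colony."""
    if mask_rate > 0 and rng is None:
        rng = np.random.default_rng(0)
    rows = (
        _rows(colony, "worker", colony.workers, 0, mask_rate, rng)
        + _rows(colony, "intermorph", colony.intermorphs, 0, mask_rate, rng)
        + _rows(colony, "male", colony.males, 0, mask_rate, rng)
    )
    return pd.DataFrame(rows)


def sample_for_genotyping(
    colony: SimulatedColony,
    n_workers: int,
    n_males: int,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random sample without replacement of workers and males.

    Returns the genotype table and a truth sidecar (individual_id,
    parent_class) for the sampled males — test/audit use only; the
    estimator never sees it.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not 0 < n_workers <= colony.n_workers:
        raise ValueError(f"n_workers={n_workers} not in (0, {colony.n_workers}]")
    if not 0 < n_males <= colony.n_males:
        raise ValueError(f"n_males={n_males} not in (0, {colony.n_males}]")

    w_idx = rng.choice(colony.n_workers, size=n_workers, replace=False)
    m_idx = rng.choice(colony.n_males, size=n_males, replace=False)

    m_ids = [f"{colony.colony_id}.male.{i}" for i in m_idx]
    rows = []
    for i in w_idx:
        g = colony.workers[i]
        row = {
            "colony_id": colony.colony_id,
            "individual_id": f"{colony.colony_id}.worker.{i}",
            "caste": "worker",
            "ploidy": 2,
        }
        for name in colony.loci:
            a, b = sorted(g[name])
            row[f"{name}_a1"], row[f"{name}_a2"] = a, b
        rows.append(row)
    for mid, i in zip(m_ids, m_idx):
        g = colony.males[i]
        row = {
            "colony_id": colony.colony_id,
            "individual_id": mid,
            "caste": "male",
            "ploidy": 1,
        }
        for name in colony.loci:
            row[f"{name}_a1"], row[f"{name}_a2"] = g[name], ""
        rows.append(row)
    table = pd.DataFrame(rows)

    truth = pd.DataFrame(
        {
            "colony_id": colony.colony_id,
            "individual_id": m_ids,
            "parent_class": [colony.male_parent_class[i] for i in m_idx],
        }
    )
    return table, truth


def mask_genotypes(table: pd.DataFrame, rate: float,
                   seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Blank out whole-locus genotypes at the given per-entry rate, to
    exercise reader and inference robustness to missing data."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mask rate outside [0, 1]")
    if rate == 0.0:
        return table
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    loci = sorted({c[:-3] for c in out.columns if c.endswith("_a1")})
    for l in loci:
        mask = rng.random(len(out)) < rate
        out.loc[mask, f"{l}_a1"] = ""
        out.loc[mask, f"{l}_a2"] = ""
    return out


def composition_row(colony: SimulatedColony, year: int = 2005) -> dict:
    """Colony-composition record matching the composition CSV schema."""
    return {
        "colony_id": colony.colony_id,
        "year": year,
        "queens": 1,
        "workers": colony.n_workers,
        "intermorphs": colony.n_intermorphs,
        "F": colony.n_virgin_queens,
        "M": colony.n_males,
    }
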
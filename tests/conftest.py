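import numpy as np
import pandas as pd
import pytest

from antparentage import build_population_loci, default_population


@pytest.fixture(scope="session")
def pop():
    """The study-like gene pool: 4 alleles at He 0.62 and 10 at He 0.82."""
    return default_population()


@pytest.fixture(scope="session")
def toy_pop():
    """Two loci with letter alleles and simple frequencies, for hand checks."""
    return build_population_loci(
        [
            {"name": "L1", "alleles": ["a", "b", "c"], "frequencies": [0.5, 0.3, 0.2]},
            {"name": "L2", "alleles": ["x", "y", "z"], "frequencies": [0.4, 0.4, 0.2]},
        ]
    )


def genotype_row(colony_id, individual_id, caste, alleles, loci=("L1", "L2")):
    """Build one genotype-table row; ``alleles`` is a per-locus tuple, each a
    pair (diploid) or single string (haploid)."""
    row = {"colony_id": colony_id, "individual_id": individual_id, "caste": caste}
    diploid = caste in ("queen", "worker", "intermorph", "virgin_queen")
    row["ploidy"] = 2 if diploid else 1
    for locus, a in zip(loci, alleles):
        if isinstance(a, (tuple, list)):
            row[f"{locus}_a1"], row[f"{locus}_a2"] = sorted(a)
        else:
            row[f"{locus}_a1"], row[f"{locus}_a2"] = a, ""
    return row


@pytest.fixture()
def make_table():
    def build(rows):
        return pd.DataFrame(rows)

    return build


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
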
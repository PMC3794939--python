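"""Population-level microsatellite loci: allele frequencies and heterozygosity.

The study system carries two unlinked microsatellite markers whose
population gene pools are summarised as allele-frequency vectors. Expected
heterozygosity He = 1 - sum(p_i^2) is the calibration target when explicit
frequencies are not supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Locus",
    "PopulationLoci",
    "expected_heterozygosity",
    "build_population_loci",
    "default_population",
]

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class Locus:
    """A single microsatellite locus: allele labels and their frequencies."""

    name: str
    alleles: tuple[str, ...]
    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.frequencies):
            raise ValueError(f"{self.name}: alleles and frequencies differ in length")
        if len(self.alleles) < 2:
            raise ValueError(f"{self.name}: need at least 2 alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(f"{self.name}: duplicate allele labels")
        p = np.asarray(self.frequencies, dtype=float)
        if np.any(p <= 0):
            raise ValueError(f"{self.name}: all frequencies must be > 0")
        if abs(p.sum() - 1.0) > _FREQ_TOL:
            raise ValueError(f"{self.name}: frequencies sum to {p.sum()}, not 1")

    @property
    def expected_heterozygosity(self) -> float:
        return expected_heterozygosity(self.frequencies)


@dataclass(frozen=True)
class PopulationLoci:
    """The population gene pool: an ordered collection of loci."""

    loci: tuple[Locus, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self.loci)

    def __getitem__(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)


def expected_heterozygosity(frequencies) -> float:
    """He = 1 - sum(p_i^2) for a valid frequency vector."""
    p = np.asarray(frequencies, dtype=float)
    if abs(p.sum() - 1.0) > _FREQ_TOL:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))


def _tune_frequencies(n_alleles: int, target_he: float, tol: float = 1e-10) -> np.ndarray:
    """Frequency vector of length ``n_alleles`` with He equal to ``target_he``.

    Parametrised as one major allele at frequency x >= 1/k with the rest
    equifrequent; He(x) = 1 - x^2 - (1-x)^2/(k-1) decreases monotonically in
    x on [1/k, 1), so deterministic bisection converges to any attainable
    target. Maximum attainable He is 1 - 1/k (all alleles equifrequent).
    """
    k = n_alleles
    he_max = 1.0 - 1.0 / k
    if target_he <= 0 or target_he > he_max + 1e-12:
        raise ValueError(
            f"target He={target_he} not attainable with {k} alleles (max {he_max:.4f})"
        )

    def he(x: float) -> float:
        return 1.0 - x**2 - (1.0 - x) ** 2 / (k - 1)

    lo, hi = 1.0 / k, 1.0 - 1e-12  # he(lo)=he_max, he(hi)->0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if he(mid) > target_he:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    x = 0.5 * (lo + hi)
    p = np.full(k, (1.0 - x) / (k - 1))
    p[0] = x
    p /= p.sum()
    return p


def build_population_loci(config: list[dict]) -> PopulationLoci:
    """Build a :class:`PopulationLoci` from per-locus config dicts.

    Each dict needs ``name`` plus either explicit ``frequencies`` (with
    optional ``alleles`` labels) or ``n_alleles`` and a ``target_he`` to
    tune to (within ±0.02 by construction; bisection is far tighter).
    """
    loci = []
    for entry in config:
        name = entry["name"]
        if "frequencies" in entry:
            freqs = tuple(float(f) for f in entry["frequencies"])
            alleles = tuple(entry.get("alleles", [f"{name}.{i+1}" for i in range(len(freqs))]))
        else:
            k = int(entry["n_alleles"])
            target = float(entry["target_he"])
            freqs = tuple(_tune_frequencies(k, target))
            alleles = tuple(entry.get("alleles", [f"{name}.{i+1}" for i in range(k)]))
        loci.append(Locus(name=name, alleles=alleles, frequencies=freqs))
    return PopulationLoci(loci=tuple(loci))


def default_population() -> PopulationLoci:
    """Two unlinked loci matching the study markers: 4 alleles at He 0.62
    and 10 alleles at He 0.82."""
    return build_population_loci(
        [
            {"name": "C20", "n_alleles": 4, "target_he": 0.62},
            {"name": "C9", "n_alleles": 10, "target_he": 0.82},
        ]
    )
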
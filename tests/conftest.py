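import numpy as np
import pytest

from memlipid.lipidome import MolPercentLipidome
from memlipid.nomenclature import parse_species


def make_lipidome(abundances: dict[str, float], scope: str = "all") -> MolPercentLipidome:
    """MolPercentLipidome from {name: mol%}; values must sum to 100."""
    return MolPercentLipidome(
        scope=scope,
        abundances={parse_species(n): v for n, v in abundances.items()},
    )


@pytest.fixture
def toy_membrane_table() -> dict[str, float]:
    """Five-species pmol table spanning membrane and storage lipids."""
    return {
        "PC-34:1;0": 40.0,
        "PE-36:2;0": 20.0,
        "TAG-58:2;0": 20.0,
        "Chol": 15.0,
        "SM-34:1;1": 5.0,
    }


def random_species_table(rng: np.random.Generator, n_species: int = 20) -> dict[str, float]:
    """Random chain-resolved GPL table (mol%, sums to 100) for oracle tests."""
    classes = ["PC", "PE", "PS", "PI", "PG", "PA"]
    names = set()
    while len(names) < n_species:
        cls = classes[rng.integers(len(classes))]
        c1, c2 = rng.integers(12, 23, size=2)
        d1 = rng.integers(0, 4)
        d2 = rng.integers(0, 7)
        names.add(f"{cls}-{c1}:{d1};0-{c2}:{d2};0")
    weights = rng.uniform(0.5, 10.0, size=n_species)
    weights = 100.0 * weights / weights.sum()
    return dict(zip(sorted(names), weights))
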
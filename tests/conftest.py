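import numpy as np
import pytest

from pinepop.datamodel import LocusAlignment
from pinepop.synthetic import StudyScenario, generate_study


@pytest.fixture
def toy_alignment() -> LocusAlignment:
    """Three 10-bp haploid sequences: S=2 (one singleton, one informative)."""
    return LocusAlignment(
        "toy",
        ["s1", "s2", "s3"],
        ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATT"],
    )


@pytest.fixture(scope="session")
def small_study():
    """Session-cached small synthetic study (8 nuclear loci + mtDNA)."""
    scenario = StudyScenario(n_loci=8)
    study, truth = generate_study(scenario, seed=11)
    return study, truth


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     miss: float = 0.0, gap: float = 0.0) -> LocusAlignment:
    """Random alignment helper shared by brute-force oracle tests."""
    bases = np.array(list("ACGT"))
    anc = rng.choice(bases, size=L)
    mat = np.tile(anc, (n, 1))
    n_mut = rng.integers(1, max(2, L // 10))
    for _ in range(n_mut):
        j = int(rng.integers(L))
        derived = rng.choice([b for b in "ACGT" if b != anc[j]])
        carriers = rng.random(n) < rng.uniform(0.1, 0.9)
        mat[carriers, j] = derived
    if miss > 0:
        mat[rng.random(mat.shape) < miss] = "N"
    if gap > 0:
        mat[rng.random(mat.shape) < gap] = "-"
    return LocusAlignment(
        f"rand", [f"s{i}" for i in range(n)], ["".join(r) for r in mat]
    )
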
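import numpy as np
import pytest

from asymflow.popgenstats import GenotypeTable


@pytest.fixture
def two_group_table() -> GenotypeTable:
    """Toy two-group table: group1 {aa x6, ab x4}, group2 {ab x4, bb x6}."""
    a, b = 1, 2
    g1 = [(a, a)] * 6 + [(a, b)] * 4
    g2 = [(a, b)] * 4 + [(b, b)] * 6
    alleles = np.array([[g] for g in g1 + g2])
    return GenotypeTable(
        ids=[f"i{k}" for k in range(20)],
        groups=["g1"] * 10 + ["g2"] * 10,
        loci=["L1"],
        alleles=alleles,
    )


@pytest.fixture
def fixed_demes_table() -> GenotypeTable:
    """Fixed difference: deme1 all aa, deme2 all bb (n=10 each)."""
    alleles = np.array([[(1, 1)]] * 10 + [[(2, 2)]] * 10)
    return GenotypeTable(
        ids=[f"i{k}" for k in range(20)],
        groups=["d1"] * 10 + ["d2"] * 10,
        loci=["L1"],
        alleles=alleles,
    )


def random_table(
    rng: np.random.Generator,
    n_per_group: dict[str, int],
    n_loci: int = 5,
    n_alleles: int = 6,
    freqs: np.ndarray | None = None,
) -> GenotypeTable:
    """HWE draws from shared (or provided per-group) allele frequencies."""
    ids, groups, rows = [], [], []
    if freqs is None:
        freqs = rng.dirichlet(np.ones(n_alleles), size=n_loci)
    for group, n in n_per_group.items():
        for i in range(n):
            geno = np.empty((n_loci, 2), dtype=np.int64)
            for j in range(n_loci):
                geno[j] = rng.choice(n_alleles, size=2, p=freqs[j]) + 1
            ids.append(f"{group}_{i}")
            groups.append(group)
            rows.append(geno)
    return GenotypeTable(
        ids=ids, groups=groups,
        loci=[f"L{j}" for j in range(n_loci)],
        alleles=np.stack(rows),
    )
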
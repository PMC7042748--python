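"""Linkage-disequilibrium single-sample effective population size.

Background association between physically unlinked loci in a closed
population reflects drift: the smaller Ne, the larger the expected squared
composite correlation r2 between allele dosages at different loci.  The
estimator follows the standard LD method: mean Burrows composite r2 across
locus pairs, minus the sampling expectation E[r2] for the sample size, then

    Ne = (1/3 + sqrt(1/9 - 2.76 * r2')) / (2 * r2')      (random mating)

with r2' = r2_hat - E[r2]; r2' <= 0 yields an infinite estimate.  The
confidence interval is a delete-one jackknife over locus pairs.

Burrows' composite disequilibrium for alleles A (locus 1) and B (locus 2)
is the covariance of per-individual allele dosages; the r reported here is
exactly the Pearson correlation of the two dosage vectors, equivalent to
Delta normalized by the dosage standard deviations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .popgenstats import MISSING, GenotypeTable


def expected_r2(s: float) -> float:
    """Sampling expectation of r2 for sample size S under random mating."""
    if s <= 0:
        raise ValueError("sample size must be positive")
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def ne_from_r2prime(r2_prime: float) -> float:
    """Point estimate from drift-attributable r2; infinite at the boundary."""
    if r2_prime <= 0:
        return math.inf
    disc = 1.0 / 9.0 - 2.76 * r2_prime
    if disc < 0:
        disc = 0.0
    return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2_prime)


def _dosages(geno: np.ndarray, code: int) -> np.ndarray:
    return (geno == code).sum(axis=1).astype(float)


def burrows_r2(
    table: GenotypeTable,
    group: str,
    locus_a: str,
    locus_b: str,
    maf_threshold: float = 0.02,
) -> tuple[float, int]:
    """Composite r2 between two loci in one group.

    Every allele pair (one allele per locus, both above the minor-allele
    frequency threshold) contributes the squared Pearson correlation of its
    dosage vectors; pairs are averaged unweighted.  Individuals missing
    either locus are excluded pairwise.  Returns (mean r2, n individuals);
    raises if either locus is monomorphic after exclusion.
    """
    sub = table.group_table(group)
    ja, jb = sub.loci.index(locus_a), sub.loci.index(locus_b)
    ga = sub.alleles[:, ja, :]
    gb = sub.alleles[:, jb, :]
    keep = (ga != MISSING).all(axis=1) & (gb != MISSING).all(axis=1)
    ga, gb = ga[keep], gb[keep]
    s = int(keep.sum())
    if s < 3:
        raise ValueError("fewer than 3 individuals scored at both loci")

    def usable_alleles(g: np.ndarray) -> list[int]:
        codes, counts = np.unique(g.ravel(), return_counts=True)
        freqs = counts / counts.sum()
        # drop the most common allele to avoid double counting: with k
        # alleles only k-1 dosages are linearly independent
        order = np.argsort(counts)[::-1]
        kept = [
            int(codes[i])
            for i in order[1:]
            if freqs[i] >= maf_threshold and freqs[i] <= 1 - maf_threshold
        ]
        # biallelic locus: keep exactly the minor allele
        if not kept and codes.size >= 2:
            minor = int(codes[order[-1]])
            f_minor = counts[order[-1]] / counts.sum()
            if f_minor >= maf_threshold:
                kept = [minor]
        return kept

    alleles_a = usable_alleles(ga)
    alleles_b = usable_alleles(gb)
    if not alleles_a or not alleles_b:
        raise ValueError("locus monomorphic after MAF exclusion")

    r2s = []
    for ca in alleles_a:
        xa = _dosages(ga, ca)
        if xa.std() == 0:
            continue
        for cb in alleles_b:
            xb = _dosages(gb, cb)
            if xb.std() == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2s.append(float(r) ** 2)
    if not r2s:
        raise ValueError("no usable allele pairs")
    return float(np.mean(r2s)), s


@dataclass
class NeEstimate:
    group: str
    mean_r2: float
    expected_r2: float
    ne: float
    ci: tuple[float, float]
    n_comparisons: int
    harmonic_s: float
    maf_threshold: float


def ld_ne(
    table: GenotypeTable,
    group: str,
    maf_threshold: float = 0.02,
) -> NeEstimate:
    """LD Ne estimate for one group with a jackknife CI over locus pairs."""
    pair_r2: list[float] = []
    pair_s: list[int] = []
    for la, lb in itertools.combinations(table.loci, 2):
        try:
            r2, s = burrows_r2(table, group, la, lb, maf_threshold=maf_threshold)
        except ValueError:
            continue
        pair_r2.append(r2)
        pair_s.append(s)
    if len(pair_r2) < 2:
        raise ValueError("fewer than 2 usable locus pairs")
    r2_arr = np.asarray(pair_r2)
    s_arr = np.asarray(pair_s, dtype=float)
    harmonic_s = len(s_arr) / np.sum(1.0 / s_arr)
    mean_r2 = float(r2_arr.mean())
    e_r2 = expected_r2(harmonic_s)
    ne = ne_from_r2prime(mean_r2 - e_r2)

    # delete-one jackknife on the mean r2, mapped through the Ne transform
    n = len(r2_arr)
    total = r2_arr.sum()
    jack_means = (total - r2_arr) / (n - 1)
    jack_mean = jack_means.mean()
    jack_var = (n - 1) / n * np.sum((jack_means - jack_mean) ** 2)
    se = math.sqrt(jack_var)
    lo_r2 = mean_r2 - 1.96 * se
    hi_r2 = mean_r2 + 1.96 * se
    # high r2 -> low Ne: the CI flips through the transform
    ci = (ne_from_r2prime(hi_r2 - e_r2), ne_from_r2prime(lo_r2 - e_r2))
    return NeEstimate(
        group=group,
        mean_r2=mean_r2,
        expected_r2=e_r2,
        ne=ne,
        ci=ci,
        n_comparisons=n,
        harmonic_s=float(harmonic_s),
        maf_threshold=maf_threshold,
    )
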
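"""Pairwise relationship classification from multilocus genotypes.

Dyads are scored under the k-coefficient mixture model: a relationship
category is a triple (k0, k1, k2) of probabilities that the pair shares
0, 1 or 2 alleles identical by descent.  Per locus,

    P(pair | k) = k0 * P0 + k1 * P1 + k2 * P2

where P0 is the product of the two HWE genotype probabilities, P1 the joint
probability given exactly one shared IBD allele, and P2 the probability of
the genotype when the pair is genetically identical at the locus.  Loci
multiply (log-likelihoods add).  Presets cover unrelated (U), half-sib
(HS, also the avuncular/grandparent class), full-sib (FS), parent-offspring
(PO) and duplicate-sample (DUP) hypotheses.

A dyad is accepted only when its best category carries a posterior-style
weight L_max / sum(L) above a threshold (default 0.9), mirroring the >90%
acceptance rule used in likelihood sibship reconstruction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .popgenstats import MISSING, GenotypeTable

K_PRESETS: dict[str, tuple[float, float, float]] = {
    "U": (1.0, 0.0, 0.0),
    "HS": (0.5, 0.5, 0.0),
    "FS": (0.25, 0.5, 0.25),
    "PO": (0.0, 1.0, 0.0),
    "DUP": (0.0, 0.0, 1.0),
}


# ---------------------------------------------------------------------------
# per-locus kernels
# ---------------------------------------------------------------------------

def _hwe_prob(g: tuple[int, int], p: dict[int, float]) -> float:
    a, b = g
    if a == b:
        return p[a] ** 2
    return 2.0 * p[a] * p[b]


def _conditional_one_ibd(
    g1: tuple[int, int], g2: tuple[int, int], p: dict[int, float]
) -> float:
    """P(g2 | g1, one shared IBD allele), unordered genotypes."""
    a, b = g1
    c, d = g2
    prob = 0.0
    for shared in (a, b):
        w = 0.5  # the IBD copy is either allele of g1 with equal chance
        if c == d:
            if c == shared:
                prob += w * p[c]
        else:
            if c == shared:
                prob += w * p[d]
            if d == shared:
                prob += w * p[c]
    return prob


def dyad_locus_likelihoods(
    g1: tuple[int, int],
    g2: tuple[int, int],
    freqs: dict[int, float],
) -> tuple[float, float, float]:
    """(P0, P1, P2) for one locus; alleles must appear in ``freqs``."""
    for allele in (*g1, *g2):
        if allele not in freqs:
            raise KeyError(
                f"allele {allele} missing from frequency table; estimate "
                "frequencies from the full sample first"
            )
    p0 = _hwe_prob(g1, freqs) * _hwe_prob(g2, freqs)
    p1 = _hwe_prob(g1, freqs) * _conditional_one_ibd(g1, g2, freqs)
    p2 = _hwe_prob(g1, freqs) if sorted(g1) == sorted(g2) else 0.0
    return p0, p1, p2


def dyad_likelihood(
    genos1: np.ndarray,
    genos2: np.ndarray,
    allele_freqs: list[dict[int, float]],
    k: tuple[float, float, float],
) -> tuple[list[float], float]:
    """Per-locus and total log-likelihood of a dyad under k = (k0, k1, k2).

    ``genos1``/``genos2`` are (L, 2) genotype arrays; loci where either
    individual is missing are skipped.  Raises if no locus is shared.
    """
    k0, k1, k2 = k
    per_locus: list[float] = []
    total = 0.0
    shared = 0
    for j in range(genos1.shape[0]):
        g1 = tuple(int(x) for x in genos1[j])
        g2 = tuple(int(x) for x in genos2[j])
        if MISSING in g1 or MISSING in g2:
            continue
        shared += 1
        p0, p1, p2 = dyad_locus_likelihoods(g1, g2, allele_freqs[j])
        lik = k0 * p0 + k1 * p1 + k2 * p2
        ll = float(np.log(lik)) if lik > 0 else -np.inf
        per_locus.append(ll)
        total += ll
    if shared == 0:
        raise ValueError("dyad shares no scored loci")
    return per_locus, total


# ---------------------------------------------------------------------------
# dyad classification
# ---------------------------------------------------------------------------

@dataclass
class DyadResult:
    id1: str
    id2: str
    site1: str
    site2: str
    log_likelihoods: dict[str, float]
    category: str
    accepted: bool
    weight: float
    lr_vs_runner_up: float
    duplicate: bool = False

    @property
    def mixed_site(self) -> bool:
        """True when one member is from the inflow and one from the outflow."""
        kinds = {_site_kind(self.site1), _site_kind(self.site2)}
        return kinds == {"inflow", "outflow"}


def _site_kind(site: str) -> str:
    s = site.lower()
    if "inflow" in s:
        return "inflow"
    if "outflow" in s:
        return "outflow"
    return "lake"


def pooled_allele_frequencies(table: GenotypeTable) -> list[dict[int, float]]:
    """Allele frequencies per locus from the whole sample (weak structure
    justifies pooling)."""
    return [table.allele_frequencies(j) for j in range(table.n_loci)]


def classify_dyads(
    table: GenotypeTable,
    categories: tuple[str, ...] = ("U", "HS", "FS", "PO"),
    lr_threshold: float = 0.9,
    pairs: list[tuple[int, int]] | None = None,
) -> list[DyadResult]:
    """Score pairs of individuals and assign the maximum-likelihood category.

    ``lr_threshold`` is the acceptance weight: a dyad is accepted only when
    L_max / sum(L over categories) exceeds it.  Pairs identical at every
    shared locus are flagged as duplicates (scored under k = (0,0,1)) and
    never reported as a relationship dyad.  ``pairs`` restricts scoring to a
    candidate subset of index pairs; default is all pairs.
    """
    if table.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    freqs = pooled_allele_frequencies(table)
    if pairs is None:
        pairs = list(itertools.combinations(range(table.n_individuals), 2))
    all_cats = (*categories, "DUP")

    # per locus: encode observed unordered genotypes as dense codes and
    # precompute the (P0, P1, P2) kernels for every genotype pair, so each
    # dyad costs a few table lookups instead of re-deriving the mixture
    n, L = table.n_individuals, table.n_loci
    codes = np.full((n, L), -1, dtype=np.int64)
    kernels: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for j in range(L):
        geno = np.sort(table.alleles[:, j, :], axis=1)
        scored = (geno != MISSING).all(axis=1)
        uniq, inverse = np.unique(geno[scored], axis=0, return_inverse=True)
        codes[scored, j] = inverse
        g = uniq.shape[0]
        p0 = np.empty((g, g))
        p1 = np.empty((g, g))
        p2 = np.empty((g, g))
        for a in range(g):
            for b in range(a, g):
                g1 = (int(uniq[a, 0]), int(uniq[a, 1]))
                g2 = (int(uniq[b, 0]), int(uniq[b, 1]))
                p0[a, b], p1[a, b], p2[a, b] = dyad_locus_likelihoods(
                    g1, g2, freqs[j]
                )
                p0[b, a], p1[b, a], p2[b, a] = p0[a, b], p1[a, b], p2[a, b]
        kernels.append((p0, p1, p2))

    ii = np.fromiter((p[0] for p in pairs), dtype=np.int64, count=len(pairs))
    jj = np.fromiter((p[1] for p in pairs), dtype=np.int64, count=len(pairs))
    n_pairs = len(pairs)
    lls = {cat: np.zeros(n_pairs) for cat in all_cats}
    shared = np.zeros(n_pairs, dtype=np.int64)
    with np.errstate(divide="ignore"):
        for j in range(L):
            c1, c2 = codes[ii, j], codes[jj, j]
            ok = (c1 >= 0) & (c2 >= 0)
            if not ok.any():
                continue
            shared += ok
            p0, p1, p2 = kernels[j]
            v0 = p0[c1[ok], c2[ok]]
            v1 = p1[c1[ok], c2[ok]]
            v2 = p2[c1[ok], c2[ok]]
            for cat in all_cats:
                k0, k1, k2 = K_PRESETS[cat]
                lls[cat][ok] += np.log(k0 * v0 + k1 * v1 + k2 * v2)

    results: list[DyadResult] = []
    comp_mat = np.vstack([lls[c] for c in categories])  # (n_cat, n_pairs)
    dup_flags = lls["DUP"] >= comp_mat.max(axis=0) - 1e-12
    best_idx = comp_mat.argmax(axis=0)
    with np.errstate(invalid="ignore"):
        shifted = comp_mat - comp_mat.max(axis=0, keepdims=True)
        weights_all = np.exp(shifted)
        weights_all /= weights_all.sum(axis=0, keepdims=True)
    order = np.sort(comp_mat, axis=0)
    for p_idx, (i, j) in enumerate(pairs):
        if shared[p_idx] == 0:
            raise ValueError(
                f"dyad ({table.ids[i]}, {table.ids[j]}) shares no scored loci"
            )
        best = categories[best_idx[p_idx]]
        weight = float(weights_all[best_idx[p_idx], p_idx])
        dup = bool(dup_flags[p_idx])
        lr = (
            float(order[-1, p_idx] - order[-2, p_idx])
            if len(categories) > 1
            else float("inf")
        )
        results.append(
            DyadResult(
                id1=table.ids[i],
                id2=table.ids[j],
                site1=table.groups[i],
                site2=table.groups[j],
                log_likelihoods={c: float(lls[c][p_idx]) for c in all_cats},
                category="DUP" if dup else best,
                accepted=(not dup) and weight > lr_threshold,
                weight=weight,
                lr_vs_runner_up=lr,
                duplicate=dup,
            )
        )
    return results


def _logsumexp(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    m = arr.max()
    if not np.isfinite(m):
        return m
    return float(m + np.log(np.exp(arr - m).sum()))


def dyads_to_frame(dyads: list[DyadResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id1": d.id1, "id2": d.id2, "site1": d.site1, "site2": d.site2,
                "category": d.category, "weight": d.weight,
                "lr": d.lr_vs_runner_up, "accepted": d.accepted,
                "mixed_site": d.mixed_site,
            }
            for d in dyads
        ]
    )


def site_pair_counts(dyads: list[DyadResult], category: str) -> pd.DataFrame:
    """Symmetric site x site matrix of accepted dyad counts for a category."""
    accepted = [d for d in dyads if d.accepted and d.category == category]
    sites: list[str] = []
    for d in accepted:
        for s in (d.site1, d.site2):
            if s not in sites:
                sites.append(s)
    m = pd.DataFrame(0, index=sites, columns=sites, dtype=int)
    for d in accepted:
        m.loc[d.site1, d.site2] += 1
        if d.site1 != d.site2:
            m.loc[d.site2, d.site1] += 1
    return m


# ---------------------------------------------------------------------------
# mixed-site proportion comparison
# ---------------------------------------------------------------------------

@dataclass
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    chi2: float
    p: float


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Two-sample proportion test with Yates continuity correction.

    Equivalent to R's prop.test on the 2x2 table; the correction is capped
    so it cannot overshoot |ad - bc|.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    a, b = x1, n1 - x1
    c, d = x2, n2 - x2
    n = n1 + n2
    cross = abs(a * d - b * c)
    corr = min(n / 2.0, cross)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return ProportionTestResult(x1, n1, x2, n2, 0.0, 1.0)
    chi2 = n * (cross - corr) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return ProportionTestResult(x1, n1, x2, n2, float(chi2), p)


def mixed_site_proportion_test(
    sib_groups: list[list[str]],
    site_of: dict[str, str],
    full_sib_groups: list[list[str]],
) -> ProportionTestResult:
    """Compare mixed inflow x outflow membership between half- and full-sib
    groups, excluding any group containing a lake-sampled member.

    ``sib_groups`` are half-sib groups (lists of individual ids),
    ``full_sib_groups`` likewise; ``site_of`` maps each id to its sampling
    site label.
    """

    def tally(groups: list[list[str]]) -> tuple[int, int]:
        mixed = kept = 0
        for g in groups:
            kinds = {_site_kind(site_of[i]) for i in g}
            if "lake" in kinds:
                continue
            kept += 1
            if kinds == {"inflow", "outflow"}:
                mixed += 1
        return mixed, kept

    x1, n1 = tally(sib_groups)
    x2, n2 = tally(full_sib_groups)
    return two_proportion_test(x1, n1, x2, n2)


# ---------------------------------------------------------------------------
# full-sib deduplication
# ---------------------------------------------------------------------------

def dedupe_full_sibs(
    table: GenotypeTable,
    dyads: list[DyadResult],
    detected_tags: set[str] | None = None,
) -> tuple[GenotypeTable, list[str]]:
    """Collapse full-sibling groups to one representative each.

    Connected components of accepted FS dyads form the groups.  Priority for
    retention: telemetry-detected individuals first, then most scored loci,
    then highest sample id.  Returns the reduced table and the removed ids.
    """
    detected_tags = detected_tags or set()
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for d in dyads:
        if d.accepted and d.category == "FS":
            union(d.id1, d.id2)

    components: dict[str, list[str]] = {}
    for x in parent:
        components.setdefault(find(x), []).append(x)

    scored = dict(zip(table.ids, table.scored_counts().tolist()))
    removed: list[str] = []
    for members in components.values():
        if len(members) < 2:
            continue

        def priority(ind: str):
            return (ind in detected_tags, scored.get(ind, 0), ind)

        keep = max(members, key=priority)
        removed.extend(m for m in members if m != keep)

    removed_set = set(removed)
    keep_idx = [i for i, ind in enumerate(table.ids) if ind not in removed_set]
    return table.subset(keep_idx), removed
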
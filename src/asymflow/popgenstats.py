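"""Genotype container, Genepop I/O and population-genetic summary statistics.

The central object is :class:`GenotypeTable`, a diploid individuals x loci
table of codominant allele pairs (microsatellite-style integer codes) with a
group label per individual.  On top of it this module provides:

* per-group diversity summaries (Ho, unbiased He, allele counts, rarefied
  allelic richness, private alleles, FIS with a bootstrap CI over loci);
* a Monte-Carlo exact Hardy-Weinberg test;
* the Weir & Cockerham (1984) theta estimator of FST with Slatkin
  linearization theta/(1-theta), permutation significance, and Holm
  sequential-Bonferroni correction;
* the QC filters used before structure analyses: drop individuals scored at
  fewer than a minimum number of loci, and flag loci whose FIS exceeds a
  threshold in a minimum number of sampling groups;
* temporal pooling of same-site year samples when within-site between-year
  differentiation is non-significant.

Allele code 0 means missing throughout, as in the Genepop format.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

MISSING = 0


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid multilocus genotypes for individuals assigned to groups.

    Parameters
    ----------
    ids:
        Individual identifiers, length n.
    groups:
        Group label per individual (sampling site, behaviour class, ...).
    loci:
        Locus names, length L.
    alleles:
        Integer array of shape (n, L, 2); 0 encodes a missing allele call.
        Allele order within a genotype carries no meaning.
    """

    ids: list[str]
    groups: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{n} individuals x {L} loci x 2"
            )
        if len(self.groups) != n:
            raise ValueError("groups length does not match ids")
        if (self.alleles < 0).any():
            raise ValueError("allele codes must be non-negative integers")

    # -- basic views --------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def scored_mask(self) -> np.ndarray:
        """Boolean (n, L): genotype fully scored (both alleles non-missing)."""
        return (self.alleles != MISSING).all(axis=2)

    def scored_counts(self) -> np.ndarray:
        """Number of scored loci per individual."""
        return self.scored_mask().sum(axis=1)

    def subset(self, index: np.ndarray | list[int]) -> "GenotypeTable":
        index = np.asarray(index)
        return GenotypeTable(
            ids=[self.ids[i] for i in index],
            groups=[self.groups[i] for i in index],
            loci=list(self.loci),
            alleles=self.alleles[index].copy(),
        )

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero(np.asarray(self.groups, dtype=object) == group)
        if idx.size == 0:
            raise KeyError(f"group {group!r} not present")
        return idx

    def group_table(self, group: str) -> "GenotypeTable":
        return self.subset(self.group_indices(group))

    def relabel_groups(self, mapping: dict[str, str]) -> "GenotypeTable":
        return GenotypeTable(
            ids=list(self.ids),
            groups=[mapping.get(g, g) for g in self.groups],
            loci=list(self.loci),
            alleles=self.alleles.copy(),
        )

    def drop_loci(self, loci: set[str] | list[str]) -> "GenotypeTable":
        drop = set(loci)
        keep = [j for j, name in enumerate(self.loci) if name not in drop]
        return GenotypeTable(
            ids=list(self.ids),
            groups=list(self.groups),
            loci=[self.loci[j] for j in keep],
            alleles=self.alleles[:, keep].copy(),
        )

    def allele_counts(self, locus_index: int) -> dict[int, int]:
        """Counts of each non-missing allele code at one locus."""
        a = self.alleles[:, locus_index, :].ravel()
        a = a[a != MISSING]
        codes, counts = np.unique(a, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    def allele_frequencies(self, locus_index: int) -> dict[int, float]:
        counts = self.allele_counts(locus_index)
        total = sum(counts.values())
        if total == 0:
            return {}
        return {a: c / total for a, c in counts.items()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        sorted_self = np.sort(self.alleles, axis=2)
        sorted_other = np.sort(other.alleles, axis=2)
        return (
            self.ids == other.ids
            and self.groups == other.groups
            and self.loci == other.loci
            and np.array_equal(sorted_self, sorted_other)
        )


# ---------------------------------------------------------------------------
# Genepop I/O
# ---------------------------------------------------------------------------

class GenepopParseError(ValueError):
    """Malformed Genepop input; message carries the 1-based line number."""


def _split_genepop_code(code: str, line_no: int) -> tuple[int, int]:
    if len(code) == 4:
        w = 2
    elif len(code) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {line_no}: genotype code {code!r} is not 4 or 6 digits"
        )
    if not code.isdigit():
        raise GenepopParseError(f"line {line_no}: non-numeric genotype {code!r}")
    return int(code[:w]), int(code[w:])


def read_genepop(path) -> GenotypeTable:
    """Read a Genepop file (2- or 3-digit allele codes; 0 = missing).

    Group labels are taken from the identifier of the last individual in each
    POP block when it looks like a shared prefix, otherwise ``pop1``,
    ``pop2``...  In practice the files written by :func:`write_genepop` carry
    the group name as the individual-line prefix before the comma, and that
    prefix is used directly.
    """
    with open(path) as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise GenepopParseError("line 1: empty file")
    loci: list[str] = []
    i = 1  # skip title line
    # locus names: one per line, or a single comma-separated line
    while i < len(raw) and raw[i].strip().lower() != "pop":
        chunk = raw[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise GenepopParseError("line 2: no locus names before first POP")

    ids: list[str] = []
    groups: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    current_group = None
    while i < len(raw):
        line = raw[i]
        stripped = line.strip()
        i += 1
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_counter += 1
            current_group = f"pop{pop_counter}"
            continue
        if current_group is None:
            raise GenepopParseError(f"line {i}: genotype row before first POP")
        if "," not in stripped:
            raise GenepopParseError(f"line {i}: missing comma in individual row")
        label, geno_part = stripped.split(",", 1)
        label = label.strip()
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"line {i}: {len(codes)} genotypes for {len(loci)} loci"
            )
        pair_row = [_split_genepop_code(c, i) for c in codes]
        # label convention "group id" or bare id
        if " " in label:
            grp, ind = label.split(" ", 1)
            groups.append(grp)
            ids.append(ind.strip())
        else:
            groups.append(current_group)
            ids.append(label)
        rows.append(pair_row)

    if not rows:
        raise GenepopParseError("no individuals found")
    alleles = np.array(rows, dtype=np.int64)
    return GenotypeTable(ids=ids, groups=groups, loci=loci, alleles=alleles)


def write_genepop(table: GenotypeTable, path, title: str = "asymflow export") -> None:
    """Write a 3-digit-code Genepop file, one POP block per group."""
    if (table.alleles > 999).any():
        raise ValueError("allele codes exceed 3-digit Genepop capacity")
    lines = [title]
    lines.extend(table.loci)
    order = np.asarray(table.groups, dtype=object)
    for group in table.group_names():
        lines.append("Pop")
        for i in np.flatnonzero(order == group):
            codes = "".join(
                f" {a:03d}{b:03d}" for a, b in table.alleles[i]
            )
            lines.append(f"{table.groups[i]} {table.ids[i]} ,{codes}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_individuals(
    table: GenotypeTable, min_scored: int = 10
) -> tuple[GenotypeTable, dict[str, int]]:
    """Drop individuals scored at fewer than ``min_scored`` loci (strict <)."""
    scored = table.scored_counts()
    keep = np.flatnonzero(scored >= min_scored)
    report = {
        "retained": int(keep.size),
        "removed": int(table.n_individuals - keep.size),
    }
    return table.subset(keep), report


def flag_problem_loci(
    fis_by_group_locus: pd.DataFrame,
    fis_threshold: float = 0.15,
    min_groups: int = 6,
) -> set[str]:
    """Flag loci with FIS > threshold in at least ``min_groups`` groups.

    ``fis_by_group_locus`` is a groups x loci DataFrame of FIS values (NaN
    allowed for monomorphic cells).  The comparison is strictly greater-than.
    """
    if not np.isfinite(fis_threshold):
        raise ValueError("fis_threshold must be finite")
    exceed = (fis_by_group_locus > fis_threshold).sum(axis=0)
    return set(exceed.index[exceed >= min_groups])


# ---------------------------------------------------------------------------
# per-group summaries
# ---------------------------------------------------------------------------

def _locus_ho_he(sub: GenotypeTable, j: int) -> tuple[float, float, int] | None:
    """(Ho, unbiased He, n scored) at locus j, or None if unscored."""
    geno = sub.alleles[:, j, :]
    scored = (geno != MISSING).all(axis=1)
    n = int(scored.sum())
    if n == 0:
        return None
    g = geno[scored]
    ho = float((g[:, 0] != g[:, 1]).mean())
    _, counts = np.unique(g.ravel(), return_counts=True)
    freqs = counts / counts.sum()
    gene_div = 1.0 - float((freqs ** 2).sum())
    he = (2 * n / (2 * n - 1)) * gene_div if n > 1 else gene_div
    return ho, he, n


def rarefied_allelic_richness(allele_counts: dict[int, int], g: int) -> float:
    """Expected allele count in a random subsample of g gene copies.

    Hurlbert rarefaction: sum over alleles of 1 - C(N - N_a, g)/C(N, g).
    """
    N = sum(allele_counts.values())
    if g > N:
        raise ValueError(f"rarefaction size g={g} exceeds sample of {N} copies")
    if g < 1:
        raise ValueError("g must be >= 1")

    def log_comb(n: int, k: int) -> float:
        if k < 0 or k > n:
            return -np.inf
        return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))

    total = 0.0
    denom = log_comb(N, g)
    for count in allele_counts.values():
        lc = log_comb(N - count, g)
        prob_absent = math.exp(lc - denom) if np.isfinite(lc) else 0.0
        total += 1.0 - prob_absent
    return total


@dataclass
class GroupSummary:
    group: str
    n: int
    ho: float
    he: float
    n_alleles: int
    allelic_richness: float
    private_alleles: int
    fis: float
    fis_ci: tuple[float, float]
    rarefaction_g: int


def fis_point(ho: float, he: float) -> float:
    """FIS = 1 - Ho/He; NaN where He = 0 (monomorphic)."""
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def fis_by_group_locus(table: GenotypeTable) -> pd.DataFrame:
    """Groups x loci DataFrame of per-locus FIS (NaN for monomorphic cells)."""
    out = {}
    for group in table.group_names():
        sub = table.group_table(group)
        row = {}
        for j, locus in enumerate(table.loci):
            stats = _locus_ho_he(sub, j)
            row[locus] = float("nan") if stats is None else fis_point(stats[0], stats[1])
        out[group] = row
    return pd.DataFrame.from_dict(out, orient="index")[table.loci]


def summarize_group(
    table: GenotypeTable,
    group: str,
    rarefaction_g: int | None = None,
    n_bootstrap: int = 1000,
    rng: np.random.Generator | None = None,
) -> GroupSummary:
    """Diversity summary for one group.

    Ho and unbiased He are averaged over scored polymorphic-or-not loci;
    FIS = 1 - mean(Ho)/mean(He) with a bootstrap-over-loci 95% CI; allelic
    richness is rarefied to ``rarefaction_g`` gene copies (default: the
    group's smallest per-locus scored 2n); private alleles are alleles seen
    in this group and no other.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    sub = table.group_table(group)
    other_idx = [i for i in range(table.n_individuals) if table.groups[i] != group]

    per_locus: list[tuple[float, float]] = []  # (ho, he) for scored loci
    locus_ns: list[int] = []
    counts_per_locus: list[dict[int, int]] = []
    for j in range(table.n_loci):
        stats = _locus_ho_he(sub, j)
        if stats is None:
            counts_per_locus.append({})
            continue
        ho, he, n = stats
        per_locus.append((ho, he))
        locus_ns.append(n)
        counts_per_locus.append(sub.allele_counts(j))
    if not per_locus:
        raise ValueError(f"group {group!r} has no scored loci")

    if rarefaction_g is None:
        rarefaction_g = 2 * min(locus_ns)

    ar_values = []
    n_alleles = 0
    n_private = 0
    others = table.subset(other_idx) if other_idx else None
    for j in range(table.n_loci):
        counts = counts_per_locus[j]
        if not counts:
            continue
        n_alleles += len(counts)
        g_here = min(rarefaction_g, sum(counts.values()))
        ar_values.append(rarefied_allelic_richness(counts, g_here))
        if others is not None:
            elsewhere = set(others.allele_counts(j))
            n_private += sum(1 for a in counts if a not in elsewhere)
        else:
            n_private += len(counts)

    hos = np.array([p[0] for p in per_locus])
    hes = np.array([p[1] for p in per_locus])
    ho_bar, he_bar = float(hos.mean()), float(hes.mean())
    fis = fis_point(ho_bar, he_bar)

    # bootstrap over loci for the FIS interval
    L = len(per_locus)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        pick = rng.integers(0, L, size=L)
        he_b = hes[pick].mean()
        boot[b] = 1.0 - hos[pick].mean() / he_b if he_b > 0 else np.nan
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])

    return GroupSummary(
        group=group,
        n=sub.n_individuals,
        ho=ho_bar,
        he=he_bar,
        n_alleles=n_alleles,
        allelic_richness=float(np.mean(ar_values)),
        private_alleles=n_private,
        fis=fis,
        fis_ci=(float(lo), float(hi)),
        rarefaction_g=rarefaction_g,
    )


def summary_table(table: GenotypeTable, rarefaction_g: int | None = None) -> pd.DataFrame:
    """Per-group summary DataFrame mirroring a sampling-sites diversity table."""
    rows = []
    for group in table.group_names():
        s = summarize_group(table, group, rarefaction_g=rarefaction_g)
        rows.append(
            {
                "group": s.group,
                "n": s.n,
                "He": s.he,
                "Ho": s.ho,
                "NA": s.n_alleles,
                "AR": s.allelic_richness,
                "AP": s.private_alleles,
                "FIS": s.fis,
                "FIS_lo": s.fis_ci[0],
                "FIS_hi": s.fis_ci[1],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact test
# ---------------------------------------------------------------------------

def _het_count(geno: np.ndarray) -> int:
    return int((geno[:, 0] != geno[:, 1]).sum())


def hwe_test(
    table: GenotypeTable,
    group: str,
    locus: str,
    n_montecarlo: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo exact HWE test for one locus in one group.

    Alleles at the locus are permuted among the scored individuals and
    re-paired; the test statistic is the heterozygote count, with two-sided
    extremeness measured by |het - E(het)| where E is the permutation mean.
    p = (1 + #{as or more extreme}) / (1 + n_montecarlo).  Monomorphic or
    single-allele inputs return p = 1.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    sub = table.group_table(group)
    j = sub.loci.index(locus)
    geno = sub.alleles[:, j, :]
    geno = geno[(geno != MISSING).all(axis=1)]
    if geno.shape[0] == 0:
        return 1.0
    pool = geno.ravel().copy()
    if len(set(pool.tolist())) < 2:
        return 1.0

    obs_het = _het_count(geno)
    perm_hets = np.empty(n_montecarlo, dtype=np.int64)
    for b in range(n_montecarlo):
        rng.shuffle(pool)
        perm = pool.reshape(-1, 2)
        perm_hets[b] = _het_count(perm)
    center = perm_hets.mean()
    extreme = np.abs(perm_hets - center) >= abs(obs_het - center) - 1e-12
    return float((1 + extreme.sum()) / (1 + n_montecarlo))


def hwe_all(
    table: GenotypeTable, n_montecarlo: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """HWE p-values for every group x locus combination."""
    rng = np.random.default_rng(seed)
    rows = []
    for group in table.group_names():
        for locus in table.loci:
            p = hwe_test(table, group, locus, n_montecarlo=n_montecarlo, rng=rng)
            rows.append({"group": group, "locus": locus, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta and friends
# ---------------------------------------------------------------------------

def _wc_components(
    alleles_by_group: list[np.ndarray],
) -> tuple[float, float, float]:
    """Sum of WC84 a, b, c variance components over alleles at one locus.

    ``alleles_by_group``: per group an (n_i, 2) array of scored genotypes.
    """
    r = len(alleles_by_group)
    ns = np.array([g.shape[0] for g in alleles_by_group], dtype=float)
    if (ns < 1).any() or r < 2:
        return 0.0, 0.0, 0.0
    n_bar = ns.mean()
    n_c = (r * n_bar - (ns ** 2).sum() / (r * n_bar)) / (r - 1)
    all_codes = np.unique(np.concatenate([g.ravel() for g in alleles_by_group]))
    a_sum = b_sum = c_sum = 0.0
    for code in all_codes:
        p_i = np.array([(g == code).mean() for g in alleles_by_group])
        h_i = np.array(
            [((g[:, 0] == code) ^ (g[:, 1] == code)).mean() for g in alleles_by_group]
        )
        p_bar = (ns * p_i).sum() / (r * n_bar)
        s2 = (ns * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
        h_bar = (ns * h_i).sum() / (r * n_bar)
        if n_bar <= 1:
            continue
        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0
        a_sum += a
        b_sum += b
        c_sum += c
    return a_sum, b_sum, c_sum


def weir_cockerham_theta(
    table: GenotypeTable, group_a: str, group_b: str
) -> float:
    """Multi-locus Weir & Cockerham (1984) theta between two groups.

    Per locus the variance components a, b, c are accumulated over alleles
    with pairwise deletion of missing genotypes; theta = sum(a)/sum(a+b+c).
    """
    sub_a = table.group_table(group_a)
    sub_b = table.group_table(group_b)
    if sub_a.n_individuals < 2 or sub_b.n_individuals < 2:
        raise ValueError("both groups need >= 2 individuals")
    num = den = 0.0
    any_locus = False
    for j in range(table.n_loci):
        per_group = []
        ok = True
        for sub in (sub_a, sub_b):
            geno = sub.alleles[:, j, :]
            geno = geno[(geno != MISSING).all(axis=1)]
            if geno.shape[0] < 1:
                ok = False
                break
            per_group.append(geno)
        if not ok:
            continue
        codes = np.unique(np.concatenate([g.ravel() for g in per_group]))
        if codes.size < 2:
            continue  # monomorphic locus carries no information
        any_locus = True
        a, b, c = _wc_components(per_group)
        num += a
        den += a + b + c
    if not any_locus:
        raise ValueError("no overlapping polymorphic scored loci between groups")
    if den == 0:
        return 0.0
    return num / den


def linearize_fst(theta: float) -> float:
    """Slatkin linearization theta/(1-theta); raises at the theta=1 pole."""
    if theta == 1.0:
        raise ValueError("linearized FST undefined at theta = 1")
    return theta / (1.0 - theta)


def fst_permutation_p(
    table: GenotypeTable,
    group_a: str,
    group_b: str,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Permutation p-value for theta between two groups.

    Individuals are shuffled between the two groups keeping sizes fixed;
    p = (1 + #{theta_perm >= theta_obs}) / (1 + n_perm).  Returns
    (theta_obs, p).
    """
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse p-value", stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng(0)
    idx_a = table.group_indices(group_a)
    idx_b = table.group_indices(group_b)
    pool = np.concatenate([idx_a, idx_b])
    joint = table.subset(pool)
    n_a = idx_a.size
    labels = np.array(["A"] * n_a + ["B"] * idx_b.size, dtype=object)
    joint.groups = labels.tolist()
    theta_obs = weir_cockerham_theta(joint, "A", "B")
    hits = 0
    for _ in range(n_perm):
        joint.groups = labels[rng.permutation(len(pool))].tolist()
        theta_p = weir_cockerham_theta(joint, "A", "B")
        if theta_p >= theta_obs - 1e-15:
            hits += 1
    return theta_obs, (1 + hits) / (1 + n_perm)


def pairwise_fst(
    table: GenotypeTable,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise theta, linearized values, permutation p, Holm flags."""
    rng = np.random.default_rng(seed)
    groups = table.group_names()
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        theta, p = fst_permutation_p(table, ga, gb, n_perm=n_perm, rng=rng)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "theta": theta,
                "linearized": linearize_fst(theta) if theta != 1.0 else np.nan,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["significant"] = sequential_bonferroni(df["p"].tolist(), alpha=alpha)
    return df


def sequential_bonferroni(p_values: list[float], alpha: float = 0.05) -> list[bool]:
    """Holm step-down correction; returns a reject flag per input p-value."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] < alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject.tolist()


# ---------------------------------------------------------------------------
# temporal pooling
# ---------------------------------------------------------------------------

def pool_temporal_samples(
    table: GenotypeTable,
    site_of_group: dict[str, str],
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Merge same-site temporal samples whose differentiation is non-significant.

    ``site_of_group`` maps each group label (site x year sample) to its site.
    For every within-site pair of temporal samples, theta and a permutation p
    are computed; if no within-site comparison at a site is significant at the
    uncorrected ``alpha``, that site's samples are merged under the site label.
    Returns the (possibly) relabelled table and the comparison report.
    """
    rng = np.random.default_rng(seed)
    by_site: dict[str, list[str]] = {}
    for g in table.group_names():
        by_site.setdefault(site_of_group.get(g, g), []).append(g)
    rows = []
    mapping: dict[str, str] = {}
    for site, gs in by_site.items():
        significant = False
        for ga, gb in itertools.combinations(gs, 2):
            theta, p = fst_permutation_p(table, ga, gb, n_perm=n_perm, rng=rng)
            rows.append(
                {"site": site, "group_a": ga, "group_b": gb, "theta": theta,
                 "linearized": linearize_fst(theta) if theta != 1.0 else np.nan,
                 "p": p}
            )
            if p < alpha:
                significant = True
        if not significant and len(gs) > 1:
            for g in gs:
                mapping[g] = site
    return table.relabel_groups(mapping), pd.DataFrame(rows)
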
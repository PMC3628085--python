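"""Dyadic within- vs between-household inference on distance matrices.

The central statistic contrasts the pairwise community distances of
defined host dyads (couples, parent-child, cohabiting dogs, owner-dog)
inside a household against the same dyad type across households.  All
eligible pairwise distances are ranked jointly and

    R = (mean rank between - mean rank within) / (N / 2),

bounded in [-1, 1]; R > 0 means within-household pairs are more similar.
Significance comes from permuting household labels among eligible
individuals within each role stratum (mothers among mothers, fathers
among fathers, ...), which preserves the dyad structure of every
permuted dataset, with the add-one permutation p-value.

The module also provides one-way PERMANOVA on a distance matrix, the
distance-to-adult-baseline age trajectory, and the normal-approximation
minimal detectable effect size for two-sample comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .io_formats import SampleMetadata

__all__ = [
    "DYAD_CATEGORIES",
    "DyadPairs",
    "DyadTestResult",
    "PermanovaResult",
    "build_dyads",
    "anosim_r",
    "dyad_permutation_test",
    "permanova_oneway",
    "age_trajectory",
    "AgeTrajectoryResult",
    "min_detectable_effect",
]

#: offspring age windows used by the dyad categories (years)
CHILD_AGE_RANGE = (3.0, 18.0)
INFANT_AGE_RANGE = (0.0, 1.0)


# ---------------------------------------------------------------------------
# Dyad construction
# ---------------------------------------------------------------------------

@dataclass
class DyadPairs:
    """Eligible individuals and their within/between sample-pair sets.

    ``ids_a``/``ids_b`` are sample ids of the two dyad sides (identical
    lists for symmetric categories such as ``families`` or ``dogs``);
    ``within``/``between`` are lists of ``(sample_id, sample_id)`` pairs.
    """

    category: str
    ids_a: list[str]
    ids_b: list[str]
    fam_a: list[str]
    fam_b: list[str]
    roles_a: list[str]
    roles_b: list[str]
    symmetric: bool
    within: list[tuple[str, str]] = field(default_factory=list)
    between: list[tuple[str, str]] = field(default_factory=list)


def _one_sample_per_host(metadata: SampleMetadata, site: str,
                         species: str) -> pd.DataFrame:
    df = metadata.at_site(site, species)
    # one sample per host at a site in valid metadata; keep first otherwise
    return df[~df["host_id"].duplicated()]


def _age_in(df: pd.DataFrame, lo: float, hi: float) -> pd.Series:
    return (df["age"] >= lo) & (df["age"] < hi)


def _select(metadata: SampleMetadata, site: str, category: str,
            child_age_range: tuple[float, float],
            infant_age_range: tuple[float, float]):
    """Return (side_a, side_b, symmetric) eligible-sample DataFrames."""
    if category == "families":
        df = _one_sample_per_host(metadata, site, "human")
        dogs = _one_sample_per_host(metadata, site, "dog")
        df = pd.concat([df, dogs]) if len(dogs) else df
        return df, df, True
    if category == "spouses":
        a = _one_sample_per_host(metadata, site, "human")
        return a[a["role"] == "adult_M"], a[a["role"] == "adult_F"], False
    if category in ("father_child", "mother_child", "father_infant", "mother_infant"):
        hum = _one_sample_per_host(metadata, site, "human")
        parent_role = "adult_M" if category.startswith("father") else "adult_F"
        parents = hum[hum["role"] == parent_role]
        if category.endswith("child"):
            lo, hi = child_age_range
            kids = hum[hum["role"].isin(["child", "infant"]) & _age_in(hum, lo, hi)]
        else:
            lo, hi = infant_age_range
            kids = hum[hum["role"].isin(["infant", "child"]) & _age_in(hum, lo, hi)]
        return parents, kids, False
    if category == "dogs":
        d = _one_sample_per_host(metadata, site, "dog")
        return d, d, True
    raise ValueError(f"unknown dyad category {category!r}")


def _owner_dog_pairs(metadata: SampleMetadata, human_site: str, dog_site: str,
                     owners: bool) -> DyadPairs:
    humans = _one_sample_per_host(metadata, human_site, "human")
    adults = humans[humans["role"].isin(["adult_M", "adult_F", "senior"])]
    adults = adults[adults["has_dog"] == owners]
    dogs = _one_sample_per_host(metadata, dog_site, "dog")
    pairs = DyadPairs(
        category="owner_own_dog" if owners else "nonowner_dog",
        ids_a=list(adults.index), ids_b=list(dogs.index),
        fam_a=list(adults["family_id"]), fam_b=list(dogs["family_id"]),
        roles_a=list(adults["role"]), roles_b=list(dogs["role"]),
        symmetric=False)
    for (sa, fa), (sb, fb) in itertools.product(
            zip(pairs.ids_a, pairs.fam_a), zip(pairs.ids_b, pairs.fam_b)):
        (pairs.within if (fa == fb and owners) else pairs.between).append((sa, sb))
    return pairs


def build_dyads(metadata: SampleMetadata, category: str, site: str,
                dog_site: Optional[str] = None,
                child_age_range: tuple[float, float] = CHILD_AGE_RANGE,
                infant_age_range: tuple[float, float] = INFANT_AGE_RANGE,
                ) -> DyadPairs:
    """Within- and between-household sample pairs for one dyad category.

    ``category`` is one of ``families, spouses, father_child,
    mother_child, father_infant, mother_infant, dogs, owner_own_dog,
    owner_other_dog, nonowner_dog``.  For the owner-dog categories,
    ``site`` is the human skin site and ``dog_site`` the dog site
    (defaults to ``site``).  Within pairs share a household; between
    pairs combine the same roles across households.
    """
    if category in ("owner_own_dog", "owner_other_dog"):
        return _owner_dog_pairs(metadata, site, dog_site or site, owners=True)
    if category == "nonowner_dog":
        return _owner_dog_pairs(metadata, site, dog_site or site, owners=False)
    a, b, symmetric = _select(metadata, site, category,
                              child_age_range, infant_age_range)
    fams = set(a["family_id"]) | set(b["family_id"])
    if len(fams) < 2:
        raise ValueError(f"category {category!r} at site {site!r}: "
                         f"fewer than 2 eligible families")
    pairs = DyadPairs(category=category,
                      ids_a=list(a.index), ids_b=list(b.index),
                      fam_a=list(a["family_id"]), fam_b=list(b["family_id"]),
                      roles_a=list(a["role"]), roles_b=list(b["role"]),
                      symmetric=symmetric)
    if symmetric:
        for (i, (sa, fa)), (j, (sb, fb)) in itertools.combinations(
                enumerate(zip(pairs.ids_a, pairs.fam_a)), 2):
            (pairs.within if fa == fb else pairs.between).append((sa, sb))
    else:
        for (sa, fa), (sb, fb) in itertools.product(
                zip(pairs.ids_a, pairs.fam_a), zip(pairs.ids_b, pairs.fam_b)):
            (pairs.within if fa == fb else pairs.between).append((sa, sb))
    if not pairs.within:
        raise ValueError(f"category {category!r} at site {site!r}: no within pairs")
    return pairs


# ---------------------------------------------------------------------------
# ANOSIM-like R and its permutation test
# ---------------------------------------------------------------------------

def anosim_r(within: Sequence[float], between: Sequence[float]) -> float:
    """Rank-based within/between contrast, bounded in [-1, 1].

    All distances are ranked jointly (ties get the average rank);
    R = (mean rank of between - mean rank of within) / (N/2).
    """
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    if within.size == 0 or between.size == 0:
        raise ValueError("both distance sets must be non-empty")
    n = within.size + between.size
    ranks = stats.rankdata(np.concatenate([within, between]))
    return float((ranks[within.size:].mean() - ranks[:within.size].mean()) / (n / 2.0))


def _mean_ci(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    if values.size < 2:
        return mean, 0.0
    return mean, float(1.96 * values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class DyadTestResult:
    category: str
    site: str
    r: float
    p_value: float
    n_within: int
    n_between: int
    mean_within: float
    ci_within: float
    mean_between: float
    ci_between: float
    n_permutations: int
    warning: Optional[str] = None


def dyad_permutation_test(matrix: DistanceMatrix, metadata: SampleMetadata,
                          category: str, site: str, n_perm: int = 10000,
                          seed: int = 0, dog_site: Optional[str] = None,
                          **dyad_kwargs) -> DyadTestResult:
    """Observed R plus a household-label permutation null.

    The permutation unit is the individual's household label within its
    role stratum: each permutation shuffles which household every
    father/mother/child/dog belongs to, the dyads are rebuilt, and R is
    recomputed.  One-sided add-one p-value (alternative: within pairs
    are closer than between pairs).
    """
    pairs = build_dyads(metadata, category, site, dog_site=dog_site, **dyad_kwargs)
    if not pairs.between or not pairs.within:
        raise ValueError("need both within- and between-household pairs")
    idx = {sid: k for k, sid in enumerate(matrix.ids)}
    missing = [s for s in set(pairs.ids_a) | set(pairs.ids_b) if s not in idx]
    if missing:
        raise KeyError(f"sample(s) absent from distance matrix: {missing[:5]}")
    d = matrix.data

    # the pair universe (within + between) is invariant under household
    # relabeling, so rank the universe once and recompute only the
    # within/between split per permutation
    pos_a = {s: k for k, s in enumerate(pairs.ids_a)}
    pos_b = pos_a if pairs.symmetric else {s: k for k, s in enumerate(pairs.ids_b)}
    universe = [(pos_a[a], pos_b[b]) for a, b in pairs.within + pairs.between]
    u_i = np.array([u for u, _ in universe])
    u_j = np.array([v for _, v in universe])
    row = np.array([idx[s] for s in pairs.ids_a])
    col = np.array([idx[s] for s in (pairs.ids_a if pairs.symmetric else pairs.ids_b)])
    dists = d[row[u_i], col[u_j]]
    ranks = stats.rankdata(dists)
    n_pairs = len(universe)

    fam_a = np.array(pairs.fam_a)
    fam_b = fam_a if pairs.symmetric else np.array(pairs.fam_b)
    within_mask = fam_a[u_i] == fam_b[u_j]
    n_w = int(within_mask.sum())
    n_b = n_pairs - n_w

    def r_of(mask: np.ndarray) -> float:
        mw = ranks[mask].mean()
        mb = ranks[~mask].mean()
        return float((mb - mw) / (n_pairs / 2.0))

    r_obs = r_of(within_mask)

    rng = np.random.default_rng([seed, 0xD7AD])
    roles_a = np.array(pairs.roles_a)
    roles_b = roles_a if pairs.symmetric else np.array(pairs.roles_b)
    strata_a = {r: np.nonzero(roles_a == r)[0] for r in np.unique(roles_a)}
    strata_b = None if pairs.symmetric else \
        {r: np.nonzero(roles_b == r)[0] for r in np.unique(roles_b)}

    n_ge = 0
    for _ in range(n_perm):
        pa = fam_a.copy()
        for members in strata_a.values():
            pa[members] = pa[members][rng.permutation(len(members))]
        if pairs.symmetric:
            pb = pa
        else:
            pb = fam_b.copy()
            for members in strata_b.values():
                pb[members] = pb[members][rng.permutation(len(members))]
        mask = pa[u_i] == pb[u_j]
        n_in = mask.sum()
        if n_in == 0 or n_in == n_pairs:
            # degenerate relabeling: no contrast; count as non-exceeding
            continue
        if r_of(mask) >= r_obs:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_perm)

    warning = None
    n_indiv = len(pairs.ids_a) + (0 if pairs.symmetric else len(pairs.ids_b))
    if n_indiv <= 5:  # fewer than ~100 distinct relabelings possible
        import math
        distinct = 1.0
        for members in strata_a.values():
            distinct *= math.factorial(len(members))
        if not pairs.symmetric:
            for members in strata_b.values():
                distinct *= math.factorial(len(members))
        if distinct < 100:
            warning = (f"only ~{int(distinct)} distinct permutations; "
                       "p-value resolution is limited")
            warnings.warn(warning, stacklevel=2)

    mw, cw = _mean_ci(dists[within_mask])
    mb, cb = _mean_ci(dists[~within_mask])
    return DyadTestResult(category=category, site=site, r=r_obs, p_value=p,
                          n_within=n_w, n_between=n_b,
                          mean_within=mw, ci_within=cw,
                          mean_between=mb, ci_between=cb,
                          n_permutations=n_perm, warning=warning)


# ---------------------------------------------------------------------------
# One-way PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    df_between: int
    df_residual: int
    p_value: float
    component_of_variation: float
    n_permutations: int


def _permanova_f(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray):
    n = d2.shape[0]
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in labels:
        members = np.nonzero(groups == g)[0]
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_between = ss_total - ss_within
    return ss_total, ss_within, ss_between


def permanova_oneway(matrix: DistanceMatrix, grouping: Sequence[str],
                     n_perm: int = 999, seed: int = 0) -> PermanovaResult:
    """Pseudo-F partitioning squared distances among vs within groups.

    ``SS_total = (1/N) sum_{i<j} d_ij^2``; ``SS_within`` sums the same
    quantity per group; the p-value comes from ``n_perm`` label
    permutations (default 999).  The component of variation is the
    usual variance-component estimate
    ``(MS_between - MS_within) / n_bar`` with ``n_bar`` the average
    group size.
    """
    groups = np.asarray(list(grouping))
    n = matrix.shape[0]
    if len(groups) != n:
        raise ValueError("grouping length != matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    a = len(labels)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n <= a:
        raise ValueError("need more samples than groups")
    d2 = matrix.data ** 2

    ss_total, ss_within, ss_between = _permanova_f(d2, groups, labels)
    df_b, df_r = a - 1, n - a
    ms_b, ms_w = ss_between / df_b, ss_within / df_r
    if ss_within <= 0:
        f_obs = np.inf
    else:
        f_obs = ms_b / ms_w
    n_bar = n / a
    component = (ms_b - ms_w) / n_bar

    rng = np.random.default_rng([seed, 0xF])
    n_ge = 0
    for _ in range(n_perm):
        perm = groups[rng.permutation(n)]
        _, ssw, ssb = _permanova_f(d2, perm, labels)
        f_perm = np.inf if ssw <= 0 else (ssb / df_b) / (ssw / df_r)
        if f_perm >= f_obs:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), df_between=df_b,
                           df_residual=df_r, p_value=p,
                           component_of_variation=float(component),
                           n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Age trajectory toward the adult baseline
# ---------------------------------------------------------------------------

@dataclass
class AgeTrajectoryResult:
    per_participant: pd.DataFrame     # host_id, age, mean_distance, n_baseline
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def age_trajectory(matrix: DistanceMatrix, metadata: SampleMetadata, site: str,
                   baseline_age: tuple[float, float] = (30.0, 45.0),
                   target_ages: Optional[Callable[[float], bool]] = None,
                   include_own_family: bool = False) -> AgeTrajectoryResult:
    """Mean distance of each participant to baseline-aged adults, vs age.

    For every human participant with a sample at ``site``, average the
    distance between their sample and all same-site samples of adults in
    the ``baseline_age`` window (excluding the participant themself and,
    by default, their own household), then fit an ordinary
    least-squares line of mean distance against age.
    """
    df = _one_sample_per_host(metadata, site, "human")
    idx = {sid: k for k, sid in enumerate(matrix.ids)}
    df = df[[s in idx for s in df.index]]
    lo, hi = baseline_age
    base = df[(df["age"] >= lo) & (df["age"] <= hi)]
    if len(base) < 2:
        raise ValueError("need at least 2 baseline adults")
    rows = []
    d = matrix.data
    for sid, row in df.iterrows():
        if target_ages is not None and not target_ages(float(row["age"])):
            continue
        pool = base[base.index != sid]
        if not include_own_family:
            pool = pool[pool["family_id"] != row["family_id"]]
        if len(pool) == 0:
            continue
        dists = d[idx[sid], [idx[s] for s in pool.index]]
        rows.append({"host_id": row["host_id"], "age": float(row["age"]),
                     "mean_distance": float(np.mean(dists)),
                     "n_baseline": len(pool)})
    per = pd.DataFrame(rows)
    if len(per) < 3:
        raise ValueError("too few participants for a regression")
    if np.allclose(per["mean_distance"].var(), 0.0):
        # flat response: slope 0, no explained variance
        return AgeTrajectoryResult(per, 0.0, float(per["mean_distance"].iloc[0]),
                                   0.0, 1.0)
    fit = stats.linregress(per["age"], per["mean_distance"])
    return AgeTrajectoryResult(per, float(fit.slope), float(fit.intercept),
                               float(fit.rvalue ** 2), float(fit.pvalue))


# ---------------------------------------------------------------------------
# Power / minimal detectable effect
# ---------------------------------------------------------------------------

def min_detectable_effect(n1: int, n2: int, alpha: float = 0.05,
                          power: float = 0.90) -> float:
    """Normal-approximation minimal detectable Cohen's d for two samples.

    ``d = (z_{1-alpha/2} + z_{power}) * sqrt(1/n1 + 1/n2)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("n1 and n2 must be >= 2")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return float(z * np.sqrt(1.0 / n1 + 1.0 / n2))


DYAD_CATEGORIES = ("families", "spouses", "father_child", "mother_child",
                   "father_infant", "mother_infant", "dogs",
                   "owner_own_dog", "owner_other_dog", "nonowner_dog")
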
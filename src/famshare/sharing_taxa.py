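"""Shared-phylotype accounting and family-rank taxon summaries.

Sharing between two samples is presence-based: the number of OTUs with
at least one read in both.  Counting is intended for tables rarefied to
a common depth so richness differences do not masquerade as sharing
differences (a warning, not an error, when depths are unequal).

Taxon summaries collapse OTU counts to the taxonomy family rank as
percentages of each sample, retain families whose grand-mean abundance
exceeds a threshold (default 1%), and test each retained family across
age groups with a one-way ANOVA, Bonferroni-corrected over families.
Wilcoxon rank-sum comparisons use the exact distribution below 25 total
observations and the continuity-corrected normal approximation above.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OtuTable, SampleMetadata, family_rank

__all__ = [
    "shared_phylotypes",
    "shared_phylotype_counts",
    "SharedPhylotypeResult",
    "shared_by_taxon_family",
    "group_sharing_comparison",
    "collapse_to_family",
    "TaxonSummary",
    "taxon_age_anova",
    "AGE_GROUPS",
    "age_group_of",
]

#: age-group bins in years: [lo, hi)
AGE_GROUPS = {
    "infant": (0.0, 1.0),
    "child": (1.0, 18.0),
    "adult": (18.0, 60.0),
    "senior": (60.0, float("inf")),
}


def age_group_of(age: float) -> str:
    for name, (lo, hi) in AGE_GROUPS.items():
        if lo <= age < hi:
            return name
    raise ValueError(f"age {age} outside all bins")


def _warn_unequal_depths(table: OtuTable) -> None:
    depths = table.depths()
    if depths.size and depths.min() != depths.max():
        warnings.warn("samples have unequal depths; shared-phylotype counts "
                      "are intended for rarefied tables", stacklevel=3)


# ---------------------------------------------------------------------------
# Shared phylotypes
# ---------------------------------------------------------------------------

def shared_phylotypes(table: OtuTable, sample_i: str, sample_j: str) -> int:
    """Number of OTUs with count >= 1 in both samples."""
    _warn_unequal_depths(table)
    pres = table.presence()
    ii, jj = table.sample_index(sample_i), table.sample_index(sample_j)
    return int(np.sum(pres[:, ii] & pres[:, jj]))


def shared_phylotype_counts(table: OtuTable,
                            pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """Vector of shared-phylotype counts, one per pair."""
    _warn_unequal_depths(table)
    pres = table.presence()
    idx = {s: k for k, s in enumerate(table.sample_ids)}
    return np.array([int(np.sum(pres[:, idx[a]] & pres[:, idx[b]]))
                     for a, b in pairs])


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p; exact below 25 total observations."""
    if x.size == 0 or y.size == 0:
        return float("nan")
    method = "exact" if x.size + y.size < 25 else "asymptotic"
    try:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method=method).pvalue)
    except ValueError:
        return 1.0  # all values identical


@dataclass
class SharedPhylotypeResult:
    """Per taxon family: shared-count means for within vs between pairs."""

    per_pair_total: pd.DataFrame          # pair, group, shared
    per_family: pd.DataFrame              # family x (means, CIs, p, significant)
    n_within: int
    n_between: int


def shared_by_taxon_family(table: OtuTable,
                           within: Sequence[tuple[str, str]],
                           between: Sequence[tuple[str, str]],
                           alpha: float = 0.05) -> SharedPhylotypeResult:
    """Shared-OTU counts partitioned by taxonomy family, within vs between.

    For every taxonomy family, shared counts are compared across the two
    pair groups with a two-sided rank-sum test, Bonferroni-corrected
    over families.  The per-family counts of a pair always sum to its
    total shared count.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy; use shared_phylotypes / "
                         "shared_phylotype_counts instead")
    _warn_unequal_depths(table)
    families = [family_rank(t) or "unclassified" for t in table.taxonomy]
    fam_labels = sorted(set(families))
    fam_idx = {f: i for i, f in enumerate(fam_labels)}
    fam_of_otu = np.array([fam_idx[f] for f in families])
    pres = table.presence()
    idx = {s: k for k, s in enumerate(table.sample_ids)}

    def counts_for(pairs):
        out = np.zeros((len(pairs), len(fam_labels)), dtype=int)
        for r, (a, b) in enumerate(pairs):
            both = pres[:, idx[a]] & pres[:, idx[b]]
            np.add.at(out[r], fam_of_otu[both], 1)
        return out

    cw = counts_for(list(within))
    cb = counts_for(list(between))
    rows = []
    m = len(fam_labels)
    for i, fam in enumerate(fam_labels):
        p = _rank_sum_p(cw[:, i], cb[:, i])
        p_adj = min(1.0, p * m) if np.isfinite(p) else p
        mw, hw = _mean_ci(cw[:, i])
        mb, hb = _mean_ci(cb[:, i])
        rows.append({"family": fam, "mean_within": mw, "ci_within": hw,
                     "mean_between": mb, "ci_between": hb,
                     "p_value": p, "p_bonferroni": p_adj,
                     "significant": bool(p_adj < alpha)})
    per_family = pd.DataFrame(rows).set_index("family")
    totals = pd.DataFrame({
        "pair": [f"{a}|{b}" for a, b in list(within) + list(between)],
        "group": ["within"] * len(cw) + ["between"] * len(cb),
        "shared": np.concatenate([cw.sum(axis=1), cb.sum(axis=1)]),
    })
    return SharedPhylotypeResult(totals, per_family, len(cw), len(cb))


def _mean_ci(values) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    if values.size < 2:
        return mean, 0.0
    return mean, float(1.96 * values.std(ddof=1) / np.sqrt(values.size))


def group_sharing_comparison(table: OtuTable, metadata: SampleMetadata,
                             site: str = "palm_R",
                             alpha: float = 0.05) -> pd.DataFrame:
    """Shared-phylotype counts across cohabitation x dog-ownership strata.

    Adult pairs at one skin site are stratified into cohabiting/non-
    cohabiting crossed with both-own-dogs/neither-owns-dogs; strata
    means with 95% CIs plus Bonferroni-corrected rank-sum contrasts.
    Empty strata are skipped with a warning.
    """
    df = metadata.at_site(site, "human")
    adults = df[df["role"].isin(["adult_M", "adult_F", "senior"])]
    adults = adults[~adults["host_id"].duplicated()]
    ids = list(adults.index)
    fam = adults["family_id"].to_dict()
    dog = adults["has_dog"].to_dict()
    strata: dict[str, list[tuple[str, str]]] = {
        "cohab_dog": [], "cohab_nodog": [], "noncohab_dog": [], "noncohab_nodog": []}
    for a, b in itertools.combinations(ids, 2):
        if dog[a] != dog[b]:
            continue  # mixed-ownership pairs are not part of the contrast
        key = ("cohab" if fam[a] == fam[b] else "noncohab") + \
            ("_dog" if dog[a] else "_nodog")
        strata[key].append((a, b))

    shared = {k: shared_phylotype_counts(table, v) if v else np.array([], dtype=int)
              for k, v in strata.items()}
    populated = {k: v for k, v in shared.items() if v.size >= 2}
    for k in strata:
        if k not in populated:
            warnings.warn(f"stratum {k!r} has <2 pairs; skipped", stacklevel=2)

    contrasts = list(itertools.combinations(sorted(populated), 2))
    m = max(1, len(contrasts))
    rows = []
    for k in sorted(populated):
        mean, ci = _mean_ci(populated[k])
        rows.append({"stratum": k, "kind": "group", "n_pairs": populated[k].size,
                     "mean_shared": mean, "ci": ci, "p_bonferroni": np.nan})
    for a, b in contrasts:
        p = _rank_sum_p(populated[a], populated[b])
        rows.append({"stratum": f"{a} vs {b}", "kind": "contrast",
                     "n_pairs": populated[a].size + populated[b].size,
                     "mean_shared": np.nan, "ci": np.nan,
                     "p_bonferroni": min(1.0, p * m)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Family-rank collapse and age-group ANOVA
# ---------------------------------------------------------------------------

def collapse_to_family(table: OtuTable) -> pd.DataFrame:
    """Relative abundance (%) per taxonomy family per sample.

    Counts are summed over OTUs sharing a family label (OTUs without a
    family rank pool into ``unclassified``) and converted to percent of
    each sample's total; per-sample percentages sum to 100 for non-empty
    samples.
    """
    if table.taxonomy is None:
        raise ValueError("table has no taxonomy")
    families = [family_rank(t) or "unclassified" for t in table.taxonomy]
    df = pd.DataFrame(table.counts, index=pd.Index(families, name="family"),
                      columns=table.sample_ids)
    sums = df.groupby(level="family").sum()
    totals = sums.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = sums.div(totals.where(totals > 0), axis=1) * 100.0
    return pct.fillna(0.0)


@dataclass
class TaxonSummary:
    family: str
    group_means: dict[str, float]         # % per group
    f_statistic: float
    p_value: float
    p_bonferroni: float
    significant: bool
    degenerate: bool = False


def taxon_age_anova(family_table: pd.DataFrame, metadata: SampleMetadata,
                    groups: Optional[dict[str, tuple[float, float]]] = None,
                    min_abundance: float = 1.0, alpha: float = 0.05,
                    per_group_filter: bool = False) -> list[TaxonSummary]:
    """One-way ANOVA of family-rank % abundance across host age groups.

    ``family_table`` is the output of :func:`collapse_to_family`
    restricted (by its columns) to the samples of one body site.  Only
    families whose grand-mean abundance exceeds ``min_abundance`` % are
    tested (or whose mean in any single group exceeds it, with
    ``per_group_filter``); Bonferroni correction spans the retained
    families.
    """
    groups = groups or AGE_GROUPS
    meta = metadata.frame.loc[[s for s in family_table.columns
                               if s in metadata.frame.index]]
    meta = meta[meta["species"] == "human"]
    sample_groups: dict[str, list[str]] = {g: [] for g in groups}
    for sid, row in meta.iterrows():
        for g, (lo, hi) in groups.items():
            if lo <= float(row["age"]) < hi:
                sample_groups[g].append(sid)
                break
    sample_groups = {g: s for g, s in sample_groups.items() if len(s) >= 2}
    if len(sample_groups) < 2:
        raise ValueError("need >= 2 age groups with >= 2 samples each")

    used = [s for ss in sample_groups.values() for s in ss]
    sub = family_table[used]
    if per_group_filter:
        keep = [f for f in sub.index
                if any(sub.loc[f, ss].mean() > min_abundance
                       for ss in sample_groups.values())]
    else:
        keep = [f for f in sub.index if sub.loc[f].mean() > min_abundance]
    m = len(keep)
    out = []
    for fam in keep:
        arrays = [sub.loc[fam, ss].to_numpy(dtype=float)
                  for ss in sample_groups.values()]
        means = {g: float(np.mean(a)) for g, a in zip(sample_groups, arrays)}
        degenerate = all(np.ptp(a) == 0 for a in arrays)
        if degenerate:
            f_stat, p = float("nan"), 1.0
        else:
            f_stat, p = stats.f_oneway(*arrays)
            f_stat, p = float(f_stat), float(p)
        p_adj = min(1.0, p * m)
        out.append(TaxonSummary(family=fam, group_means=means,
                                f_statistic=f_stat, p_value=p,
                                p_bonferroni=p_adj,
                                significant=bool(p_adj < alpha),
                                degenerate=degenerate))
    out.sort(key=lambda t: t.p_value)
    return out
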
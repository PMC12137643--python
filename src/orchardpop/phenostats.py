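"""Descriptive trait statistics and cluster-vs-rest phenotype tests.

Covers the comparisons run on an orchard diversity panel: the Spearman
correlation matrix over taste traits with a significance mask, the
normality-gated two-group test (Student's t when both groups pass
Shapiro-Wilk, Mann-Whitney U otherwise), mean-based sugar component ratios,
and the flowering-date distribution summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PhenotypeTable


@dataclass
class SpearmanResult:
    rho: pd.DataFrame
    p: pd.DataFrame
    not_significant: pd.DataFrame  # True where p >= alpha


def spearman_matrix(
    phenotypes: PhenotypeTable,
    traits: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    year=None,
) -> SpearmanResult:
    """Pairwise Spearman correlations with pairwise-complete observations.

    Pairs with fewer than 3 joint observations get NaN.  The mask marks
    correlations that do not reach significance at ``alpha``.
    """
    traits = list(traits) if traits is not None else phenotypes.traits
    wide = pd.DataFrame({t: phenotypes.values(t, year=year) for t in traits})
    k = len(traits)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = wide.iloc[:, [i, j]].dropna()
            if len(sub) < 3:
                rho[i, j] = rho[j, i] = np.nan
                pmat[i, j] = pmat[j, i] = np.nan
                continue
            r, p = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    rho_df = pd.DataFrame(rho, index=traits, columns=traits)
    p_df = pd.DataFrame(pmat, index=traits, columns=traits)
    return SpearmanResult(rho=rho_df, p=p_df, not_significant=p_df >= alpha)


@dataclass
class GroupTest:
    test: str  # "t" | "mannwhitney"
    statistic: float
    p: float
    n_cluster: int
    n_rest: int


def cluster_vs_rest(
    phenotypes: PhenotypeTable,
    trait: str,
    cluster_members: Sequence,
    rest: Optional[Sequence] = None,
    alpha_normality: float = 0.05,
    year=None,
) -> GroupTest:
    """Two-sided cluster-vs-rest comparison with a normality gate.

    Shapiro-Wilk is run on each group at ``alpha_normality``; if both
    groups look normal a Student's t-test is used, otherwise the
    Mann-Whitney U test.
    """
    values = phenotypes.values(trait, year=year)
    members = [m for m in cluster_members if m in values.index]
    a = values.reindex(members).dropna().to_numpy()
    if rest is None:
        rest = [s for s in values.index if s not in set(cluster_members)]
    b = values.reindex(rest).dropna().to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 phenotyped members per group")
    norm_a = stats.shapiro(a).pvalue >= alpha_normality
    norm_b = stats.shapiro(b).pvalue >= alpha_normality
    if norm_a and norm_b:
        s, p = stats.ttest_ind(a, b)
        name = "t"
    else:
        s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mannwhitney"
    return GroupTest(test=name, statistic=float(s), p=float(p),
                     n_cluster=len(a), n_rest=len(b))


@dataclass
class TraitSummary:
    per_trait: pd.DataFrame  # trait, n, mean, median, iqr
    sugar_ratio: str  # "suc:glu:fru:1" normalised to sorbitol
    malate_citrate_range: tuple  # (min, max) per-sample ratio


def trait_summary(
    phenotypes: PhenotypeTable,
    sugar_components: Sequence[str] = ("sucrose", "glucose", "fructose", "sorbitol"),
    year=None,
) -> TraitSummary:
    """Per-trait descriptive statistics plus the canonical component ratios.

    The sugar ratio divides each component's mean by the last component's
    mean (rendered to 2 decimals, last term '1'); the malate/citrate range
    is over samples with both acids measured.
    """
    rows = []
    for t in phenotypes.traits:
        v = phenotypes.values(t, year=year).dropna()
        if v.empty:
            continue
        q1, q3 = np.percentile(v, [25, 75])
        rows.append(dict(trait=t, n=len(v), mean=v.mean(), median=v.median(),
                         iqr=q3 - q1))
    per_trait = pd.DataFrame(rows)

    means = [phenotypes.values(c, year=year).mean() for c in sugar_components]
    base = means[-1]
    if base and not np.isnan(base):
        terms = [f"{m / base:.2f}" for m in means[:-1]] + ["1"]
        sugar_ratio = ":".join(terms)
    else:
        sugar_ratio = ""

    mal = phenotypes.values("malate", year=year)
    cit = phenotypes.values("citrate", year=year)
    joint = pd.concat([mal, cit], axis=1, keys=["mal", "cit"]).dropna()
    joint = joint[joint["cit"] != 0]
    if joint.empty:
        mc_range = (np.nan, np.nan)
    else:
        ratios = joint["mal"] / joint["cit"]
        mc_range = (float(ratios.min()), float(ratios.max()))
    return TraitSummary(per_trait=per_trait, sugar_ratio=sugar_ratio,
                        malate_citrate_range=mc_range)


@dataclass
class FloweringDistribution:
    counts: pd.Series  # day-of-year -> number of accessions
    peak_day: int
    peak_share: float  # fraction flowering on the peak day
    span_days: int


def flowering_distribution(phenotypes: PhenotypeTable, year=None) -> FloweringDistribution:
    """Histogram of flowering day-of-year with peak-day share."""
    v = phenotypes.values("flowering_date", year=year).dropna().astype(int)
    if v.empty:
        raise ValueError("no flowering dates")
    counts = v.value_counts().sort_index()
    peak_day = int(counts.idxmax())
    return FloweringDistribution(
        counts=counts,
        peak_day=peak_day,
        peak_share=float(counts.max() / counts.sum()),
        span_days=int(counts.index.max() - counts.index.min()),
    )
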
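"""Two-population windowed selection scan.

The windowing protocol — MAF >= 5% filter, 50 kb windows on a 10 kb step,
at least five SNPs per window, top 1% of window scores — frames a pluggable
per-SNP statistic.  The default statistic is normalised allele-frequency
differentiation d = (p1 - p2)^2 / (pbar (1 - pbar)), symmetric in the two
populations; any callable with the same signature can be substituted (for
instance a composite-likelihood sweep score) without touching the
windowing machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix
from .ibd import nearest_rank_quantile


def maf_filter(genotypes: GenotypeMatrix, min_maf: float = 0.05) -> np.ndarray:
    """Keep variants with pooled minor allele frequency >= ``min_maf``
    (strictly below the floor is removed; monomorphic sites always go)."""
    p = genotypes.alt_freq()
    maf = np.minimum(p, 1 - p)
    return np.nan_to_num(maf, nan=-1.0) >= min_maf


def freq_differentiation(p1: np.ndarray, p2: np.ndarray, n1, n2) -> np.ndarray:
    """Default per-SNP statistic: squared frequency difference normalised
    by pooled-heterozygosity, d = (p1 - p2)^2 / (pbar (1 - pbar))."""
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    denom = pbar * (1 - pbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (p1 - p2) ** 2 / denom
    d[~np.isfinite(d)] = np.nan
    return d


@dataclass
class WindowScore:
    chrom: str
    start: int
    end: int
    n_snps: int
    score: float  # NaN when n_snps < min_snps


def window_scan(
    genotypes: GenotypeMatrix,
    pop_a: Sequence,
    pop_b: Sequence,
    chrom: np.ndarray,
    pos: np.ndarray,
    window: int = 50_000,
    step: int = 10_000,
    min_snps: int = 5,
    statistic: Optional[Callable] = None,
) -> pd.DataFrame:
    """Sliding-window scan of a two-population differentiation statistic.

    Window raw score = mean per-SNP statistic over the window's SNPs;
    windows with fewer than ``min_snps`` SNPs carry a NaN score and are
    excluded from percentile ranking.  Frequencies are estimated by allele
    counting with missing-call exclusion.
    """
    ia = [genotypes.samples.index(s) for s in pop_a]
    ib = [genotypes.samples.index(s) for s in pop_b]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each population needs at least 2 samples")
    stat = statistic or freq_differentiation
    with np.errstate(invalid="ignore"):
        p1 = np.nanmean(genotypes.dosages[ia, :], axis=0) / 2.0
        p2 = np.nanmean(genotypes.dosages[ib, :], axis=0) / 2.0
    d = stat(p1, p2, len(ia), len(ib))

    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    rows = []
    for c in pd.unique(chrom):
        on = chrom == c
        p = pos[on]
        dc = d[on]
        if len(p) == 0:
            continue
        last = int(p.max())
        for start in range(0, last + 1, step):
            end = start + window
            in_win = (p >= start) & (p < end)
            vals = dc[in_win]
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            score = float(np.mean(vals)) if n >= min_snps else np.nan
            rows.append(dict(chrom=c, start=start, end=end, n_snps=n, score=score))
            if start + step > last:
                break
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SweepRegion:
    chrom: str
    start: int
    end: int
    max_score: float


def top_regions(windows: pd.DataFrame, top_fraction: float = 0.01) -> list:
    """Candidate selective regions from the top-scoring windows.

    The cutoff is the (1 - top_fraction) nearest-rank quantile of the
    scored windows; windows at or above it are kept and overlapping or
    book-ended windows merge into regions.
    """
    scored = windows.dropna(subset=["score"])
    if scored.empty:
        return []
    cutoff = nearest_rank_quantile(scored["score"].to_numpy(), 1.0 - top_fraction)
    keep = scored[scored["score"] >= cutoff].sort_values(["chrom", "start"])
    regions = []
    cur = None
    for _, w in keep.iterrows():
        if cur is not None and w["chrom"] == cur[0] and w["start"] <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], int(w["end"])), max(cur[3], w["score"]))
        else:
            if cur is not None:
                regions.append(SweepRegion(*cur))
            cur = (w["chrom"], int(w["start"]), int(w["end"]), float(w["score"]))
    if cur is not None:
        regions.append(SweepRegion(*cur))
    return regions
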
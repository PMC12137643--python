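"""IBD-segment calling from phased haplotypes and shared-region discovery.

The caller is a deterministic identity-by-state run finder: for each sample
pair and each of the four haplotype combinations, maximal marker runs of
identity (with a small mismatch allowance) become candidate segments, which
are merged across combinations.  Externally produced RefinedIBD segment
files (see :func:`orchardpop.io.read_refined_ibd`) can be used in place of
the caller.

Shared regions within a kinship cluster are found by piling the cluster's
pairwise segments into fixed-width genomic bins and keeping the top decile
of bin coverage counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import HAP_MISSING, GenotypeMatrix, IBDSegment


# ---------------------------------------------------------------------------
# IBS-run segment caller
# ---------------------------------------------------------------------------

def _runs_with_mismatch(match: np.ndarray, g: int) -> list:
    """Maximal [start, end) index runs containing at most ``g`` False
    entries, never starting or ending on a mismatch."""
    runs = []
    n = len(match)
    i = 0
    while i < n:
        if not match[i]:
            i += 1
            continue
        j = i
        mismatches = 0
        last_good = i
        k = i
        while k < n:
            if match[k]:
                last_good = k
                k += 1
            else:
                if mismatches < g:
                    mismatches += 1
                    k += 1
                else:
                    break
        runs.append((i, last_good + 1))
        i = last_good + 1
    return runs


def call_ibd_segments(
    genotypes: GenotypeMatrix,
    chrom: np.ndarray,
    pos: np.ndarray,
    min_bp: int = 500_000,
    min_markers: int = 25,
    max_mismatch: int = 1,
    pairs: Optional[Sequence] = None,
) -> list:
    """Call pairwise IBD segments as long identical haplotype runs.

    For each pair of samples and each of the four haplotype combinations,
    maximal runs of marker identity (allowing ``max_mismatch`` isolated
    mismatches per run; missing alleles count as mismatches) are collected
    per chromosome, filtered to >= ``min_bp`` and >= ``min_markers``, and
    merged across combinations into union intervals per pair.

    Raises on unphased input — supply RefinedIBD output instead.
    """
    if genotypes.phased is None:
        raise ValueError(
            "call_ibd_segments requires phased haplotypes; "
            "for unphased data read RefinedIBD segment files instead"
        )
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    samples = genotypes.samples
    H = genotypes.phased
    ok = H != HAP_MISSING

    chrom_idx = [(c, np.flatnonzero(chrom == c)) for c in pd.unique(chrom)]
    if pairs is None:
        pairs = [
            (samples[i], samples[j])
            for i in range(len(samples))
            for j in range(i + 1, len(samples))
        ]

    segments = []
    for a, b in pairs:
        ia, ib = samples.index(a), samples.index(b)
        raw = []  # (chrom, start_idx, end_idx) in global marker indices
        for ha in (2 * ia, 2 * ia + 1):
            for hb in (2 * ib, 2 * ib + 1):
                m = (H[ha] == H[hb]) & ok[ha] & ok[hb]
                for c, idx in chrom_idx:
                    for s, e in _runs_with_mismatch(m[idx], max_mismatch):
                        gi, ge = idx[s], idx[e - 1]
                        n_markers = e - s
                        length = int(pos[ge]) + 1 - int(pos[gi])
                        if length >= min_bp and n_markers >= min_markers:
                            raw.append((c, int(pos[gi]), int(pos[ge]) + 1, n_markers))
        # union-merge across haplotype combinations
        by_chrom: dict = {}
        for c, s, e, nm in raw:
            by_chrom.setdefault(c, []).append((s, e, nm))
        for c, ivals in by_chrom.items():
            ivals.sort()
            merged = []
            for s, e, nm in ivals:
                if merged and s <= merged[-1][1]:
                    ps, pe, pnm = merged[-1]
                    merged[-1] = (ps, max(pe, e), max(pnm, nm))
                else:
                    merged.append((s, e, nm))
            for s, e, nm in merged:
                segments.append(
                    IBDSegment(sample_a=str(a), sample_b=str(b), chrom=str(c),
                               start=s, end=e, score=float(nm))
                )
    segments.sort(key=lambda s: (s.chrom, s.start, s.sample_a, s.sample_b))
    return segments


# ---------------------------------------------------------------------------
# Pileup and shared regions
# ---------------------------------------------------------------------------

@dataclass
class IBDPileup:
    """Per-bin counts of distinct within-cluster pairs whose IBD segment
    covers the bin midpoint."""

    bin_bp: int
    counts: dict  # chrom -> np.ndarray of pair counts
    n_pairs: int


def ibd_pileup(
    segments: Sequence[IBDSegment],
    cluster_members: Sequence,
    bin_bp: int = 10_000,
    chrom_lengths: Optional[dict] = None,
) -> IBDPileup:
    """Pile within-cluster pairwise segments into genomic bins.

    A bin is covered by a pair when any of the pair's segments contains the
    bin midpoint; each pair counts once per bin.
    """
    members = set(str(m) for m in cluster_members)
    if len(members) < 2:
        raise ValueError("cluster needs at least 2 members")
    segs = [
        s for s in segments
        if str(s.sample_a) in members and str(s.sample_b) in members
    ]
    if chrom_lengths is None:
        chrom_lengths = {}
        for s in segs:
            chrom_lengths[s.chrom] = max(chrom_lengths.get(s.chrom, 0), s.end)

    counts = {
        c: np.zeros(int(np.ceil(L / bin_bp)), dtype=int)
        for c, L in chrom_lengths.items()
    }
    covered: dict = {c: {} for c in counts}
    for s in segs:
        if s.chrom not in counts:
            continue
        arr = counts[s.chrom]
        nbins = len(arr)
        for b in range(nbins):
            mid = b * bin_bp + bin_bp / 2
            if s.start <= mid < s.end:
                covered[s.chrom].setdefault(b, set()).add(s.pair)
    for c, d in covered.items():
        for b, pairs_at in d.items():
            counts[c][b] = len(pairs_at)
    pairs_seen = {s.pair for s in segs}
    return IBDPileup(bin_bp=bin_bp, counts=counts, n_pairs=len(pairs_seen))


@dataclass(frozen=True)
class SharedIBDRegion:
    cluster_id: str
    chrom: str
    start: int
    end: int
    frequency: int  # max pair count over the region's bins
    percentile: float


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Lower nearest-rank quantile: the element at floor(q * n) of the
    ascending sort (clamped), chosen for determinism."""
    v = np.sort(np.asarray(values))
    if len(v) == 0:
        raise ValueError("empty value set")
    idx = min(int(np.floor(q * len(v))), len(v) - 1)
    return float(v[idx])


def shared_regions(
    pileup: IBDPileup,
    top_fraction: float = 0.10,
    cluster_id: str = "Clr1",
) -> list:
    """Top-decile shared IBD regions of a cluster.

    The coverage threshold is the (1 - top_fraction) nearest-rank quantile
    of the *positive* bin counts; bins at or above it are kept and adjacent
    kept bins merge into regions.  An all-zero pileup yields no regions.
    """
    positive = np.concatenate([c[c > 0] for c in pileup.counts.values()]) \
        if pileup.counts else np.array([])
    if len(positive) == 0:
        return []
    threshold = nearest_rank_quantile(positive, 1.0 - top_fraction)
    total_pos = len(positive)
    regions = []
    for chrom, arr in pileup.counts.items():
        keep = arr >= threshold
        b = 0
        while b < len(arr):
            if not keep[b]:
                b += 1
                continue
            start_bin = b
            while b < len(arr) and keep[b]:
                b += 1
            freq = int(arr[start_bin:b].max())
            pct = float(np.mean(positive <= freq))
            regions.append(
                SharedIBDRegion(
                    cluster_id=cluster_id,
                    chrom=chrom,
                    start=start_bin * pileup.bin_bp,
                    end=b * pileup.bin_bp,
                    frequency=freq,
                    percentile=pct,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def overlap_loci(regions: Sequence, intervals: Sequence) -> pd.DataFrame:
    """Overlap table between shared regions and query intervals.

    ``intervals`` holds (name, chrom, start, end) tuples.  Rows report
    overlap length (bp) and Jaccard; zero-overlap pairs are omitted.
    """
    rows = []
    for r in regions:
        for name, chrom, start, end in intervals:
            if chrom != r.chrom:
                continue
            ov = min(r.end, end) - max(r.start, start)
            if ov <= 0:
                continue
            union = max(r.end, end) - min(r.start, start)
            rows.append(
                dict(cluster=r.cluster_id, region_chrom=r.chrom,
                     region_start=r.start, region_end=r.end, interval=name,
                     overlap_bp=int(ov), jaccard=ov / union)
            )
    return pd.DataFrame(
        rows, columns=["cluster", "region_chrom", "region_start", "region_end",
                       "interval", "overlap_bp", "jaccard"]
    )
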
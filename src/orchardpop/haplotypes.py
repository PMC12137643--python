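"""LD blocks, within-block haplotypes, phenotype comparisons, and
haplotype networks.

Block finding is a deterministic greedy extension on composite LD: a block
grows along the map while every new SNP keeps r^2 >= cut with every SNP
already in the block.  Haplotype "frequency" is counted in accessions
carrying the allele string (chromosome-copy counting available by flag);
the network is a minimum-spanning network on Hamming distance that retains
all minimum-weight ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HAP_MISSING, GenotypeMatrix, PhenotypeTable


def ld_r2(genotypes: GenotypeMatrix, i: int, j: int) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors over
    jointly non-missing samples.  NaN with fewer than 3 joint samples or a
    monomorphic vector."""
    a = genotypes.dosages[:, i]
    b = genotypes.dosages[:, j]
    joint = ~np.isnan(a) & ~np.isnan(b)
    if joint.sum() < 3:
        return np.nan
    a, b = a[joint], b[joint]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass(frozen=True)
class LDBlock:
    chrom: str
    variant_indices: tuple  # contiguous map-order indices
    start: int
    end: int  # half-open bp

    @property
    def n_snps(self) -> int:
        return len(self.variant_indices)


def find_blocks(
    genotypes: GenotypeMatrix,
    chrom: np.ndarray,
    pos: np.ndarray,
    cut: float = 0.6,
    region: Optional[tuple] = None,
) -> list:
    """Greedy contiguous LD blocks of >= 2 SNPs.

    Starting from each unassigned SNP, the block extends right while the
    minimum r^2 between the candidate and every current member stays >=
    ``cut``.  ``region`` restricts the scan to (chrom, start, end).
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    order = np.arange(len(pos))
    if region is not None:
        c, s, e = region
        order = order[(chrom == c) & (pos >= s) & (pos < e)]
    blocks = []
    by_chrom: dict = {}
    for k in order:
        by_chrom.setdefault(chrom[k], []).append(k)
    for c, idx in by_chrom.items():
        i = 0
        while i < len(idx):
            members = [idx[i]]
            j = i + 1
            while j < len(idx):
                cand = idx[j]
                r2s = [ld_r2(genotypes, m, cand) for m in members]
                if any(np.isnan(v) or v < cut for v in r2s):
                    break
                members.append(cand)
                j += 1
            if len(members) >= 2:
                blocks.append(
                    LDBlock(
                        chrom=str(c),
                        variant_indices=tuple(members),
                        start=int(pos[members[0]]),
                        end=int(pos[members[-1]]) + 1,
                    )
                )
            i = j if len(members) >= 2 else i + 1
    return blocks


# ---------------------------------------------------------------------------
# Haplotypes within a block
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    name: str
    alleles: str  # e.g. "01101"
    carriers: list  # accessions carrying >= 1 copy
    count: int  # in accessions by default (copies when count_by="copies")
    frequency: float  # count / total retained


def build_haplotypes(
    genotypes: GenotypeMatrix,
    block: LDBlock,
    min_count: int = 2,
    count_by: str = "accessions",
) -> list:
    """Distinct allele strings over a block's SNPs, ordered Hap1, Hap2, ...
    by descending frequency.

    Haplotype copies containing a missing allele are excluded (logged via
    the carrier lists simply omitting them).  Strings carried by fewer than
    ``min_count`` units (accessions by default) are dropped, and
    frequencies are renormalised over the retained strings.
    """
    if genotypes.phased is None:
        raise ValueError("build_haplotypes needs phased genotypes")
    cols = list(block.variant_indices)
    H = genotypes.phased[:, cols]
    strings: dict = {}
    copy_counts: dict = {}
    for i, sample in enumerate(genotypes.samples):
        for h in (2 * i, 2 * i + 1):
            row = H[h]
            if np.any(row == HAP_MISSING):
                continue
            s = "".join(str(int(a)) for a in row)
            strings.setdefault(s, set()).add(sample)
            copy_counts[s] = copy_counts.get(s, 0) + 1

    entries = []
    for s, carriers in strings.items():
        count = len(carriers) if count_by == "accessions" else copy_counts[s]
        if count >= min_count:
            entries.append((s, sorted(carriers, key=str), count))
    entries.sort(key=lambda e: (-e[2], e[0]))
    total = sum(e[2] for e in entries)
    return [
        Haplotype(name=f"Hap{k}", alleles=s, carriers=c, count=n,
                  frequency=n / total if total else 0.0)
        for k, (s, c, n) in enumerate(entries, start=1)
    ]


# ---------------------------------------------------------------------------
# Phenotype comparison across haplotype groups
# ---------------------------------------------------------------------------

@dataclass
class LsdResult:
    groups: pd.DataFrame  # haplotype, n, mean, letters
    pairwise: pd.DataFrame  # hap_a, hap_b, diff, t, p, significant
    anova_f: float
    anova_p: float


def _letter_display(names, means, sig_matrix):
    """Compact letter display: groups sharing a letter are not
    significantly different.  Standard insert-and-absorb construction."""
    order = np.argsort(-np.asarray(means))
    letters = {names[i]: "" for i in range(len(names))}
    groups = []  # list of sets of indices sharing a letter
    for oi in order:
        placed = False
        for g in groups:
            if all(not sig_matrix[oi][gj] for gj in g):
                g.add(oi)
                placed = True
        if not placed:
            groups.append({oi})
    groups_sorted = sorted(groups, key=lambda g: -max(means[i] for i in g))
    for li, g in enumerate(groups_sorted):
        ch = chr(ord("a") + li)
        for i in g:
            letters[names[i]] += ch
    return letters


def haplotype_phenotype_test(
    haplotypes: Sequence[Haplotype],
    phenotypes: PhenotypeTable,
    trait: str,
    genotypes: Optional[GenotypeMatrix] = None,
    block: Optional[LDBlock] = None,
    alpha: float = 0.05,
    year=None,
) -> LsdResult:
    """One-way ANOVA plus Fisher's least-significant-difference pairwise
    comparisons across haplotype groups.

    Accessions enter a group only when both chromosome copies carry the
    same haplotype (ambiguous heterozygous carriers are excluded) whenever
    phased genotypes and the block are supplied; otherwise all carriers
    are used.  LSD t-tests share the ANOVA's pooled error variance, and a
    compact letter display summarises the separations at ``alpha``.
    """
    values = phenotypes.values(trait, year=year)
    groups = {}
    for hap in haplotypes:
        if genotypes is not None and block is not None:
            members = _homozygous_carriers(genotypes, block, hap)
        else:
            members = hap.carriers
        v = values.reindex(members).dropna().to_numpy()
        if len(v) >= 2:
            groups[hap.name] = v
    if len(groups) < 2:
        raise ValueError("need >= 2 haplotype groups with phenotyped carriers")

    names = list(groups)
    arrays = [groups[g] for g in names]
    f, p_anova = stats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    df_err = n_total - k
    mse = sum(np.sum((a - a.mean()) ** 2) for a in arrays) / df_err

    rows = []
    sig = {i: {j: False for j in range(k)} for i in range(k)}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[i], arrays[j]
            diff = a.mean() - b.mean()
            se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t = diff / se
            pp = 2 * stats.t.sf(abs(t), df_err)
            sig[i][j] = sig[j][i] = pp < alpha
            rows.append(dict(hap_a=names[i], hap_b=names[j], diff=diff,
                             t=t, p=pp, significant=pp < alpha))
    means = np.array([a.mean() for a in arrays])
    letters = _letter_display(names, means, sig)
    gdf = pd.DataFrame(
        dict(haplotype=names, n=[len(a) for a in arrays], mean=means,
             letters=[letters[g] for g in names])
    )
    return LsdResult(groups=gdf, pairwise=pd.DataFrame(rows),
                     anova_f=float(f), anova_p=float(p_anova))


def _homozygous_carriers(genotypes: GenotypeMatrix, block: LDBlock, hap: Haplotype) -> list:
    cols = list(block.variant_indices)
    out = []
    for i, sample in enumerate(genotypes.samples):
        rows = genotypes.phased[np.ix_([2 * i, 2 * i + 1], cols)]
        if np.any(rows == HAP_MISSING):
            continue
        s0 = "".join(str(int(a)) for a in rows[0])
        s1 = "".join(str(int(a)) for a in rows[1])
        if s0 == s1 == hap.alleles:
            out.append(sample)
    return out


# ---------------------------------------------------------------------------
# Haplotype network
# ---------------------------------------------------------------------------

def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotype strings differ in length")
    return sum(x != y for x, y in zip(a, b))


def divergence_percent(a: str, b: str) -> float:
    """Percentage of sites differing between two haplotype strings."""
    return 100.0 * hamming(a, b) / len(a)


def haplotype_network(haplotypes: Sequence[Haplotype]) -> nx.Graph:
    """Minimum-spanning network on Hamming distance.

    Edges are added in increasing weight classes; every edge of a weight
    class whose endpoints lie in different components *at the start of the
    class* is kept, so all minimal ties survive (unlike a plain MST).
    Node attributes carry counts; edge attribute ``mutations`` the
    Hamming distance.
    """
    if len(haplotypes) < 2:
        raise ValueError("need >= 2 haplotypes for a network")
    g = nx.Graph()
    for h in haplotypes:
        g.add_node(h.name, count=h.count, alleles=h.alleles)
    dists = []
    for i, a in enumerate(haplotypes):
        for b in haplotypes[i + 1:]:
            dists.append((hamming(a.alleles, b.alleles), a.name, b.name))
    dists.sort()
    uf = nx.utils.UnionFind([h.name for h in haplotypes])
    for w in sorted({d[0] for d in dists}):
        batch = [d for d in dists if d[0] == w]
        # connectivity frozen at the start of the weight class
        root_before = {h.name: uf[h.name] for h in haplotypes}
        added = []
        for _, a, b in batch:
            if root_before[a] != root_before[b]:
                g.add_edge(a, b, mutations=w)
                added.append((a, b))
        for a, b in added:
            uf.union(a, b)
    return g


# ---------------------------------------------------------------------------
# Cluster-wise haplotype frequencies
# ---------------------------------------------------------------------------

def cluster_haplotype_freq(
    genotypes: GenotypeMatrix,
    block: LDBlock,
    haplotypes: Sequence[Haplotype],
    clusters: dict,
) -> pd.DataFrame:
    """Per-cluster share of accessions carrying each retained haplotype.

    An accession homozygous for a haplotype contributes 1 to it; one
    carrying two different retained haplotypes contributes 0.5 to each.
    Copies whose string was filtered out are ignored, and each cluster row
    is normalised to sum to 1 over accessions with >= 1 retained copy.
    """
    by_string = {h.alleles: h.name for h in haplotypes}
    cols = list(block.variant_indices)
    rows = []
    for cid, members in clusters.items():
        weights = {h.name: 0.0 for h in haplotypes}
        total = 0.0
        for sample in members:
            if sample not in genotypes.samples:
                continue
            i = genotypes.samples.index(sample)
            copies = []
            for hrow in (2 * i, 2 * i + 1):
                alleles = genotypes.phased[hrow, cols]
                if np.any(alleles == HAP_MISSING):
                    continue
                s = "".join(str(int(a)) for a in alleles)
                if s in by_string:
                    copies.append(by_string[s])
            if not copies:
                continue
            w = 1.0 / len(copies)
            for name in copies:
                weights[name] += w
            total += 1.0
        if total > 0:
            rows.append(
                dict(cluster=cid,
                     **{name: weights[name] / total for name in weights})
            )
    return pd.DataFrame(rows).set_index("cluster") if rows else pd.DataFrame()
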
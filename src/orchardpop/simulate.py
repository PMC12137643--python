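"""Gene-dropping simulator for multi-family inbred orchard populations.

The generator emulates the statistical structure of an orchard germplasm
panel: a set of founder cultivars with independent variants in
Hardy-Weinberg proportions, descent through a recorded pedigree with
Haldane (no-interference) recombination, clonal "sport" mutants that copy a
parent's diplotype up to a few somatic changes, planted QTLs whose effect
sizes are scaled to target variance shares, and a genotyping-artifact layer
(missing calls, Poisson read depth, depth-driven genotype quality).

Founder-allele descent is recorded during the drop, so the simulator emits
exact identity-by-descent truth alongside the genotypes.

All randomness flows from a single integer seed through named
``numpy.random`` streams, one per operation, so each stage is individually
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    IBDSegment,
    PedigreeTable,
    PhenotypeTable,
    VariantTable,
)

# stable stream ids so adding an operation never shifts another's draws
_STREAMS = {
    "founders": 1,
    "gene_drop": 2,
    "phenotypes": 3,
    "degrade": 4,
    "pedigree": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class QTL:
    """A planted causal variant: index into the variant set, trait name and
    target fraction of phenotypic variance explained."""

    variant_index: int
    trait: str
    pve: float


@dataclass
class SimulationConfig:
    """Parameters of the synthetic population.

    Defaults describe a modest diversity panel: tens of founder cultivars,
    a uniform founder allele-frequency spectrum on [maf_min, 0.5], and a
    constant genetic map of ``recomb_cm_per_mb`` cM/Mb per chromosome
    (Haldane model, no interference).
    """

    n_founders: int = 40
    n_variants: int = 2000
    chrom_lengths: dict = field(default_factory=lambda: {"Chr1": 25_000_000})
    maf_min: float = 0.05
    recomb_cm_per_mb: float = 2.5
    n_mut_sport: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must lie in [0, 0.5]")

    def variant_map(self) -> pd.DataFrame:
        """Evenly spread variant positions over the configured chromosomes,
        proportional to chromosome length."""
        total = sum(self.chrom_lengths.values())
        rows = []
        remaining = self.n_variants
        items = list(self.chrom_lengths.items())
        for k, (chrom, length) in enumerate(items):
            m = (
                remaining
                if k == len(items) - 1
                else int(round(self.n_variants * length / total))
            )
            m = min(m, remaining)
            pos = np.linspace(0, length - 1, m, dtype=np.int64) if m else []
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
            remaining -= m
        return pd.concat(rows, ignore_index=True)


@dataclass
class TruthSet:
    """Ground truth recorded during simulation.

    ``origins`` labels every haplotype cell with the founder haplotype it
    descends from, which makes pairwise IBD exact: two samples are IBD at a
    site when they share an origin label on some haplotype combination.
    """

    samples: list
    origins: np.ndarray  # (2N, M) founder-haplotype labels
    chrom: np.ndarray
    pos: np.ndarray
    pedigree: Optional[PedigreeTable] = None
    qtl_effects: dict = field(default_factory=dict)  # trait -> {index: beta}
    realized_pve: dict = field(default_factory=dict)  # trait -> {index: share}
    true_dosages: Optional[np.ndarray] = None  # pre-degradation genotypes

    def ibd_segments(self, sample_a, sample_b, min_bp: int = 0,
                     merge_gap_markers: int = 0) -> list:
        """Exact IBD segments for a pair from the recorded descent labels.

        A maximal run of consecutive markers where any of the four
        haplotype combinations shares its founder origin becomes one
        segment; bounds are the outermost marker positions of the run
        (half-open at ``pos + 1``).

        ``merge_gap_markers`` expresses the truth at a caller's resolution:
        runs separated by at most that many non-sharing markers are fused,
        matching an identity-run caller that tolerates the same number of
        mismatches (sub-resolution gaps — e.g. two meioses recombining at
        adjacent markers — are invisible to any identity-by-state caller).
        """
        ia, ib = self.samples.index(sample_a), self.samples.index(sample_b)
        a0, a1 = self.origins[2 * ia], self.origins[2 * ia + 1]
        b0, b1 = self.origins[2 * ib], self.origins[2 * ib + 1]
        share = (a0 == b0) | (a0 == b1) | (a1 == b0) | (a1 == b1)
        out = []
        for chrom in pd.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == chrom)
            s = share[idx].copy()
            if merge_gap_markers > 0:
                on = np.flatnonzero(s)
                for u, v in zip(on[:-1], on[1:]):
                    if 0 < v - u - 1 <= merge_gap_markers:
                        s[u:v] = True
            run_start = None
            for k in range(len(idx) + 1):
                on = k < len(idx) and s[k]
                if on and run_start is None:
                    run_start = k
                elif not on and run_start is not None:
                    start = int(self.pos[idx[run_start]])
                    end = int(self.pos[idx[k - 1]]) + 1
                    if end - start >= min_bp:
                        out.append(
                            IBDSegment(
                                sample_a=str(sample_a), sample_b=str(sample_b),
                                chrom=str(chrom), start=start, end=end,
                                score=float(k - run_start),
                            )
                        )
                    run_start = None
        return out


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

def simulate_founders(config: SimulationConfig) -> GenotypeMatrix:
    """Draw founder diplotypes: per-variant ALT frequency uniform on
    [maf_min, 0.5], haplotype alleles i.i.d. Bernoulli (Hardy-Weinberg)."""
    rng = _rng(config.seed, "founders")
    m = config.n_variants
    freqs = rng.uniform(config.maf_min, 0.5, size=m)
    haps = (rng.random((2 * config.n_founders, m)) < freqs).astype(np.int8)
    samples = [f"F{i:03d}" for i in range(config.n_founders)]
    dosages = haps[0::2].astype(float) + haps[1::2]
    return GenotypeMatrix(samples=samples, dosages=dosages, phased=haps)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _meiosis(hap_pair, origin_pair, chrom_bounds, pos, morgans, rng):
    """One gamete: Haldane crossovers (Poisson count, uniform positions),
    applied per chromosome to both allele and origin arrays."""
    gamete = np.empty_like(hap_pair[0])
    origin = np.empty_like(origin_pair[0])
    for (lo, hi), L in zip(chrom_bounds, morgans):
        if hi <= lo:
            continue
        n_x = rng.poisson(L)
        p = pos[lo:hi]
        span = p[-1] - p[0] + 1
        cuts = np.sort(rng.uniform(p[0], p[0] + span, size=n_x)) if n_x else []
        current = rng.integers(2)
        seg_start = lo
        for cut in list(cuts) + [None]:
            seg_end = hi if cut is None else lo + np.searchsorted(p, cut)
            gamete[seg_start:seg_end] = hap_pair[current][seg_start:seg_end]
            origin[seg_start:seg_end] = origin_pair[current][seg_start:seg_end]
            current = 1 - current
            seg_start = seg_end
    return gamete, origin


def gene_drop(
    founders: GenotypeMatrix,
    pedigree: PedigreeTable,
    config: SimulationConfig,
) -> tuple:
    """Drop founder haplotypes through a pedigree.

    Every cross offspring receives one recombinant gamete from each parent;
    sports copy the parent's diplotype and then flip one allele at
    ``config.n_mut_sport`` random sites.  Founder-origin labels ride along
    with the alleles, giving the exact IBD truth in the returned
    :class:`TruthSet`.

    Returns ``(GenotypeMatrix, TruthSet)`` covering founders and all
    pedigree individuals, in pedigree topological order.
    """
    rng = _rng(config.seed, "gene_drop")
    vmap = config.variant_map()
    chrom = vmap["chrom"].to_numpy(dtype=object)
    pos = vmap["pos"].to_numpy()
    if len(pos) != founders.n_variants:
        raise ValueError("config variant map does not match founder matrix")
    if founders.phased is None:
        raise ValueError("gene_drop needs phased founders")

    chrom_bounds, morgans = [], []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        chrom_bounds.append((idx[0], idx[-1] + 1))
        length_bp = config.chrom_lengths[c]
        morgans.append(length_bp / 1e6 * config.recomb_cm_per_mb / 100.0)

    haps = {s: (founders.phased[2 * i].copy(), founders.phased[2 * i + 1].copy())
            for i, s in enumerate(founders.samples)}
    origins = {s: (np.full(len(pos), 2 * i, dtype=np.int32),
                   np.full(len(pos), 2 * i + 1, dtype=np.int32))
               for i, s in enumerate(founders.samples)}

    order = pedigree.topological_order()
    for ind in order:
        if ind in haps:
            continue
        sire, dam = pedigree.parents(ind)
        row = pedigree.df[pedigree.df["individual"] == ind]
        rel = row.iloc[0]["relation_type"] if not row.empty else "cross"
        if rel == "sport":
            parent = sire if sire is not None else dam
            if parent not in haps:
                raise ValueError(f"missing parent {parent} for sport {ind}")
            h = (haps[parent][0].copy(), haps[parent][1].copy())
            o = (origins[parent][0].copy(), origins[parent][1].copy())
            if config.n_mut_sport > 0:
                sites = rng.choice(len(pos), size=min(config.n_mut_sport, len(pos)),
                                   replace=False)
                which = rng.integers(2, size=len(sites))
                for site, w in zip(sites, which):
                    h[w][site] = 1 - h[w][site]
            haps[ind], origins[ind] = h, o
        else:
            if sire is None or dam is None or sire not in haps or dam not in haps:
                raise ValueError(f"missing parent for {ind}")
            g_s, o_s = _meiosis(haps[sire], origins[sire], chrom_bounds, pos,
                                morgans, rng)
            g_d, o_d = _meiosis(haps[dam], origins[dam], chrom_bounds, pos,
                                morgans, rng)
            haps[ind] = (g_s, g_d)
            origins[ind] = (o_s, o_d)

    samples = [s for s in founders.samples] + [s for s in order if s not in founders.samples]
    phased = np.vstack([np.vstack(haps[s]) for s in samples]).astype(np.int8)
    dosages = phased[0::2].astype(float) + phased[1::2]
    genotypes = GenotypeMatrix(samples=samples, dosages=dosages, phased=phased)
    origin_mat = np.vstack([np.vstack(origins[s]) for s in samples])
    truth = TruthSet(samples=samples, origins=origin_mat, chrom=chrom, pos=pos,
                     pedigree=pedigree)
    return genotypes, truth


def random_pedigree(
    founder_ids,
    n_generations: int = 2,
    offspring_per_cross: int = 2,
    n_sports: int = 0,
    seed: int = 0,
) -> PedigreeTable:
    """A simple pedigree script: random founder crosses per generation,
    optionally decorated with sport mutants of random individuals."""
    rng = _rng(seed, "pedigree")
    rows = [dict(individual=f, sire=None, dam=None, relation_type="founder")
            for f in founder_ids]
    current = list(founder_ids)
    uid = 0
    for g in range(n_generations):
        nxt = []
        parents = list(current)
        rng.shuffle(parents)
        for i in range(0, len(parents) - 1, 2):
            for _ in range(offspring_per_cross):
                name = f"G{g + 1}_{uid:03d}"
                uid += 1
                rows.append(dict(individual=name, sire=parents[i],
                                 dam=parents[i + 1], relation_type="cross"))
                nxt.append(name)
        current = nxt
    pool = [r["individual"] for r in rows]
    for k in range(n_sports):
        src = pool[int(rng.integers(len(pool)))]
        rows.append(dict(individual=f"S{k:02d}_{src}", sire=src, dam=None,
                         relation_type="sport"))
    df = pd.DataFrame(rows)[["individual", "sire", "dam", "relation_type"]]
    df["relation_type"] = df["relation_type"].replace({"founder": "cross"})
    return PedigreeTable(df)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    qtls: list,
    seed: int = 0,
    h2_polygenic: float = 0.0,
    year: int = 2019,
    truth: Optional[TruthSet] = None,
) -> tuple:
    """Additive trait model ``y = sum_k beta_k x_k + g + e``.

    Each QTL's effect is scaled so its realized variance share matches the
    target PVE given the observed allele frequencies; the optional polygenic
    term ``g`` uses every non-QTL variant with small random effects scaled
    to ``h2_polygenic``.  Total variance is 1 by construction, so shares are
    directly comparable to targets.  Realized shares are recorded in the
    returned :class:`TruthSet`.
    """
    rng = _rng(seed, "phenotypes")
    n = genotypes.n_samples
    by_trait = {}
    for q in qtls:
        by_trait.setdefault(q.trait, []).append(q)

    if truth is None:
        truth = TruthSet(samples=list(genotypes.samples),
                         origins=np.zeros((0, 0), dtype=np.int32),
                         chrom=np.array([]), pos=np.array([]))

    records = []
    for trait, qlist in by_trait.items():
        total_pve = sum(q.pve for q in qlist)
        if total_pve + h2_polygenic >= 1:
            raise ValueError("PVE targets plus polygenic share must sum below 1")
        y = np.zeros(n)
        effects, shares = {}, {}
        qtl_idx = [q.variant_index for q in qlist]
        for q in qlist:
            x = genotypes.dosages[:, q.variant_index].copy()
            if np.any(np.isnan(x)):
                x[np.isnan(x)] = np.nanmean(x)
            v = np.var(x)
            if v == 0 and q.pve > 0:
                raise ValueError(
                    f"QTL at variant {q.variant_index} is monomorphic; "
                    f"target PVE {q.pve} unattainable"
                )
            beta = np.sqrt(q.pve / v) if q.pve > 0 else 0.0
            y = y + beta * (x - x.mean())
            effects[q.variant_index] = beta
        if h2_polygenic > 0:
            bg = np.setdiff1d(np.arange(genotypes.n_variants), qtl_idx)
            X = genotypes.dosages[:, bg].copy()
            col_mean = np.nanmean(X, axis=0)
            nan_at = np.isnan(X)
            X[nan_at] = np.take(col_mean, np.where(nan_at)[1])
            u = rng.normal(size=len(bg))
            g = (X - col_mean) @ u
            gv = np.var(g)
            if gv > 0:
                y = y + g * np.sqrt(h2_polygenic / gv)
        sigma_e = np.sqrt(max(1.0 - total_pve - h2_polygenic, 0.0))
        y = y + rng.normal(scale=sigma_e, size=n) if sigma_e > 0 else y
        var_y = np.var(y) if np.var(y) > 0 else 1.0
        for q in qlist:
            x = genotypes.dosages[:, q.variant_index]
            xm = np.where(np.isnan(x), np.nanmean(x), x)
            shares[q.variant_index] = float(
                effects[q.variant_index] ** 2 * np.var(xm) / var_y
            )
        truth.qtl_effects[trait] = effects
        truth.realized_pve[trait] = shares
        for s, v in zip(genotypes.samples, y):
            records.append(dict(accession=s, trait=trait, year=year, value=v))

    table = PhenotypeTable(pd.DataFrame(records))
    return table, truth


# ---------------------------------------------------------------------------
# Genotyping artifacts
# ---------------------------------------------------------------------------

@dataclass
class ArtifactModel:
    """Call-degradation model: per-variant missing probability (scalar or
    per-variant array), Poisson mean read depth, genotype-error rate, and a
    monotone depth-to-GQ map ``GQ = min(99, gq_per_read * DP)``."""

    missing_rate: object = 0.02
    mean_depth: float = 20.0
    error_rate: float = 0.0
    gq_per_read: float = 5.0


def degrade_calls(
    genotypes: GenotypeMatrix,
    variants: Optional[VariantTable],
    model: ArtifactModel,
    seed: int = 0,
) -> tuple:
    """Inject genotyping artifacts into clean simulated calls.

    Returns ``(VariantTable, GenotypeMatrix, true_dosages)``: the variant
    table carries per-call DP and GQ; missing calls become NaN dosages;
    with ``error_rate > 0`` a call is replaced by one of the other two
    genotypes uniformly.  The clean matrix is returned for concordance
    checks.
    """
    rng = _rng(seed, "degrade")
    n, m = genotypes.dosages.shape
    true = genotypes.dosages.copy()
    dosages = genotypes.dosages.copy()

    miss = np.broadcast_to(np.asarray(model.missing_rate, dtype=float), (m,))
    miss_mask = rng.random((n, m)) < miss[None, :]
    if model.error_rate > 0:
        err_mask = (rng.random((n, m)) < model.error_rate) & ~miss_mask
        shift = rng.integers(1, 3, size=(n, m))
        dosages = np.where(err_mask, (dosages + shift) % 3, dosages)
    dosages[miss_mask] = np.nan

    if np.isinf(model.mean_depth):
        depth = np.full((n, m), np.inf)
    else:
        depth = rng.poisson(model.mean_depth, size=(n, m)).astype(float)
    gq = np.minimum(99.0, model.gq_per_read * depth)
    depth[miss_mask] = np.nan
    gq[miss_mask] = np.nan

    if variants is None:
        vmap_chrom = np.array(["Chr1"] * m, dtype=object)
        vmap_pos = np.arange(m, dtype=np.int64)
        ref = np.array(["A"] * m, dtype=object)
        alt = np.array(["G"] * m, dtype=object)
        qual = np.full(m, 100.0)
    else:
        vmap_chrom, vmap_pos = variants.chrom, variants.pos
        ref, alt = variants.ref, variants.alt
        qual = variants.qual if variants.qual is not None else np.full(m, 100.0)

    vt = VariantTable(chrom=vmap_chrom, pos=vmap_pos, ref=ref, alt=alt,
                      qual=qual, depth=depth, gq=gq)
    gm = GenotypeMatrix(samples=list(genotypes.samples), dosages=dosages)
    return vt, gm, true
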
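"""Staged SNP-selection cascade for genotyping-array design.

The cascade mirrors the standard array-design funnel: sequencing-based QC
(missing rate, depth, genotype quality, site quality), a shared-variant
filter, a probe-uniqueness surrogate for repeat-prone flanks, genotype-call
performance categories on a validation panel, integration with a legacy
array, and the annotation / interval statistics used to describe the final
product.

The proprietary probe-convertibility score of commercial pipelines is
replaced here by a deterministic k-mer uniqueness check plus a neighbouring-
polymorphism exclusion, which captures the same failure mode (repetitive
flanking sequence) reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, GenotypeMatrix, VariantTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

@dataclass
class QcThresholds:
    """Sequencing-QC operands: missing rate (max), mean depth (min), mean
    genotype quality (min, phred), site quality (min, phred)."""

    max_missing: float = 0.4
    min_depth: float = 2.0
    min_gq: float = 10.0
    min_qual: float = 50.0

    def __post_init__(self):
        if not (0 <= self.max_missing <= 1):
            raise ValueError("max_missing must lie in [0, 1]")
        if min(self.min_depth, self.min_gq, self.min_qual) < 0:
            raise ValueError("quality thresholds must be non-negative")


def qc_filter(
    variants: VariantTable,
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds = QcThresholds(),
) -> np.ndarray:
    """Boolean keep-mask for the sequencing QC stage.

    A variant passes when missing rate <= max_missing AND mean depth (over
    non-missing calls) >= min_depth AND mean GQ >= min_gq AND site QUAL >=
    min_qual.  A metric that is entirely absent counts as failing (logged).
    Survivors get the stage flag ``qc_pass``.
    """
    miss_ok = genotypes.missing_rate() <= thresholds.max_missing

    def _mean_metric(mat, name, cutoff):
        if mat is None:
            logger.warning("qc_filter: %s absent, treating all variants as failing", name)
            return np.zeros(variants.n_variants, dtype=bool)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(mat, axis=0)
        return np.nan_to_num(mean, nan=-np.inf) >= cutoff

    depth_ok = _mean_metric(variants.depth, "depth", thresholds.min_depth)
    gq_ok = _mean_metric(variants.gq, "genotype quality", thresholds.min_gq)
    if variants.qual is None:
        logger.warning("qc_filter: QUAL absent, treating all variants as failing")
        qual_ok = np.zeros(variants.n_variants, dtype=bool)
    else:
        qual_ok = np.nan_to_num(variants.qual, nan=-np.inf) >= thresholds.min_qual

    keep = miss_ok & depth_ok & gq_ok & qual_ok
    variants.add_stage_flag("qc_pass", keep)
    return keep


def shared_variant_filter(variants: VariantTable, genotypes: GenotypeMatrix) -> np.ndarray:
    """Keep variants whose ALT allele is carried by at least two accessions
    (dosage >= 1 in >= 2 samples).  Stage flag ``shared2``."""
    carriers = np.nansum(genotypes.dosages >= 1, axis=0)
    keep = carriers >= 2
    variants.add_stage_flag("shared2", keep)
    return keep


def probe_uniqueness_filter(
    variants: VariantTable,
    reference,
    k: int = 16,
    max_hits: int = 1,
    flank: int = 35,
    exclude_polymorphic_window: bool = True,
) -> np.ndarray:
    """Surrogate probe-design filter based on flank-sequence uniqueness.

    A variant is removed when any k-mer of its +/- ``flank`` bp window
    occurs more than ``max_hits`` times in the reference (repeat-prone
    probe), when the window runs off the contig end (reason ``edge``), or —
    with ``exclude_polymorphic_window`` — when another variant of the input
    set falls inside the window (a second polymorphism under the probe).

    ``reference`` is a mapping chrom -> sequence string (e.g. a
    ``pyfaidx.Fasta`` or plain dict).
    """
    counts: dict = {}
    for chrom in set(variants.chrom.tolist()):
        seq = str(reference[chrom][:]).upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1

    pos_by_chrom: dict = {}
    for c, p in zip(variants.chrom, variants.pos):
        pos_by_chrom.setdefault(c, []).append(int(p))
    for c in pos_by_chrom:
        pos_by_chrom[c] = np.sort(pos_by_chrom[c])

    keep = np.ones(variants.n_variants, dtype=bool)
    for j in range(variants.n_variants):
        chrom, p = variants.chrom[j], int(variants.pos[j])
        seq = str(reference[chrom][:]).upper()
        lo, hi = p - flank, p + flank + 1
        if lo < 0 or hi > len(seq):
            keep[j] = False  # reason: edge
            continue
        window = seq[lo:hi]
        if any(counts.get(window[i:i + k], 0) > max_hits
               for i in range(len(window) - k + 1)):
            keep[j] = False
            continue
        if exclude_polymorphic_window:
            neighbors = pos_by_chrom[chrom]
            in_win = neighbors[(neighbors >= lo) & (neighbors < hi)]
            if len(in_win) > 1:  # itself plus another site
                keep[j] = False
    variants.add_stage_flag("probe_ok", keep)
    return keep


# ---------------------------------------------------------------------------
# Performance categories on a genotyped validation panel
# ---------------------------------------------------------------------------

class SnpCategory(Enum):
    POLY_HIGH_RESOLUTION = "PolyHighResolution"
    MONO_HIGH_RESOLUTION = "MonoHighResolution"
    NO_MINOR_HOM = "NoMinorHom"
    OFF_TARGET_VARIANT = "OffTargetVariant"
    CALL_RATE_BELOW_THRESHOLD = "CallRateBelowThreshold"
    OTHER = "Other"


def classify_performance(
    genotypes: GenotypeMatrix,
    call_rate_min: float = 0.975,
    off_target_flags: Optional[np.ndarray] = None,
) -> list:
    """Assign each variant one genotype-call performance category.

    Rules (applied in order): an external cluster-quality flag marks
    OffTargetVariant; call rate below ``call_rate_min`` marks
    CallRateBelowThreshold; a monomorphic call set is MonoHighResolution;
    all three genotype classes present is PolyHighResolution; polymorphic
    without the minor homozygote (ref hom + het) is NoMinorHom; anything
    else — e.g. both homozygote classes but no heterozygote, or an empty
    call set — is Other.
    """
    cats = []
    rates = genotypes.call_rate()
    for j in range(genotypes.n_variants):
        if off_target_flags is not None and off_target_flags[j]:
            cats.append(SnpCategory.OFF_TARGET_VARIANT)
            continue
        col = genotypes.dosages[:, j]
        called = col[~np.isnan(col)]
        if len(called) == 0:
            cats.append(SnpCategory.OTHER)
            continue
        if rates[j] < call_rate_min:
            cats.append(SnpCategory.CALL_RATE_BELOW_THRESHOLD)
            continue
        n0 = int(np.sum(called == 0))
        n1 = int(np.sum(called == 1))
        n2 = int(np.sum(called == 2))
        if n1 == 0 and (n0 == 0 or n2 == 0):
            cats.append(SnpCategory.MONO_HIGH_RESOLUTION)
        elif n0 > 0 and n1 > 0 and n2 > 0:
            cats.append(SnpCategory.POLY_HIGH_RESOLUTION)
        elif n1 > 0 and (n0 == 0 or n2 == 0):
            cats.append(SnpCategory.NO_MINOR_HOM)
        else:
            cats.append(SnpCategory.OTHER)
    return cats


def select_final(categories: Sequence[SnpCategory]) -> np.ndarray:
    """Retain the two highest-priority categories: PolyHighResolution and
    NoMinorHom (call-rate failures already carry their own category)."""
    wanted = {SnpCategory.POLY_HIGH_RESOLUTION, SnpCategory.NO_MINOR_HOM}
    return np.array([c in wanted for c in categories])


# ---------------------------------------------------------------------------
# Legacy-array integration
# ---------------------------------------------------------------------------

@dataclass
class MergeResult:
    merged: set
    n_final: int
    n_legacy: int
    n_overlap: int

    @property
    def n_merged(self) -> int:
        return len(self.merged)


def integrate_legacy(final_positions: set, legacy_positions: Sequence) -> MergeResult:
    """Union the designed SNP set with a legacy array by (chrom, pos).

    Duplicates within one input are deduplicated with a warning; the merged
    count obeys |A u B| = |A| + |B| - |A n B| exactly.
    """
    final_set = set(final_positions)
    legacy_list = list(legacy_positions)
    legacy_set = set(legacy_list)
    if len(legacy_set) != len(legacy_list):
        logger.warning("integrate_legacy: %d duplicate legacy positions removed",
                       len(legacy_list) - len(legacy_set))
    overlap = final_set & legacy_set
    return MergeResult(
        merged=final_set | legacy_set,
        n_final=len(final_set),
        n_legacy=len(legacy_set),
        n_overlap=len(overlap),
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_regions(
    variants: VariantTable,
    annotation: GeneAnnotation,
    flank_bp: int = 1000,
) -> np.ndarray:
    """Classify each SNP as genic / upstream / downstream /
    upstream_downstream / intergenic.

    Genic (inside any gene span) takes precedence.  Upstream and downstream
    are strand-oriented flanks of width ``flank_bp``; a SNP lying in the
    upstream flank of one gene and the downstream flank of another gets the
    combined class.  Chromosomes absent from the annotation fall back to
    intergenic with a warning.
    """
    out = np.empty(variants.n_variants, dtype=object)
    genes_by_chrom = {c: g for c, g in annotation.genes.groupby("chrom")}
    warned = set()
    for j in range(variants.n_variants):
        chrom, p = variants.chrom[j], int(variants.pos[j])
        g = genes_by_chrom.get(chrom)
        if g is None:
            if chrom not in warned:
                logger.warning("chromosome %s absent from annotation", chrom)
                warned.add(chrom)
            out[j] = "intergenic"
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        strands = g["strand"].to_numpy()
        if np.any((p >= starts) & (p < ends)):
            out[j] = "genic"
            continue
        up = down = False
        for s, e, st in zip(starts, ends, strands):
            if st == "+":
                up |= s - flank_bp <= p < s
                down |= e <= p < e + flank_bp
            else:
                up |= e <= p < e + flank_bp
                down |= s - flank_bp <= p < s
        if up and down:
            out[j] = "upstream_downstream"
        elif up:
            out[j] = "upstream"
        elif down:
            out[j] = "downstream"
        else:
            out[j] = "intergenic"
    return out


_CODON_TABLE = None


def _translate(codon: str) -> str:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE = standard_dna_table
    if codon in _CODON_TABLE.stop_codons:
        return "*"
    return _CODON_TABLE.forward_table.get(codon, "X")


_COMP = str.maketrans("ACGT", "TGCA")


def annotate_effects(
    variants: VariantTable,
    annotation: GeneAnnotation,
    reference,
) -> np.ndarray:
    """Coding-effect class per SNP: synonymous, nonsynonymous, stop_gain,
    stop_loss, noncoding_genic, or None for SNPs outside genes.

    The affected codon is reconstructed on the coding strand from the
    spliced CDS; genes with CDS length not divisible by 3 are skipped
    (flagged at read time).  Large-effect = stop_gain or stop_loss.
    """
    out = np.full(variants.n_variants, None, dtype=object)
    regions = annotate_regions(variants, annotation)
    # genomic position -> (mRNA, index within spliced CDS) maps
    cds_maps = {}
    for mrna, segs in annotation.cds.items():
        gene = annotation.mrna_gene.get(mrna, mrna)
        if gene in annotation.flagged:
            continue
        grow = annotation.genes[annotation.genes["gene_id"] == gene]
        strand = grow.iloc[0]["strand"] if not grow.empty else "+"
        chrom = grow.iloc[0]["chrom"] if not grow.empty else None
        coords = []
        for s, e, _ in sorted(segs):
            coords.extend(range(s, e))
        if strand == "-":
            coords = coords[::-1]
        cds_maps[mrna] = (chrom, strand, {g: i for i, g in enumerate(coords)}, coords)

    for j in range(variants.n_variants):
        if regions[j] != "genic":
            continue
        chrom, p = variants.chrom[j], int(variants.pos[j])
        ref_a, alt_a = variants.ref[j], variants.alt[j]
        effect = "noncoding_genic"
        for mrna, (mchrom, strand, pos_map, coords) in cds_maps.items():
            if mchrom != chrom or p not in pos_map:
                continue
            idx = pos_map[p]
            codon_i = idx // 3
            seq = str(reference[chrom][:]).upper()
            codon_ref = ""
            for k in range(3):
                gpos = coords[codon_i * 3 + k]
                base = seq[gpos]
                codon_ref += base.translate(_COMP) if strand == "-" else base
            offset = idx % 3
            ref_c = ref_a.translate(_COMP) if strand == "-" else ref_a
            alt_c = alt_a.translate(_COMP) if strand == "-" else alt_a
            if codon_ref[offset] != ref_c:
                logger.warning("reference mismatch at %s:%d in %s", chrom, p, mrna)
            codon_alt = codon_ref[:offset] + alt_c + codon_ref[offset + 1:]
            aa_ref, aa_alt = _translate(codon_ref), _translate(codon_alt)
            if aa_ref == aa_alt:
                effect = "synonymous"
            elif aa_alt == "*":
                effect = "stop_gain"
            elif aa_ref == "*":
                effect = "stop_loss"
            else:
                effect = "nonsynonymous"
            break
        out[j] = effect
    return out


# ---------------------------------------------------------------------------
# Descriptive statistics and reporting
# ---------------------------------------------------------------------------

@dataclass
class IntervalStats:
    gaps: dict  # chrom -> np.ndarray of adjacent gaps (bp)
    mean: float
    all_gaps: np.ndarray

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.all_gaps, q)) if len(self.all_gaps) else np.nan

    def fraction_within(self, distance: int) -> float:
        """Fraction of adjacent intervals at or below ``distance`` bp."""
        if len(self.all_gaps) == 0:
            return np.nan
        return float(np.mean(self.all_gaps <= distance))


def interval_stats(chrom: np.ndarray, pos: np.ndarray) -> IntervalStats:
    """Adjacent inter-SNP distances per chromosome plus pooled summary.

    Chromosomes with fewer than 2 SNPs contribute no gaps.
    """
    gaps = {}
    pooled = []
    for c in pd.unique(np.asarray(chrom, dtype=object)):
        p = np.sort(np.asarray(pos)[np.asarray(chrom) == c])
        g = np.diff(p) if len(p) >= 2 else np.array([], dtype=np.int64)
        gaps[c] = g
        pooled.append(g)
    all_gaps = np.concatenate(pooled) if pooled else np.array([])
    mean = float(np.mean(all_gaps)) if len(all_gaps) else np.nan
    return IntervalStats(gaps=gaps, mean=mean, all_gaps=all_gaps)


@dataclass
class ConcordanceReport:
    per_sample: pd.Series
    overall: float
    missing_a: float
    missing_b: float


def genotype_concordance(calls_a: GenotypeMatrix, calls_b: GenotypeMatrix) -> ConcordanceReport:
    """Per-sample and overall genotype concordance over jointly non-missing
    calls, plus per-source missing fractions."""
    shared = [s for s in calls_a.samples if s in calls_b.samples]
    if not shared or calls_a.n_variants != calls_b.n_variants:
        raise ValueError("no shared (sample, variant) grid")
    ia = [calls_a.samples.index(s) for s in shared]
    ib = [calls_b.samples.index(s) for s in shared]
    A = calls_a.dosages[ia, :]
    B = calls_b.dosages[ib, :]
    joint = ~np.isnan(A) & ~np.isnan(B)
    if not joint.any():
        raise ValueError("no jointly called genotypes")
    match = (A == B) & joint
    with np.errstate(invalid="ignore"):
        per_sample = pd.Series(
            np.sum(match, axis=1) / np.sum(joint, axis=1), index=shared
        )
    return ConcordanceReport(
        per_sample=per_sample,
        overall=float(np.sum(match) / np.sum(joint)),
        missing_a=float(np.mean(np.isnan(A))),
        missing_b=float(np.mean(np.isnan(B))),
    )


def render_percent(count: int, denominator: int, decimals: int = 2) -> str:
    """Percentage string rounded half-up, e.g. 61924/173925 -> '35.61%'."""
    if denominator == 0:
        raise ValueError("zero denominator")
    pct = Decimal(count) * 100 / Decimal(denominator)
    q = Decimal(10) ** -decimals
    return f"{pct.quantize(q, rounding=ROUND_HALF_UP)}%"


@dataclass
class FunnelReport:
    """Ordered funnel of (stage label, surviving count, removed count) with
    percentage lines rendered against the final merged count."""

    stages: list = field(default_factory=list)  # (label, count, removed)
    final_count: int = 0

    @classmethod
    def from_counts(cls, labelled_counts: Sequence, final_count: Optional[int] = None):
        """Build from [(label, count), ...]; removed = previous - current
        (negative differences, e.g. at an integration stage, count as 0)."""
        stages = []
        prev = None
        for label, count in labelled_counts:
            removed = max(prev - count, 0) if prev is not None else 0
            stages.append((label, int(count), int(removed)))
            prev = count
        fc = int(final_count if final_count is not None else labelled_counts[-1][1])
        return cls(stages=stages, final_count=fc)

    def percent_line(self, count: int) -> str:
        return render_percent(count, self.final_count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "count", "removed"])
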
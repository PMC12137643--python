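"""Canonical in-memory containers shared by every stage of the pipeline.

Conventions
-----------
Coordinates
    External text formats (VCF, GFF3, RefinedIBD output) keep their native
    1-based inclusive convention; everything held in memory uses 0-based
    half-open intervals.  Conversion happens exactly once, in the readers
    and writers of :mod:`orchardpop.io`.
Missing data
    Missing dosages, depths and qualities are ``numpy.nan`` in float arrays.
    Phased haplotype alleles use the integer sentinel :data:`HAP_MISSING`;
    the sentinel is only ever compared, never used in arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele in an integer haplotype matrix.
HAP_MISSING: int = -9


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Per-variant metadata: positions, alleles, call-level quality metrics.

    Parameters
    ----------
    chrom : array of str, shape (m,)
        Chromosome label per variant.
    pos : array of int, shape (m,)
        0-based position of the SNP (converted from the 1-based VCF POS at
        the I/O boundary).
    ref, alt : arrays of str, shape (m,)
        Single-nucleotide reference and alternate alleles.
    qual : array of float, shape (m,)
        Site quality (the VCF QUAL column), used as the "allele quality"
        operand of the QC cascade.  NaN when absent.
    depth, gq : arrays of float, shape (n_samples, m), optional
        Per-call sequencing depth and phred genotype quality.  NaN when a
        call carries no annotation.
    stage_flags : list of set of str
        Labels of the filter stages each variant has passed.
    flank : array of str, optional
        Reference sequence context around each SNP when a FASTA was given.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: Optional[np.ndarray] = None
    depth: Optional[np.ndarray] = None
    gq: Optional[np.ndarray] = None
    stage_flags: Optional[list] = None
    flank: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.qual is not None:
            self.qual = np.asarray(self.qual, dtype=float)
        if self.stage_flags is None:
            self.stage_flags = [set() for _ in range(self.n_variants)]
        if np.any(self.pos < 0):
            raise ValueError("positions must be non-negative (0-based)")
        same = self.ref == self.alt
        if np.any(same):
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def __len__(self) -> int:
        return self.n_variants

    def subset(self, index) -> "VariantTable":
        """Return a new table restricted to ``index`` (mask or indices)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return VariantTable(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            qual=None if self.qual is None else self.qual[index],
            depth=None if self.depth is None else self.depth[:, index],
            gq=None if self.gq is None else self.gq[:, index],
            stage_flags=[set(self.stage_flags[i]) for i in index],
            flank=None if self.flank is None else self.flank[index],
        )

    def add_stage_flag(self, flag: str, mask=None) -> None:
        """Mark variants (all, or those selected by ``mask``) as having
        passed the named filter stage."""
        idx = range(self.n_variants) if mask is None else np.flatnonzero(mask)
        for i in idx:
            self.stage_flags[i].add(flag)

    def positions_set(self) -> set:
        return set(zip(self.chrom.tolist(), self.pos.tolist()))


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Accessions x variants dosage matrix, optionally phased.

    ``dosages`` counts ALT alleles (0, 1, 2) with NaN for a missing call.
    ``phased``, when present, is a ``(2 n_samples, m)`` integer matrix of
    per-haplotype ALT indicators; row ``2i`` and ``2i+1`` are the two
    chromosome copies of sample ``i`` and sum to the dosage wherever the
    dosage is not missing.
    """

    samples: list
    dosages: np.ndarray
    phased: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample list does not match dosage rows")
        if self.phased is not None:
            self.phased = np.asarray(self.phased, dtype=np.int8)
            if self.phased.shape != (2 * self.n_samples, self.n_variants):
                raise ValueError("phased matrix must be (2N, M)")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per variant."""
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def alt_freq(self) -> np.ndarray:
        """ALT allele frequency per variant over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            samples=self.samples,
            dosages=self.dosages[:, index],
            phased=None if self.phased is None else self.phased[:, index],
        )

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        hap_idx = np.ravel(np.column_stack((2 * index, 2 * index + 1)))
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            dosages=self.dosages[index, :],
            phased=None if self.phased is None else self.phased[hap_idx, :],
        )

    def validate_phase(self) -> None:
        """Check haplotype pair sums against non-missing dosages."""
        if self.phased is None:
            return
        ok = self.phased != HAP_MISSING
        pair_ok = ok[0::2] & ok[1::2]
        sums = (self.phased[0::2].astype(float) + self.phased[1::2])
        called = ~np.isnan(self.dosages) & pair_ok
        if not np.allclose(sums[called], self.dosages[called]):
            raise ValueError("phased haplotypes inconsistent with dosages")


# ---------------------------------------------------------------------------
# Phenotypes, pedigree, annotation, IBD
# ---------------------------------------------------------------------------

class PhenotypeTable:
    """Long-format trait table keyed by (accession, trait, year).

    Flowering dates are stored as integer day-of-year; concentration and
    index traits keep their native units.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"accession", "trait", "year", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"phenotype table needs columns {sorted(required)}")
        dup = df.duplicated(subset=["accession", "trait", "year"])
        if dup.any():
            raise ValueError("duplicate (accession, trait, year) records")
        self.df = df.reset_index(drop=True)

    def values(self, trait: str, year=None, accessions: Optional[Sequence] = None) -> pd.Series:
        """Trait values indexed by accession (one year, or averaged)."""
        sub = self.df[self.df["trait"] == trait]
        if year is not None:
            sub = sub[sub["year"] == year]
        series = sub.groupby("accession")["value"].mean()
        if accessions is not None:
            series = series.reindex(accessions)
        return series

    @property
    def traits(self) -> list:
        return sorted(self.df["trait"].unique())


class PedigreeTable:
    """Directed pedigree with cross and sport (bud mutation) relations.

    A *sport* is a clonal mutant: it has exactly one named parent whose
    genome it copies up to a handful of somatic changes.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"individual", "sire", "dam", "relation_type"}
        if not required.issubset(df.columns):
            raise ValueError(f"pedigree needs columns {sorted(required)}")
        df = df.copy()
        for col in ("sire", "dam"):
            df[col] = df[col].where(df[col].notna(), None)
            df[col] = df[col].replace({"": None, "0": None})
        self.df = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        ind = self.df["individual"]
        if ind.duplicated().any():
            raise ValueError("duplicate individuals in pedigree")
        known = set(ind)
        for _, row in self.df.iterrows():
            if row["relation_type"] == "sport":
                named = [p for p in (row["sire"], row["dam"]) if p is not None]
                if len(named) != 1:
                    raise ValueError(
                        f"sport {row['individual']} must name exactly one parent"
                    )
        # every named parent appears as an individual or is declared a founder
        parents = set(p for p in self.df["sire"] if p is not None)
        parents |= set(p for p in self.df["dam"] if p is not None)
        self._implicit_founders = sorted(parents - known)
        self.topological_order()  # raises on cycle

    @property
    def individuals(self) -> list:
        return list(self.df["individual"])

    def parents(self, individual) -> tuple:
        row = self.df[self.df["individual"] == individual]
        if row.empty:
            return (None, None)
        return (row.iloc[0]["sire"], row.iloc[0]["dam"])

    def founders(self) -> list:
        """Individuals with no recorded parents, plus parents that never
        appear as individuals themselves."""
        own = [
            r["individual"]
            for _, r in self.df.iterrows()
            if r["sire"] is None and r["dam"] is None
        ]
        return own + self._implicit_founders

    def topological_order(self) -> list:
        """All individuals (founders first), parents before offspring.

        Raises ``ValueError`` naming the cycle if the pedigree is cyclic.
        """
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.founders())
        for _, row in self.df.iterrows():
            g.add_node(row["individual"])
            for p in (row["sire"], row["dam"]):
                if p is not None:
                    g.add_edge(p, row["individual"])
        try:
            return list(nx.topological_sort(g))
        except nx.NetworkXUnfeasible:
            cycle = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cycle}")

    def sport_pairs(self) -> list:
        """(sport, source-parent) pairs."""
        out = []
        for _, row in self.df.iterrows():
            if row["relation_type"] == "sport":
                parent = row["sire"] if row["sire"] is not None else row["dam"]
                out.append((row["individual"], parent))
        return out


@dataclass
class GeneAnnotation:
    """Gene models: spans for region annotation, CDS for effect calls.

    ``genes`` has columns gene_id, chrom, start, end (0-based half-open),
    strand.  ``cds`` maps an mRNA id to an ordered list of (start, end,
    phase) CDS segments in genomic order; ``mrna_gene`` maps mRNA -> gene.
    Genes whose concatenated CDS length is not a multiple of 3 are listed
    in ``flagged`` and skipped by effect annotation rather than rejected.
    """

    genes: pd.DataFrame
    cds: dict = field(default_factory=dict)
    mrna_gene: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)

    def genes_on(self, chrom: str) -> pd.DataFrame:
        return self.genes[self.genes["chrom"] == chrom]


@dataclass(frozen=True)
class IBDSegment:
    """A pairwise identical-by-descent interval (0-based half-open bp).

    The sample pair is stored in canonical (sorted) order.
    """

    sample_a: str
    sample_b: str
    chrom: str
    start: int
    end: int
    score: float = 0.0
    length_cm: Optional[float] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("IBD segment start > end")
        if self.sample_a == self.sample_b:
            raise ValueError("IBD segment needs two distinct samples")
        if str(self.sample_a) > str(self.sample_b):
            a, b = self.sample_a, self.sample_b
            object.__setattr__(self, "sample_a", b)
            object.__setattr__(self, "sample_b", a)

    @property
    def pair(self) -> tuple:
        return (self.sample_a, self.sample_b)

    @property
    def length_bp(self) -> int:
        return self.end - self.start
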
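"""Readers and writers for the external formats the pipeline touches.

VCF parsing goes through :mod:`cyvcf2`; GFF3 is read with a lightweight
column parser.  Reference sequence, where needed, is any mapping from
chromosome name to sequence string (a ``pyfaidx.Fasta`` works).  All
coordinate conversion to the internal 0-based half-open convention
happens here.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    HAP_MISSING,
    GeneAnnotation,
    GenotypeMatrix,
    IBDSegment,
    PedigreeTable,
    PhenotypeTable,
    VariantTable,
)

logger = logging.getLogger(__name__)

_NUCS = {"A", "C", "G", "T"}


class VcfData(NamedTuple):
    variants: VariantTable
    genotypes: GenotypeMatrix
    n_skipped: int


def read_vcf(path, want_phase: bool = False) -> VcfData:
    """Read a VCF into a (VariantTable, GenotypeMatrix) pair.

    Only biallelic SNP records are kept; multiallelic and indel records are
    skipped and counted in ``n_skipped``.  ``./.`` becomes a missing dosage.
    Phase is captured only when ``want_phase`` is set and every genotype of
    a record is phased.

    Stage flags previously serialised by :func:`write_vcf` (INFO key
    ``STAGES``) are restored.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)

    chroms, poss, refs, alts, quals, flags = [], [], [], [], [], []
    dosage_rows, depth_rows, gq_rows, hap_rows = [], [], [], []
    n_skipped = 0
    phase_ok = want_phase

    for v in vcf:
        if len(v.ALT) != 1 or v.REF not in _NUCS or v.ALT[0] not in _NUCS:
            n_skipped += 1
            continue
        gts = v.genotypes  # [allele0, allele1, phased] per sample
        if any(len(g) != 3 for g in gts):
            raise ValueError(f"mixed ploidy at {v.CHROM}:{v.POS}")
        dos = np.empty(n)
        haps = np.empty(2 * n, dtype=np.int8)
        rec_phased = True
        for i, g in enumerate(gts):
            a0, a1, ph = g
            if a0 < 0 or a1 < 0:
                dos[i] = np.nan
                haps[2 * i] = haps[2 * i + 1] = HAP_MISSING
            else:
                dos[i] = a0 + a1
                haps[2 * i], haps[2 * i + 1] = a0, a1
            rec_phased &= bool(ph)
        phase_ok &= rec_phased
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        raw = v.INFO.get("STAGES")
        flags.append(set(raw.split(",")) if raw else set())
        dosage_rows.append(dos)
        hap_rows.append(haps)
        for key, rows_list in (("DP", depth_rows), ("GQ", gq_rows)):
            try:
                arr = v.format(key)
            except KeyError:
                arr = None
            rows_list.append(
                arr.astype(float).reshape(n) if arr is not None
                else np.full(n, np.nan)
            )
    vcf.close()

    m = len(poss)
    dosages = np.array(dosage_rows).T if m else np.empty((n, 0))
    depth = np.array(depth_rows).T if m else None
    gqm = np.array(gq_rows).T if m else None
    if depth is not None and np.all(np.isnan(depth)):
        depth = None
    if gqm is not None and np.all(np.isnan(gqm)):
        gqm = None
    phased = None
    if phase_ok and m:
        phased = np.array(hap_rows, dtype=np.int8).T
    # negative DP placeholders from cyvcf2 -> NaN
    if depth is not None:
        depth[depth < 0] = np.nan
    if gqm is not None:
        gqm[gqm < 0] = np.nan

    variants = VariantTable(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        qual=np.array(quals, dtype=float),
        depth=depth,
        gq=gqm,
        stage_flags=flags,
    )
    genotypes = GenotypeMatrix(samples=samples, dosages=dosages, phased=phased)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    return VcfData(variants, genotypes, n_skipped)


def write_vcf(variants: VariantTable, genotypes: GenotypeMatrix, path) -> None:
    """Write a VCF 4.2 file with GT (phased separators when haplotypes are
    present), DP/GQ when available, and stage flags in INFO key STAGES."""
    if variants.n_variants != genotypes.n_variants:
        raise ValueError("variant table and genotype matrix differ in length")
    has_dp = variants.depth is not None
    has_gq = variants.gq is not None
    phased = genotypes.phased is not None
    fmt_keys = ["GT"] + (["DP"] if has_dp else []) + (["GQ"] if has_gq else [])

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(variants.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##INFO=<ID=STAGES,Number=.,Type=String,'
            'Description="Filter stages passed">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_dp:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        if has_gq:
            fh.write(
                '##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                'Description="Genotype quality">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.samples)
            + "\n"
        )
        sep = "|" if phased else "/"
        for j in range(variants.n_variants):
            qual = variants.qual[j] if variants.qual is not None else np.nan
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            stages = sorted(variants.stage_flags[j])
            info = f"STAGES={','.join(stages)}" if stages else "."
            cells = []
            for i in range(genotypes.n_samples):
                d = genotypes.dosages[i, j]
                if np.isnan(d):
                    gt = f".{sep}."
                elif phased:
                    a0 = genotypes.phased[2 * i, j]
                    a1 = genotypes.phased[2 * i + 1, j]
                    gt = f".{sep}." if a0 == HAP_MISSING else f"{a0}|{a1}"
                else:
                    d = int(d)
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[d]
                parts = [gt]
                if has_dp:
                    dp = variants.depth[i, j]
                    parts.append("." if np.isnan(dp) else str(int(round(dp))))
                if has_gq:
                    g = variants.gq[i, j]
                    parts.append("." if np.isnan(g) else str(int(round(g))))
                cells.append(":".join(parts))
            fh.write(
                f"{variants.chrom[j]}\t{variants.pos[j] + 1}\t.\t"
                f"{variants.ref[j]}\t{variants.alt[j]}\t{qual_s}\tPASS\t{info}\t"
                + ":".join(fmt_keys)
                + "\t"
                + "\t".join(cells)
                + "\n"
            )


def read_pedigree(path) -> PedigreeTable:
    """Read a pedigree CSV with header individual,sire,dam,relation_type."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    if "relation_type" not in df.columns:
        df["relation_type"] = "cross"
    df["relation_type"] = df["relation_type"].fillna("cross")
    return PedigreeTable(df)


_KNOWN_TRAITS = {
    "SSC", "pH", "TA", "sucrose", "glucose", "fructose", "sorbitol",
    "malate", "citrate", "quinate", "shikimate", "flowering_date",
}


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype TSV with header accession,trait,year,value.

    Unknown trait names are kept with a warning; flowering dates are cast
    to integer day-of-year.
    """
    df = pd.read_csv(path, sep="\t")
    unknown = set(df["trait"].unique()) - _KNOWN_TRAITS
    if unknown:
        logger.warning("unknown trait names kept: %s", sorted(unknown))
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    return PhenotypeTable(df)


def read_gff(path, fasta=None) -> GeneAnnotation:
    """Read gene models from GFF3 (genes, mRNAs, CDS segments).

    Coordinates are converted to 0-based half-open.  ``fasta`` (a path or a
    ``pyfaidx.Fasta``) is accepted for interface symmetry with the effect
    annotator, which needs the sequence; it is not required here.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                continue
            rows.append(f)

    def attrs(s):
        out = {}
        for kv in s.split(";"):
            if "=" in kv:
                k, v = kv.split("=", 1)
                out[k.strip()] = v.strip()
        return out

    genes, cds, mrna_gene = [], defaultdict(list), {}
    cds_strand = {}
    for f in rows:
        chrom, _, ftype, start, end, _, strand, phase, attr = f[:9]
        a = attrs(attr)
        start0, end0 = int(start) - 1, int(end)
        if ftype == "gene":
            genes.append(
                dict(gene_id=a.get("ID"), chrom=chrom, start=start0, end=end0,
                     strand=strand)
            )
        elif ftype == "mRNA":
            mrna_gene[a.get("ID")] = a.get("Parent")
        elif ftype == "CDS":
            parent = a.get("Parent")
            ph = 0 if phase == "." else int(phase)
            cds[parent].append((start0, end0, ph))
            cds_strand[parent] = strand

    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"])
    flagged = []
    for mrna, segs in cds.items():
        segs.sort()
        total = sum(e - s for s, e, _ in segs)
        if total % 3 != 0:
            flagged.append(mrna_gene.get(mrna, mrna))
            logger.warning("CDS length of %s not divisible by 3", mrna)
    return GeneAnnotation(
        genes=genes_df, cds=dict(cds), mrna_gene=mrna_gene, flagged=flagged
    )


def read_refined_ibd(path, min_lod: Optional[float] = None) -> list:
    """Read RefinedIBD 9-column output into canonical IBD segments.

    Columns: sample1, hap1, sample2, hap2, chrom, start, end, LOD, cM.
    Haplotype indices are collapsed to the sample-pair level: overlapping
    or adjacent intervals reported for different haplotype combinations of
    the same pair are merged to their union.  Records with start > end are
    rejected with a warning; ``min_lod``, when given, drops low-score rows.
    """
    cols = ["s1", "h1", "s2", "h2", "chrom", "start", "end", "lod", "cm"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols)
    by_pair = defaultdict(list)
    for _, r in df.iterrows():
        if r["start"] > r["end"]:
            logger.warning("rejected IBD record with start > end: %s", tuple(r))
            continue
        if min_lod is not None and r["lod"] < min_lod:
            continue
        a, b = sorted([str(r["s1"]), str(r["s2"])])
        # 1-based inclusive -> 0-based half-open
        by_pair[(a, b, r["chrom"])].append(
            (int(r["start"]) - 1, int(r["end"]), float(r["lod"]), float(r["cm"]))
        )

    segments = []
    for (a, b, chrom), ivals in sorted(by_pair.items()):
        ivals.sort()
        merged = []
        for s, e, lod, cm in ivals:
            if merged and s <= merged[-1][1]:
                ps, pe, plod, pcm = merged[-1]
                merged[-1] = (ps, max(pe, e), max(plod, lod), max(pcm, cm))
            else:
                merged.append((s, e, lod, cm))
        for s, e, lod, cm in merged:
            segments.append(
                IBDSegment(sample_a=a, sample_b=b, chrom=str(chrom),
                           start=s, end=e, score=lod, length_cm=cm)
            )
    return segments


def write_kinship_tsv(samples, matrix, path) -> None:
    """Square kinship matrix as TSV with header IDs."""
    pd.DataFrame(matrix, index=samples, columns=samples).to_csv(path, sep="\t")


def read_positions_tsv(path) -> set:
    """Legacy-array SNP list: TSV with columns chrom, pos (1-based)."""
    df = pd.read_csv(path, sep="\t")
    chrom_col, pos_col = df.columns[:2]
    return set(zip(df[chrom_col].astype(str), df[pos_col].astype(int) - 1))
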
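"""Readers, writers and the GATK-style hard-filter stage.

All coordinates are 1-based inclusive throughout the package (the native
convention of VCF and GFF3); any conversion happens only at the boundary of
a third-party API and is noted where it occurs.

Genotypes are stored as alt-allele dosage: 0 (hom ref), 1 (het), 2 (hom alt),
with ``MISSING`` (-1) for uncalled genotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF
from skbio import TreeNode

logger = logging.getLogger(__name__)

MISSING = -1

#: INFO metrics of the hard-filter stage and their removal conditions.
#: A site is removed when ANY condition holds; a metric absent from a record
#: passes its own rule (the convention of GATK hard filtering).
HARD_FILTER_RULES: dict[str, tuple[str, float]] = {
    "QD": ("<", 2.0),
    "ReadPosRankSum": ("<", -8.0),
    "FS": (">", 60.0),
    "QUAL": ("<", 30.0),
    "DP": ("<", 4.0),
    "SOR": (">", 3.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
}


@dataclass
class VariantRecord:
    """A biallelic SNP site with per-sample alt dosages."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float | None = None
    info: dict[str, float] = field(default_factory=dict)
    genotypes: np.ndarray | None = None  # dosage per sample, MISSING = -1

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNPs as alt-allele dosage.

    ``dosages`` is an ``(n_samples, n_snps)`` int8 array with ``MISSING``
    for uncalled genotypes.  Variant metadata arrays are parallel to the
    SNP axis.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows do not match sample_ids")
        for arr in (self.chrom, self.pos, self.ref, self.alt):
            if len(arr) != m:
                raise ValueError("variant metadata length does not match dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP, ignoring missing genotypes."""
        d = np.ma.masked_equal(self.dosages, MISSING)
        return np.asarray(d.mean(axis=0) / 2.0)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosages=self.dosages[:, index],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        ids = [self.sample_ids[i] for i in np.atleast_1d(index)]
        return GenotypeMatrix(
            sample_ids=ids,
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosages=self.dosages[np.atleast_1d(index), :],
        )

    def imputed(self) -> np.ndarray:
        """Float dosage matrix with missing entries replaced by per-SNP means."""
        d = self.dosages.astype(float)
        d[d == MISSING] = np.nan
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
        return d


@dataclass
class GeneModel:
    """A protein-coding gene model with a derived upstream promoter window."""

    gene_id: str
    chrom: str
    strand: str
    gene_span: tuple[int, int]  # 1-based inclusive
    cds_segments: list[tuple[int, int]]  # genomic order, 1-based inclusive
    promoter_length: int = 2000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        lo, hi = self.gene_span
        segs = sorted(self.cds_segments)
        for (a, b) in segs:
            if a < lo or b > hi:
                raise ValueError(
                    f"CDS segment {a}-{b} outside gene span of {self.gene_id}"
                )
        for (a, b), (c, d) in zip(segs, segs[1:]):
            if c <= b:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        self.cds_segments = segs

    @property
    def promoter_span(self) -> tuple[int, int]:
        """Upstream window of ``promoter_length`` bp, strand-aware, clipped at 1."""
        lo, hi = self.gene_span
        if self.strand == "+":
            return (max(1, lo - self.promoter_length), lo - 1)
        return (hi + 1, hi + self.promoter_length)

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds_segments)

    def region_of(self, pos: int) -> str:
        """Classify a position as promoter / CDS / intron / intergenic."""
        plo, phi = self.promoter_span
        if plo <= pos <= phi:
            return "promoter"
        if any(a <= pos <= b for a, b in self.cds_segments):
            return "CDS"
        if self.gene_span[0] <= pos <= self.gene_span[1]:
            return "intron"
        return "intergenic"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a diploid VCF into a dosage matrix plus per-site records.

    Multi-allelic sites are skipped (with a logged count), not split: all
    downstream analyses operate on biallelic SNPs.  ``./.`` genotypes map to
    the missing sentinel.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} contains no sample columns")

    records: list[VariantRecord] = []
    dosage_rows: list[np.ndarray] = []
    chroms, poss, refs, alts = [], [], [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        # cyvcf2 gt_types with gts012: 0/1/2 = dosage, 3 = unknown
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        info = {}
        for k in HARD_FILTER_RULES:
            if k == "QUAL":
                continue
            val = v.INFO.get(k)
            if val is not None:
                info[k] = float(val)
        rec = VariantRecord(
            chrom=v.CHROM,
            pos=v.POS,
            ref=v.REF,
            alt=v.ALT[0],
            qual=None if v.QUAL is None else float(v.QUAL),
            info=info,
            genotypes=g,
        )
        records.append(rec)
        dosage_rows.append(g)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_multi:
        logger.info("skipped %d multi-allelic records in %s", n_multi, path)
    if not records:
        dosages = np.zeros((len(samples), 0), dtype=np.int8)
    else:
        dosages = np.stack(dosage_rows, axis=1)
    gm = GenotypeMatrix(
        sample_ids=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        dosages=dosages,
    )
    return gm, records


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              records: list[VariantRecord] | None = None) -> None:
    """Write a minimal VCF v4.2 representation of a dosage matrix.

    Dosage 1 is emitted as 0/1: phase is not represented in this package.
    If ``records`` is given, QUAL and INFO metrics are carried through.
    """
    by_key = {r.key: r for r in records} if records else {}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(str(x) for x in gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        for k in HARD_FILTER_RULES:
            if k == "QUAL":
                continue
            vtype = "Integer" if k == "DP" else "Float"
            fh.write(f'##INFO=<ID={k},Number=1,Type={vtype},Description="{k}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j in range(gm.n_snps):
            rec = by_key.get((gm.chrom[j], int(gm.pos[j])))
            qual = "." if rec is None or rec.qual is None else f"{rec.qual:g}"
            if rec is not None and rec.info:
                info = ";".join(f"{k}={v:g}" for k, v in sorted(rec.info.items()))
            else:
                info = "."
            gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{gm.ref[j]}\t{gm.alt[j]}\t"
                     f"{qual}\tPASS\t{info}\tGT\t{gts}\n")


def hard_filter_variants(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord], dict[str, int]]:
    """Apply the per-site hard filter and report per-rule removal counts.

    Removal conditions (a site failing ANY is removed): QD < 2.0,
    ReadPosRankSum < -8.0, FS > 60.0, QUAL < 30.0, DP < 4.0, SOR > 3.0,
    MQ < 40.0, MQRankSum < -12.5.  All inequalities are strict, so boundary
    values are retained.  A metric absent from a record passes its own rule.

    Returns (retained, removed, per-rule removal counts).  Counts can sum to
    more than the number removed because a site may violate several rules.
    """
    retained: list[VariantRecord] = []
    removed: list[VariantRecord] = []
    counts = {k: 0 for k in HARD_FILTER_RULES}
    for rec in records:
        failed = False
        for metric, (op, threshold) in HARD_FILTER_RULES.items():
            value = rec.qual if metric == "QUAL" else rec.info.get(metric)
            if value is None or math.isnan(value):
                continue
            hit = value < threshold if op == "<" else value > threshold
            if hit:
                counts[metric] += 1
                failed = True
        (removed if failed else retained).append(rec)
    return retained, removed, counts


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path, promoter_length: int = 2000) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features of a GFF3 file into gene models.

    When a gene has several mRNAs the first (by ID order) is used for the
    CDS structure.  GFF3 is 1-based inclusive, matching the package-wide
    convention, so coordinates pass through unchanged.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = sorted(db.children(gene, featuretype="mRNA"), key=lambda f: f.id)
        if mrnas:
            cds = [(c.start, c.end) for c in db.children(mrnas[0], featuretype="CDS")]
        else:
            cds = [(c.start, c.end) for c in db.children(gene, featuretype="CDS")]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                gene_span=(gene.start, gene.end),
                cds_segments=cds,
                promoter_length=promoter_length,
            )
        )
    return models


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            lo, hi = g.gene_span
            fh.write(f"{g.chrom}\t.\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.t1"
            fh.write(f"{g.chrom}\t.\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                     f"ID={mrna};Parent={g.gene_id}\n")
            # Phase column: cumulative CDS length determines the frame offset.
            segs = g.cds_segments if g.strand == "+" else g.cds_segments[::-1]
            consumed = 0
            phases = {}
            for (a, b) in segs:
                phases[(a, b)] = (3 - consumed % 3) % 3
                consumed += b - a + 1
            for i, (a, b) in enumerate(g.cds_segments):
                fh.write(f"{g.chrom}\t.\tCDS\t{a}\t{b}\t.\t{g.strand}\t"
                         f"{phases[(a, b)]}\tID={mrna}.cds{i};Parent={mrna}\n")


# ---------------------------------------------------------------------------
# Newick / tables
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick with branch lengths to 6 decimals."""
    if tree is None or (tree.is_tip() and tree.name is None):
        raise ValueError("cannot serialize an empty tree")

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = node.name or ""
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += node.name
        if node.length is not None:
            body += f":{node.length:.6f}"
        return body

    return fmt(tree) + ";"


def read_newick(text_or_path: str | Path) -> TreeNode:
    """Parse Newick text (or a file path) into a ``skbio.TreeNode``."""
    p = Path(str(text_or_path))
    if p.exists():
        return TreeNode.read(str(p), format="newick")
    from io import StringIO

    return TreeNode.read(StringIO(str(text_or_path)), format="newick")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a delimited table with a header row; the delimiter is sniffed."""
    return pd.read_csv(path, sep=None, engine="python", **kwargs)


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)
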
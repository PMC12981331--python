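"""Candidate-gene windows, variant-effect annotation and haplotype analysis.

Significant SNPs define +/-50 kb candidate windows; variants inside a gene
are annotated at codon level against a reference sequence; promoter and
coding (CDS) haplotypes are built from unphased dosage states, rare classes
(fewer than five carriers by default) are excluded, the surviving classes
are connected by a minimum spanning tree over Hamming distances, and class
phenotypes are compared by one-way ANOVA with pairwise Welch tests under
Holm adjustment.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq3
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import MISSING, GeneModel, GenotypeMatrix


@dataclass
class CandidateWindow:
    chrom: str
    pos: int
    span: tuple[int, int]
    gene_ids: list[str] = field(default_factory=list)


@dataclass
class EffectAnnotation:
    chrom: str
    pos: int
    region: str                      # promoter / CDS / intron / intergenic
    coding_effect: str = "none"      # synonymous / missense / nonsense / none
    aa_change: str | None = None     # e.g. Thr93Ala
    codon_number: int | None = None


@dataclass
class HaplotypeTable:
    """Haplotype classes over a site set, ordered by descending frequency."""

    region_label: str                 # "promoter" or "coding"
    sites: list[tuple[str, int]]
    classes: pd.DataFrame             # haplotype, name, count
    assignments: pd.Series            # accession -> class name (or 'unassigned')
    min_carriers: int
    het_policy: str


def candidate_windows(
    snps: list[tuple[str, int]],
    genes: list[GeneModel],
    flank: int = 50_000,
) -> list[CandidateWindow]:
    """Genes whose span intersects [pos - flank, pos + flank] (closed interval).

    The window is clipped at the chromosome start (position 1).
    """
    out = []
    for chrom, pos in snps:
        lo, hi = max(1, pos - flank), pos + flank
        hits = [
            g.gene_id
            for g in genes
            if g.chrom == chrom and g.gene_span[0] <= hi and g.gene_span[1] >= lo
        ]
        out.append(CandidateWindow(chrom=chrom, pos=pos, span=(lo, hi), gene_ids=hits))
    return out


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS (transcript
    orientation), or None when the position is not coding."""
    segs = gene.cds_segments
    if gene.strand == "+":
        consumed = 0
        for a, b in segs:
            if a <= pos <= b:
                return consumed + (pos - a)
            consumed += b - a + 1
    else:
        consumed = 0
        for a, b in reversed(segs):
            if a <= pos <= b:
                return consumed + (b - pos)
            consumed += b - a + 1
    return None


def cds_sequence(gene: GeneModel, reference: dict[str, str]) -> str:
    """Spliced CDS in transcript orientation from a chrom -> sequence dict."""
    seq = reference[gene.chrom]
    parts = [seq[a - 1 : b] for a, b in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def annotate_variant_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: GeneModel,
    reference: dict[str, str],
) -> EffectAnnotation:
    """Codon-level consequence of a SNP against a gene model.

    For CDS positions the reference and alternate codons are translated with
    the standard genetic code; a premature stop is ``nonsense``, an
    amino-acid change ``missense`` (labelled like Thr93Ala), identity
    ``synonymous``.  Non-CDS positions are classified by region only.
    """
    if chrom != gene.chrom:
        return EffectAnnotation(chrom=chrom, pos=pos, region="intergenic")
    region = gene.region_of(pos)
    ann = EffectAnnotation(chrom=chrom, pos=pos, region=region)
    if region != "CDS":
        return ann
    seq = reference[chrom]
    ref_base = seq[pos - 1]
    if ref_base.upper() != ref.upper():
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: "
            f"sequence has {ref_base!r}, variant claims {ref!r}"
        )
    offset = _cds_offset(gene, pos)
    cds = cds_sequence(gene, reference)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length of {gene.gene_id} not divisible by 3")
    alt_tx = alt if gene.strand == "+" else str(Seq(alt).complement())
    codon_i = offset // 3
    within = offset % 3
    codon_ref = cds[3 * codon_i : 3 * codon_i + 3]
    codon_alt = codon_ref[:within] + alt_tx + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    ann.codon_number = codon_i + 1
    if aa_ref == aa_alt:
        ann.coding_effect = "synonymous"
    elif aa_alt == "*":
        ann.coding_effect = "nonsense"
        ann.aa_change = f"{seq3(aa_ref)}{codon_i + 1}Ter"
    else:
        ann.coding_effect = "missense"
        ann.aa_change = f"{seq3(aa_ref)}{codon_i + 1}{seq3(aa_alt)}"
    return ann


def build_haplotypes(
    gm: GenotypeMatrix,
    region_span: tuple[int, int],
    chrom: str,
    region_label: str = "promoter",
    min_carriers: int = 5,
    het_policy: str = "het_state",
) -> HaplotypeTable:
    """Group accessions by their joint dosage string over a region's sites.

    Phase is unavailable, so the default policy keeps the heterozygous state
    as its own symbol (0/H/2 per site); ``drop_het`` instead discards any
    accession heterozygous at a region site.  Accessions with missing calls
    in the region are always unassigned.  Classes are ordered by descending
    carrier count (ties by string) and named ``Hap-P1``/``Hap-C1``... after
    the region; classes with fewer than ``min_carriers`` carriers are rare
    and dropped, their members marked unassigned.
    """
    if het_policy not in ("het_state", "drop_het"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    lo, hi = region_span
    idx = np.where((gm.chrom == chrom) & (gm.pos >= lo) & (gm.pos <= hi))[0]
    if len(idx) == 0:
        raise ValueError(f"no SNPs in {chrom}:{lo}-{hi}")
    sites = [(chrom, int(p)) for p in gm.pos[idx]]
    symbols = {0: "0", 1: "H", 2: "2"}

    hap_strings: dict[str, str | None] = {}
    for i, acc in enumerate(gm.sample_ids):
        states = gm.dosages[i, idx]
        if np.any(states == MISSING):
            hap_strings[acc] = None
            continue
        if het_policy == "drop_het" and np.any(states == 1):
            hap_strings[acc] = None
            continue
        hap_strings[acc] = "".join(symbols[int(s)] for s in states)

    counts: dict[str, int] = {}
    for h in hap_strings.values():
        if h is not None:
            counts[h] = counts.get(h, 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    prefix = "Hap-P" if region_label == "promoter" else "Hap-C"
    kept = [(h, c) for h, c in ordered if c >= min_carriers]
    if not kept:
        warnings.warn("all haplotype classes are rare; empty table", stacklevel=2)
    names = {h: f"{prefix}{r + 1}" for r, (h, _) in enumerate(kept)}
    classes = pd.DataFrame(
        [{"haplotype": h, "name": names[h], "count": c} for h, c in kept]
    )
    assignments = pd.Series(
        {
            acc: names.get(h, "unassigned") if h is not None else "unassigned"
            for acc, h in hap_strings.items()
        },
        name="haplotype_class",
    )
    return HaplotypeTable(
        region_label=region_label, sites=sites, classes=classes,
        assignments=assignments, min_carriers=min_carriers, het_policy=het_policy,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def haplotype_network_mst(table: HaplotypeTable) -> list[tuple[str, str, int]]:
    """Minimum spanning tree over Hamming distances between class strings.

    Kruskal with a fully deterministic edge order: (weight, lexicographic
    node pair).  Returns edges as (class_a, class_b, distance); a single
    class yields no edges.
    """
    if len(table.classes) < 2:
        return []
    names = list(table.classes["name"])
    strings = dict(zip(table.classes["name"], table.classes["haplotype"]))
    edges = sorted(
        (
            (_hamming(strings[a], strings[b]), a, b)
            for a, b in itertools.combinations(sorted(names), 2)
        ),
    )
    parent = {n: n for n in names}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    mst = []
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            mst.append((a, b, w))
            if len(mst) == len(names) - 1:
                break
    return mst


def haplotype_phenotype_test(
    table: HaplotypeTable,
    trait: pd.Series,
    min_group: int = 2,
) -> dict:
    """Compare a trait across haplotype classes.

    Returns per-class mean +/- SE, the one-way ANOVA F and p, and pairwise
    Welch t-tests with Holm-adjusted p-values.  Classes with fewer than
    ``min_group`` phenotyped members are excluded (warned); if all values
    are identical the F statistic is undefined and flagged.
    """
    groups: dict[str, np.ndarray] = {}
    for name in table.classes["name"]:
        members = table.assignments[table.assignments == name].index
        vals = trait.reindex(members).dropna().to_numpy(dtype=float)
        if len(vals) >= min_group:
            groups[name] = vals
        else:
            warnings.warn(f"class {name} has <{min_group} phenotyped members; "
                          "excluded", stacklevel=2)
    if len(groups) < 2:
        raise ValueError("need >= 2 haplotype classes with phenotypes")
    summary = pd.DataFrame(
        {
            "n": {k: len(v) for k, v in groups.items()},
            "mean": {k: v.mean() for k, v in groups.items()},
            "se": {k: v.std(ddof=1) / np.sqrt(len(v)) for k, v in groups.items()},
        }
    )
    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled, pooled[0]):
        anova_f, anova_p, degenerate = np.nan, np.nan, True
    else:
        anova_f, anova_p = stats.f_oneway(*groups.values())
        degenerate = False
    pairs, raw_p, tstats = [], [], []
    for a, b in itertools.combinations(sorted(groups), 2):
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        pairs.append((a, b))
        tstats.append(float(t))
        raw_p.append(float(p) if np.isfinite(p) else 1.0)
    if raw_p:
        adj = multipletests(raw_p, method="holm")[1]
    else:
        adj = []
    pairwise = pd.DataFrame(
        {
            "class_a": [a for a, _ in pairs],
            "class_b": [b for _, b in pairs],
            "t": tstats,
            "p": raw_p,
            "p_holm": list(adj),
        }
    )
    return {
        "summary": summary,
        "anova_F": float(anova_f) if np.isfinite(anova_f) else np.nan,
        "anova_p": float(anova_p) if np.isfinite(anova_p) else np.nan,
        "degenerate": degenerate,
        "pairwise": pairwise,
    }
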
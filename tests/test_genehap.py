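import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import toy_matrix
from droughtmap.genehap import (
    annotate_variant_effect,
    build_haplotypes,
    candidate_windows,
    haplotype_network_mst,
    haplotype_phenotype_test,
)
from droughtmap.io_formats import GeneModel

# The standard genetic code, frozen independently as the test oracle.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class TestCandidateWindows:
    def test_window_arithmetic(self):
        w = candidate_windows([("chr10", 206_216_541)], [])[0]
        assert w.span == (206_166_541, 206_266_541)

    def test_gene_touching_window_edge_included(self):
        g = GeneModel("edge", "chr1", "+", (40_000, 50_000), [])
        w = candidate_windows([("chr1", 100_000)], [g], flank=50_000)[0]
        assert "edge" in w.gene_ids
        g2 = GeneModel("out", "chr1", "+", (30_000, 49_999), [])
        w2 = candidate_windows([("chr1", 100_000)], [g2], flank=50_000)[0]
        assert "out" not in w2.gene_ids

    def test_window_clipped_at_chromosome_start(self):
        w = candidate_windows([("chr1", 10_000)], [], flank=50_000)[0]
        assert w.span[0] == 1


def _plus_gene(cds_seq, promoter_length=50):
    ref = {"chr1": "A" * 100 + cds_seq + "T" * 100}
    gene = GeneModel("g", "chr1", "+", (101, 100 + len(cds_seq)),
                     [(101, 100 + len(cds_seq))], promoter_length=promoter_length)
    return gene, ref


class TestEffectAnnotation:
    def test_synonymous_third_position(self):
        gene, ref = _plus_gene("ATGGCTTGA")  # M A *
        # GCT -> GCC, both Ala
        ann = annotate_variant_effect("chr1", 106, "T", "C", gene, ref)
        assert ann.coding_effect == "synonymous"

    def test_missense_thr_to_ala(self):
        gene, ref = _plus_gene("ATGACTTGA")  # M T *
        ann = annotate_variant_effect("chr1", 104, "A", "G", gene, ref)
        assert ann.coding_effect == "missense"
        assert ann.aa_change == "Thr2Ala"

    def test_nonsense(self):
        gene, ref = _plus_gene("ATGTGGTGA")  # M W *
        ann = annotate_variant_effect("chr1", 106, "G", "A", gene, ref)  # TGG->TGA... pos?
        # TGG codon spans 104-106; third base G->A gives TGA
        assert ann.coding_effect == "nonsense"

    def test_promoter_and_intergenic_classification(self):
        gene, ref = _plus_gene("ATGTGGTGA", promoter_length=50)
        assert annotate_variant_effect("chr1", 60, "A", "G", gene, ref).region == "promoter"
        assert annotate_variant_effect("chr1", 10, "A", "G", gene, ref).region == "intergenic"

    def test_reference_mismatch_rejected(self):
        gene, ref = _plus_gene("ATGTGGTGA")
        with pytest.raises(ValueError, match="chr1:104"):
            annotate_variant_effect("chr1", 104, "C", "G", gene, ref)

    def test_full_codon_table_classification(self):
        """Every single-base substitution in every codon is classified in
        agreement with the standard genetic code (independent table)."""
        bases = "ACGT"
        checked = 0
        for codon in map("".join, itertools.product(bases, repeat=3)):
            if CODON_TABLE[codon] == "*":
                continue  # reference stop codons are not inside a valid CDS
            cds = "ATG" + codon + "TGA"
            gene, ref = _plus_gene(cds)
            for within in range(3):
                for alt in bases:
                    if alt == codon[within]:
                        continue
                    mutant = codon[:within] + alt + codon[within + 1:]
                    pos = 104 + within
                    ann = annotate_variant_effect(
                        "chr1", pos, codon[within], alt, gene, ref
                    )
                    aa_ref, aa_alt = CODON_TABLE[codon], CODON_TABLE[mutant]
                    if aa_ref == aa_alt:
                        expected = "synonymous"
                    elif aa_alt == "*":
                        expected = "nonsense"
                    else:
                        expected = "missense"
                    assert ann.coding_effect == expected, (codon, mutant)
                    checked += 1
        assert checked == 61 * 9

    def test_minus_strand_uses_transcript_orientation(self):
        """On the minus strand the codon is read off the reverse complement."""
        from Bio.Seq import Seq

        cds_tx = "ATGACTTGA"  # M T *
        genomic = str(Seq(cds_tx).reverse_complement())
        ref = {"chr1": "A" * 100 + genomic + "T" * 100}
        gene = GeneModel("g", "chr1", "-", (101, 109), [(101, 109)],
                         promoter_length=50)
        # transcript position of codon-2 base 1 (A of ACT) = offset 3
        # -> genomic pos = 109 - 3 = 106; transcript A->G is genomic T->C
        ann = annotate_variant_effect("chr1", 106, ref["chr1"][105], "C", gene, ref)
        assert ann.coding_effect == "missense"
        assert ann.aa_change == "Thr2Ala"

    def test_extracted_cds_translates_cleanly(self):
        """The spliced CDS of a gene model matches the codon-table oracle."""
        from droughtmap.genehap import cds_sequence

        gene, ref = _plus_gene("ATGACTGGGAAATGA")
        cds = cds_sequence(gene, ref)
        aa = "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))
        assert aa == "MTGK*"


class TestHaplotypes:
    def _region_matrix(self, counts):
        """Build accessions with class strings repeated per requested count."""
        rows = []
        patterns = [[0, 0, 0], [2, 2, 2], [0, 2, 0], [2, 0, 2], [1, 1, 0]]
        for pat, c in zip(patterns, counts):
            rows.extend([pat] * c)
        return toy_matrix(rows, positions=[10, 20, 30])

    def test_rare_class_filter(self):
        gm = self._region_matrix([6, 4, 2])
        tab = build_haplotypes(gm, (1, 100), "chr1", min_carriers=5)
        assert len(tab.classes) == 1
        assert tab.classes.iloc[0]["count"] == 6
        assert (tab.assignments != "unassigned").sum() == 6

    def test_min_carriers_one_keeps_all(self):
        gm = self._region_matrix([6, 4, 2])
        tab = build_haplotypes(gm, (1, 100), "chr1", min_carriers=1)
        assert tab.classes["count"].sum() == 12
        assert (tab.assignments == "unassigned").sum() == 0

    def test_identical_accessions_single_class(self):
        gm = self._region_matrix([8])
        tab = build_haplotypes(gm, (1, 100), "chr1", min_carriers=5)
        assert len(tab.classes) == 1
        assert tab.classes.iloc[0]["count"] == 8

    def test_all_rare_warns_empty(self):
        gm = self._region_matrix([2, 2, 2])
        with pytest.warns(UserWarning, match="rare"):
            tab = build_haplotypes(gm, (1, 100), "chr1", min_carriers=5)
        assert tab.classes.empty

    def test_counts_partition_retained(self):
        gm = self._region_matrix([6, 5, 4, 3])
        tab = build_haplotypes(gm, (1, 100), "chr1", min_carriers=4)
        assigned = tab.assignments[tab.assignments != "unassigned"]
        assert tab.classes["count"].sum() == len(assigned)
        assert sorted(assigned.value_counts().to_list(), reverse=True) == [6, 5, 4]

    def test_het_policy_drop(self):
        gm = self._region_matrix([5, 5, 0, 0, 5])  # last pattern has hets
        tab = build_haplotypes(gm, (1, 100), "chr1", min_carriers=2,
                               het_policy="drop_het")
        assert tab.classes["count"].sum() == 10

    def test_naming_by_region(self):
        gm = self._region_matrix([6, 5])
        t1 = build_haplotypes(gm, (1, 100), "chr1", region_label="promoter")
        t2 = build_haplotypes(gm, (1, 100), "chr1", region_label="coding")
        assert t1.classes["name"].iloc[0] == "Hap-P1"
        assert t2.classes["name"].iloc[0] == "Hap-C1"


def _mst_weight(edges):
    return sum(w for _, _, w in edges)


def _brute_force_mst_weight(names, dist):
    best = np.inf
    n = len(names)
    all_edges = list(itertools.combinations(range(n), 2))
    for subset in itertools.combinations(all_edges, n - 1):
        # spanning check by union-find
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in subset:
            parent[find(a)] = find(b)
        if len({find(i) for i in range(n)}) == 1:
            w = sum(dist[a][b] for a, b in subset)
            best = min(best, w)
    return best


class TestNetwork:
    def _table(self, haps):
        classes = pd.DataFrame({
            "haplotype": haps,
            "name": [f"Hap-P{i + 1}" for i in range(len(haps))],
            "count": [10 - i for i in range(len(haps))],
        })
        from droughtmap.genehap import HaplotypeTable

        return HaplotypeTable(
            region_label="promoter", sites=[("chr1", 1)], classes=classes,
            assignments=pd.Series(dtype=object), min_carriers=5,
            het_policy="het_state",
        )

    def test_triangle_uses_two_short_edges(self):
        tab = self._table(["000", "001", "011"])  # d(1,2)=1, d(2,3)=1, d(1,3)=2
        edges = haplotype_network_mst(tab)
        assert _mst_weight(edges) == 2
        assert all(w == 1 for _, _, w in edges)

    def test_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(6)
        for trial in range(5):
            n = 6
            haps = ["".join(rng.choice(list("02H"), size=8)) for _ in range(n)]
            if len(set(haps)) < n:
                continue
            tab = self._table(haps)
            edges = haplotype_network_mst(tab)
            names = list(tab.classes["name"])
            strings = dict(zip(names, tab.classes["haplotype"]))
            dist = [
                [sum(x != y for x, y in zip(strings[a], strings[b])) for b in names]
                for a in names
            ]
            assert _mst_weight(edges) == _brute_force_mst_weight(names, dist)

    def test_single_class_no_edges(self):
        tab = self._table(["000"])
        assert haplotype_network_mst(tab) == []

    def test_deterministic_tie_breaking(self):
        tab = self._table(["00", "02", "20", "22"])
        e1 = haplotype_network_mst(tab)
        e2 = haplotype_network_mst(tab)
        assert e1 == e2


class TestPhenotypeAssociation:
    def _assoc_table(self, n_a=20, n_b=20):
        from droughtmap.genehap import HaplotypeTable

        names = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
        assignments = pd.Series(
            ["Hap-P1"] * n_a + ["Hap-P2"] * n_b, index=names
        )
        classes = pd.DataFrame({
            "haplotype": ["0", "2"],
            "name": ["Hap-P1", "Hap-P2"],
            "count": [n_a, n_b],
        })
        return HaplotypeTable(
            region_label="promoter", sites=[("chr1", 1)], classes=classes,
            assignments=assignments, min_carriers=5, het_policy="het_state",
        )

    def test_null_rarely_significant(self):
        tab = self._assoc_table(50, 50)
        rng = np.random.default_rng(9)
        hits = 0
        reps = 100
        for _ in range(reps):
            trait = pd.Series(rng.normal(size=100), index=tab.assignments.index)
            res = haplotype_phenotype_test(tab, trait)
            hits += res["anova_p"] < 0.05
        assert hits <= 10  # ~5% expected; 90% of runs clean

    def test_shifted_groups_detected(self):
        tab = self._assoc_table(20, 20)
        rng = np.random.default_rng(10)
        trait = pd.Series(
            np.concatenate([rng.normal(0, 1, 20), rng.normal(2, 1, 20)]),
            index=tab.assignments.index,
        )
        res = haplotype_phenotype_test(tab, trait)
        assert res["anova_p"] < 0.01
        assert (res["pairwise"]["p_holm"] < 0.01).all()

    def test_identical_values_flagged(self):
        tab = self._assoc_table(10, 10)
        trait = pd.Series(1.0, index=tab.assignments.index)
        res = haplotype_phenotype_test(tab, trait)
        assert res["degenerate"]

    def test_summary_shape(self):
        tab = self._assoc_table(15, 25)
        rng = np.random.default_rng(11)
        trait = pd.Series(rng.normal(size=40), index=tab.assignments.index)
        res = haplotype_phenotype_test(tab, trait)
        assert list(res["summary"]["n"]) == [15, 25]
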
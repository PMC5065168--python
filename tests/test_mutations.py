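import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoshatter.calling import CNACall
from karyoshatter.genome import GeneInterval
from karyoshatter.mutations import (MutationRecord, biallelic_status,
                                    classify_zygosity, filter_scored_variants,
                                    load_mutation_table,
                                    minimal_deleted_region,
                                    write_mutation_table)

#: worked example: the TP53 variants of the three chromothriptic MDS cases
CHROMOTHRIPSIS_TP53 = [
    MutationRecord("#072", "TP53", "c.395A>G", "p.Lys132Arg", "missense",
                   92.5, "COSM308311"),
    MutationRecord("#027", "TP53", "c.406C>T", "p.Gln136*", "nonsense",
                   46.5, "COSM126985"),
    MutationRecord("#027", "TP53", "c.833C>T", "p.Pro278Leu", "missense",
                   43.5, "COSM129831"),
    MutationRecord("#026", "TP53", "c.499C>T", "p.Gln167*", "nonsense",
                   93.5, "COSM121081"),
]


def rec(vaf=50.0, mtype="missense", gene="TP53", sample="P1", cosmic=None):
    return MutationRecord(sample, gene, "c.1A>G", "p.Met1Val", mtype, vaf,
                          cosmic)


class TestTableIO:
    def test_roundtrip_preserves_records(self, tmp_path):
        path = tmp_path / "muts.tsv"
        write_mutation_table(CHROMOTHRIPSIS_TP53, path)
        assert load_mutation_table(path) == CHROMOTHRIPSIS_TP53

    def test_publication_style_headers_accepted(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "Sample ID\tGene\tNucleotide change\tAA change\tMutation type"
            "\tVAF (%)\tCOSMIC ID\n"
            "#072\tTP53\tc.395A>G\tp.Lys132Arg\tmissense\t92.5\tCOSM308311\n")
        records = load_mutation_table(path)
        assert records == [CHROMOTHRIPSIS_TP53[0]]

    def test_empty_table_with_header(self, tmp_path):
        path = tmp_path / "muts.tsv"
        write_mutation_table([], path)
        assert load_mutation_table(path) == []

    def test_vaf_out_of_range_rejected_naming_row(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text(
            "sample\tgene\tcdna_change\tprotein_change\tmutation_type"
            "\tvaf\tcosmic_id\n"
            "P1\tTP53\tc.1A>G\tp.M1V\tmissense\t101\t\n")
        with pytest.raises(ValueError, match="line 2"):
            load_mutation_table(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "muts.tsv"
        path.write_text("sample\tgene\tvaf\nP1\tTP53\t50\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_mutation_table(path)


class TestScoringFilter:
    def test_intronic_removed(self):
        assert filter_scored_variants([rec(mtype="intronic")]) == []

    def test_known_snp_id_removed(self):
        r = rec(cosmic="rs12345")
        assert filter_scored_variants([r], {"rs12345"}) == []

    def test_exonic_missense_retained(self):
        r = rec()
        assert filter_scored_variants([r], {"rs12345"}) == [r]

    def test_idempotent(self):
        records = [rec(), rec(mtype="intronic"), rec(cosmic="rs1")]
        once = filter_scored_variants(records, {"rs1"})
        assert filter_scored_variants(once, {"rs1"}) == once


class TestZygosity:
    @pytest.mark.parametrize("vaf,expected", [
        (93.5, "homozygous_or_hemizygous"),
        (92.5, "homozygous_or_hemizygous"),
        (46.5, "heterozygous"),
        (43.5, "heterozygous"),
        (80.0, "homozygous_or_hemizygous"),  # inclusive threshold
        (79.9, "heterozygous"),
    ])
    def test_vaf_classification(self, vaf, expected):
        assert classify_zygosity(rec(vaf=vaf)).zygosity == expected

    def test_published_chromothripsis_cases_give_two_homozygous_patients(self):
        """Of the three chromothriptic cases, one carries two heterozygous
        mutations and the other two one homozygous mutation each."""
        calls = [classify_zygosity(r) for r in CHROMOTHRIPSIS_TP53]
        hom_patients = {c.record.sample for c in calls
                        if c.zygosity == "homozygous_or_hemizygous"}
        het_patients = {c.record.sample for c in calls
                        if c.zygosity == "heterozygous"}
        assert hom_patients == {"#072", "#026"}
        assert het_patients == {"#027"}

    def test_threshold_monotonicity(self):
        """Raising the threshold never converts heterozygous to homozygous."""
        for vaf in np.linspace(0, 100, 21):
            r = rec(vaf=float(vaf))
            lo = classify_zygosity(r, 70.0).zygosity
            hi = classify_zygosity(r, 90.0).zygosity
            assert not (lo == "heterozygous"
                        and hi == "homozygous_or_hemizygous")

    def test_binomial_recovery_at_depth_500(self):
        """At depth >= 500, implanted zygosity for true VAFs <= 60 or >= 90 is
        recovered with error rate < 1%."""
        from karyoshatter.simulate import TrueVariant, simulate_variant_table
        rng_seed, depth, n = 0, 500, 2000
        variants, truth = [], []
        for i, tv in enumerate([30.0, 50.0, 60.0, 90.0, 95.0, 100.0]):
            zyg = ("homozygous_or_hemizygous" if tv >= 80
                   else "heterozygous")
            for j in range(n // 6):
                variants.append(TrueVariant(f"P{i}_{j}", "TP53", "c.1A>G",
                                            "p.M1V", "missense", tv, zyg))
                truth.append(zyg)
        table = simulate_variant_table(variants, depth, seed=rng_seed)
        errors = 0
        for vaf, true_zyg in zip(table["vaf"], truth):
            got = classify_zygosity(rec(vaf=float(vaf))).zygosity
            errors += got != true_zyg
        assert errors / len(truth) < 0.01


class TestBiallelicStatus:
    GENES = {"DNMT3A": GeneInterval("DNMT3A", "chr2", 23_000_000, 23_200_000),
             "TET2": GeneInterval("TET2", "chr4", 104_000_000, 104_200_000)}

    def loss(self, chrom="chr2", start=22_000_000, end=24_000_000):
        return CNACall(chrom, start, end, -1.0, 50, "loss", 1)

    def zyg(self, gene="DNMT3A", sample="P1", vaf=73.5):
        return classify_zygosity(rec(vaf=vaf, gene=gene, sample=sample))

    def test_deletion_plus_mutation(self):
        st = biallelic_status("P1", "DNMT3A", [self.loss()],
                              [self.zyg(vaf=73.5)], self.GENES)
        assert st.category == "deletion_plus_mutation"

    def test_deletion_only(self):
        st = biallelic_status("P1", "TET2",
                              [self.loss("chr4", 103_500_000, 104_500_000)],
                              [], self.GENES)
        assert st.category == "deletion_only"

    def test_mutation_only_and_wild_type(self):
        st = biallelic_status("P1", "DNMT3A", [], [self.zyg()], self.GENES)
        assert st.category == "mutation_only"
        st = biallelic_status("P1", "DNMT3A", [], [], self.GENES)
        assert st.category == "wild_type"

    def test_deletion_not_overlapping_gene_ignored(self):
        st = biallelic_status("P1", "DNMT3A",
                              [self.loss(start=30_000_000, end=31_000_000)],
                              [], self.GENES)
        assert st.category == "wild_type"

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError, match="NOPE"):
            biallelic_status("P1", "NOPE", [], [], self.GENES)


class TestMinimalDeletedRegion:
    def test_single_deletion_is_identity(self):
        mdr = minimal_deleted_region("TET2", [("chr4", (100, 500))])
        assert (mdr.start, mdr.end) == (100, 500)
        assert mdr.n_supporting_patients == 1

    def test_two_overlapping_deletions(self):
        mdr = minimal_deleted_region(
            "TET2", [("chr4", (100, 500)), ("chr4", (300, 900))])
        assert (mdr.start, mdr.end) == (300, 500)
        assert mdr.size_bp == 200

    def test_disjoint_deletions_yield_absent(self):
        assert minimal_deleted_region(
            "X", [("chr4", (0, 100)), ("chr4", (200, 300))]) is None

    def test_multi_chromosome_input_rejected(self):
        with pytest.raises(ValueError, match="chromosomes"):
            minimal_deleted_region(
                "X", [("chr4", (0, 100)), ("chr5", (0, 100))])

    @given(st.lists(
        st.tuples(st.integers(0, 1000), st.integers(1, 500)),
        min_size=1, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_containment_and_shrinkage(self, raw):
        """The MDR is contained in every supporting deletion, and adding a
        deletion never widens it."""
        dels = [("chr1", (s, s + w)) for s, w in raw]
        mdr = minimal_deleted_region("L", dels)
        if mdr is not None:
            for _, (s, e) in dels:
                assert s <= mdr.start and mdr.end <= e
        if len(dels) > 1:
            sub = minimal_deleted_region("L", dels[:-1])
            if sub is None:
                assert mdr is None
            elif mdr is not None:
                assert sub.end - sub.start >= mdr.end - mdr.start
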
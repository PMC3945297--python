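import numpy as np
import pytest

from conftest import make_sift_table, random_cds
from somasel.errors import ClassificationError, ValidationError
from somasel.site_counting import Effect, GeneModel
from somasel.variant_processing import (
    FUNC_MF,
    FUNC_NA,
    FUNC_UNSCORED,
    GroupCounts,
    SubstitutionRecord,
    apply_nonsense_frameshift_filter,
    classify_records,
    classify_substitution,
    deduplicate_within_tumor,
    filter_germline_by_frequency,
    patient_zero_hit_summary,
    read_germline_vcf,
    read_maf,
    select_longest_transcript,
    tally_group_counts,
    write_maf,
)


def rec(patient="p1", gene="g1", transcript="t1", pos=1, ref="A", alt="T", **kw):
    return SubstitutionRecord(patient, gene, transcript, pos, ref, alt, **kw)


class TestSelectLongestTranscript:
    def test_single_transcript(self):
        m = GeneModel("g1", "t1", "ATGTTT")
        assert select_longest_transcript([m]) == {"g1": m}

    def test_longest_wins(self):
        short = GeneModel("g1", "t1", "A" * 300)
        long = GeneModel("g1", "t2", "A" * 303)
        assert select_longest_transcript([short, long])["g1"] is long
        assert select_longest_transcript([long, short])["g1"] is long

    def test_tie_broken_by_smallest_id(self):
        t2 = GeneModel("g1", "T2", "ATGTTT")
        t1 = GeneModel("g1", "T1", "ATGAAA")
        assert select_longest_transcript([t2, t1])["g1"] is t1


class TestClassifySubstitution:
    def test_synonymous(self):
        gene = GeneModel("g1", "t1", "ATGTTT")
        out = classify_substitution(rec(pos=6, ref="T", alt="C"), gene)
        assert out.effect is Effect.SYNONYMOUS  # TTT -> TTC, both Phe
        assert out.func_class_sift == FUNC_NA

    def test_nonsense(self):
        gene = GeneModel("g1", "t1", "ATGTGG")
        out = classify_substitution(rec(pos=6, ref="G", alt="A"), gene)
        assert out.effect is Effect.NONSENSE  # TGG -> TGA

    def test_missense_sift_mf_at_004(self):
        gene = GeneModel("g1", "t1", "ATGTTT")
        # TTT -> GTT is Val at protein position 2
        table = make_sift_table({("g1", 2, "V"): 0.04})
        out = classify_substitution(rec(pos=4, ref="T", alt="G"), gene, table)
        assert out.effect is Effect.MISSENSE
        assert out.func_class_sift == FUNC_MF

    def test_missense_without_table_unscored(self):
        gene = GeneModel("g1", "t1", "ATGTTT")
        out = classify_substitution(rec(pos=4, ref="T", alt="G"), gene)
        assert out.func_class_sift == FUNC_UNSCORED

    def test_ref_mismatch_rejected(self):
        gene = GeneModel("g1", "t1", "ATGTTT")
        with pytest.raises(ClassificationError):
            classify_substitution(rec(pos=6, ref="A", alt="C"), gene)

    def test_position_out_of_range_rejected(self):
        gene = GeneModel("g1", "t1", "ATGTTT")
        with pytest.raises(ClassificationError):
            classify_substitution(rec(pos=7, ref="T", alt="C"), gene)

    def test_frameshift_passthrough(self):
        gene = GeneModel("g1", "t1", "ATGTTT")
        out = classify_substitution(
            rec(pos=4, ref="T", alt="T", variant_class="frameshift_indel"), gene
        )
        assert out.frameshift_flag and out.effect is None

    def test_batch_collects_rejections(self):
        gene = {"g1": GeneModel("g1", "t1", "ATGTTT")}
        records = [rec(pos=6, ref="T", alt="C"), rec(gene="gX", pos=1)]
        kept, rejected = classify_records(records, gene)
        assert len(kept) == 1 and len(rejected) == 1
        assert "unknown gene" in rejected[0][1]


class TestDeduplicateWithinTumor:
    def test_same_change_same_patient_once(self):
        records = [rec(), rec()]
        assert len(deduplicate_within_tumor(records)) == 1

    def test_same_change_different_patients_kept(self):
        records = [rec(patient="p1"), rec(patient="p2")]
        assert len(deduplicate_within_tumor(records)) == 2

    def test_empty(self):
        assert deduplicate_within_tumor([]) == []

    def test_idempotent_and_shrinking(self, rng):
        records = [
            rec(
                patient=f"p{rng.integers(3)}",
                gene=f"g{rng.integers(3)}",
                pos=int(rng.integers(1, 5)),
            )
            for _ in range(100)
        ]
        once = deduplicate_within_tumor(records)
        assert len(once) <= len(records)
        assert deduplicate_within_tumor(once) == once


def _random_cohort(rng, n=120):
    effects = [Effect.SYNONYMOUS, Effect.MISSENSE, Effect.NONSENSE]
    return [
        rec(
            patient=f"p{rng.integers(4)}",
            gene=f"g{rng.integers(4)}",
            pos=int(rng.integers(1, 8)),
            effect=effects[rng.integers(3)],
        )
        for _ in range(n)
    ]


class TestNonsenseFrameshiftFilter:
    def test_rule_application(self):
        records = [
            rec(patient="p1", gene="geneA", pos=1, effect=Effect.MISSENSE),
            rec(patient="p1", gene="geneA", pos=2, effect=Effect.NONSENSE),
            rec(patient="p1", gene="geneB", pos=1, effect=Effect.MISSENSE),
        ]
        kept, removed = apply_nonsense_frameshift_filter(records)
        assert len(removed) == 2  # both geneA records, trigger included
        assert [r.gene_id for r in kept] == ["geneB"]

    def test_no_truncations_passthrough(self):
        records = [rec(effect=Effect.MISSENSE), rec(pos=2, effect=Effect.SYNONYMOUS)]
        kept, removed = apply_nonsense_frameshift_filter(records)
        assert kept == records and removed == []

    def test_per_patient_scoping(self):
        records = [
            rec(patient="p1", gene="geneA", effect=Effect.NONSENSE),
            rec(patient="p2", gene="geneA", effect=Effect.MISSENSE),
        ]
        kept, removed = apply_nonsense_frameshift_filter(records)
        assert [r.patient_id for r in kept] == ["p2"]

    def test_frameshift_triggers_too(self):
        records = [
            rec(patient="p1", gene="geneA", effect=Effect.MISSENSE),
            rec(patient="p1", gene="geneA", pos=2, frameshift_flag=True),
        ]
        kept, removed = apply_nonsense_frameshift_filter(records)
        assert kept == [] and len(removed) == 2

    def test_partition_property(self, rng):
        records = _random_cohort(rng)
        kept, removed = apply_nonsense_frameshift_filter(records)
        assert len(kept) + len(removed) == len(records)
        tainted = {
            (r.patient_id, r.gene_id) for r in records if r.effect is Effect.NONSENSE
        }
        assert all((r.patient_id, r.gene_id) not in tainted for r in kept)

    def test_order_invariance_with_dedup(self, rng):
        records = _random_cohort(rng)
        a, _ = apply_nonsense_frameshift_filter(deduplicate_within_tumor(records))
        b = deduplicate_within_tumor(apply_nonsense_frameshift_filter(records)[0])
        assert a == b


class TestGermlineFrequencyFilter:
    def test_boundary_is_strict(self):
        assert filter_germline_by_frequency([rec(patient="", allele_freq=0.10)]) == []

    def test_above_kept(self):
        records = [rec(patient="", allele_freq=0.25)]
        assert filter_germline_by_frequency(records) == records

    def test_zero_threshold(self):
        records = [rec(patient="", allele_freq=0.001), rec(patient="", allele_freq=0.0)]
        assert filter_germline_by_frequency(records, 0.0) == records[:1]

    def test_missing_freq_dropped(self, caplog):
        assert filter_germline_by_frequency([rec(patient="")]) == []


class TestTallyGroupCounts:
    def test_basic_counts(self):
        records = [
            rec(pos=i, effect=Effect.MISSENSE, func_class_sift=FUNC_MF)
            for i in range(1, 4)
        ] + [rec(pos=5, effect=Effect.SYNONYMOUS)]
        counts = tally_group_counts(records, {"g1"})
        assert counts.n == 3 and counts.s == 1 and counts.mf_sift == 3

    def test_outside_gene_set_not_counted(self):
        counts = tally_group_counts([rec(gene="gX", effect=Effect.MISSENSE)], {"g1"})
        assert counts.n == 0

    def test_empty_gene_set_warns_zero(self):
        counts = tally_group_counts([rec(effect=Effect.MISSENSE)], set())
        assert counts.n == 0 and counts.s == 0

    def test_mf_plus_lf_bounded_by_n(self, rng):
        labels = [FUNC_MF, "LF", FUNC_UNSCORED]
        records = [
            rec(
                pos=int(rng.integers(1, 50)),
                effect=Effect.MISSENSE,
                func_class_sift=labels[rng.integers(3)],
            )
            for _ in range(200)
        ]
        counts = tally_group_counts(records, {"g1"})
        assert counts.mf_sift + counts.lf_sift <= counts.n

    def test_additive_over_disjoint_sets(self, rng):
        records = _random_cohort(rng)
        genes = {r.gene_id for r in records}
        set_a = {g for g in genes if g < "g2"}
        set_b = genes - set_a
        a = tally_group_counts(records, set_a)
        b = tally_group_counts(records, set_b)
        both = tally_group_counts(records, genes)
        assert (a.n + b.n, a.s + b.s) == (both.n, both.s)


class TestPatientCoverage:
    def test_worked_percentages(self):
        patients = [f"p{i:03d}" for i in range(772)]
        drivers = {f"d{i}" for i in range(15)}
        hits = [rec(patient=p, gene="d1") for p in patients[360:]]
        summary = patient_zero_hit_summary(hits, drivers, patients)
        assert summary["n_zero_hit"] == 360
        assert round(summary["pct_zero_hit"], 1) == 46.6

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            patient_zero_hit_summary([], {"g"}, [])


class TestIO:
    def test_maf_round_trip(self, tmp_path):
        records = [rec(), rec(pos=2, variant_class="frameshift_indel", alt="A",
                             frameshift_flag=True)]
        path = tmp_path / "somatic.tsv"
        write_maf(records, path)
        back = read_maf(path)
        assert [(r.patient_id, r.gene_id, r.cds_pos, r.variant_class) for r in back] == [
            ("p1", "g1", 1, "SNV"),
            ("p1", "g1", 2, "frameshift_indel"),
        ]
        assert back[1].frameshift_flag

    def test_maf_missing_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("patient_id\tgene_id\np1\tg1\n")
        with pytest.raises(ValidationError):
            read_maf(path)

    def test_maf_unknown_variant_class(self, tmp_path):
        path = tmp_path / "bad.tsv"
        write_maf([rec()], path)
        path.write_text(path.read_text().replace("SNV", "weird"))
        with pytest.raises(ValidationError):
            read_maf(path)

    def test_vcf_round_trip(self, tmp_path, rng):
        from somasel.synthetic_data import write_germline_vcf

        models = [GeneModel("g1", "t1", random_cds(rng, 20))]
        records = [
            SubstitutionRecord("", "g1", "t1", 5, models[0].cds[4], "A"
                               if models[0].cds[4] != "A" else "C",
                               allele_freq=0.42),
        ]
        path = tmp_path / "germ.vcf"
        write_germline_vcf(records, models, path)
        back = read_germline_vcf(path)
        assert len(back) == 1
        assert back[0].allele_freq == pytest.approx(0.42, abs=1e-5)
        assert back[0].cds_pos == 5
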
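import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_pph_table, make_sift_table, random_cds
from somasel.errors import SchemeMismatchError, ValidationError
from somasel.site_counting import (
    Effect,
    FunctionalityTable,
    GeneModel,
    Scheme,
    aggregate_site_counts,
    count_functional_sites,
    count_syn_nonsyn_sites,
    compute_site_counts,
    enumerate_possible_changes,
    read_cds_fasta,
    read_functionality_table,
    read_site_counts_tsv,
    write_cds_fasta,
    write_functionality_table,
    write_site_counts_tsv,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_change_counts(cds: str) -> dict[str, int]:
    """Independent oracle: translate all 9 mutated codons per position."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOPS:
        codons = codons[:-1]
    out = {"syn": 0, "missense": 0, "nonsense": 0, "codons": 0}
    for codon in codons:
        if any(b not in "ACGT" for b in codon):
            continue
        out["codons"] += 1
        aa = str(Seq(codon).translate())
        for pos in range(3):
            for alt in "ACGT":
                if alt == codon[pos]:
                    continue
                mut_aa = str(Seq(codon[:pos] + alt + codon[pos + 1 :]).translate())
                if mut_aa == "*":
                    out["nonsense"] += 1
                elif mut_aa == aa:
                    out["syn"] += 1
                else:
                    out["missense"] += 1
    return out


class TestEnumeratePossibleChanges:
    def test_atg_all_nonsynonymous(self):
        changes = enumerate_possible_changes("ATG")
        assert len(changes) == 9
        assert all(e in (Effect.MISSENSE, Effect.NONSENSE) for _, _, e in changes)
        assert sum(e is Effect.SYNONYMOUS for _, _, e in changes) == 0

    def test_ttt_single_synonymous(self):
        changes = enumerate_possible_changes("TTT")
        syn = [(p, a) for p, a, e in changes if e is Effect.SYNONYMOUS]
        assert syn == [(2, "C")]  # TTT -> TTC, both Phe
        assert len(changes) == 9

    def test_tgg_contains_both_stop_gains(self):
        changes = enumerate_possible_changes("TGG")
        nonsense = {(p, a) for p, a, e in changes if e is Effect.NONSENSE}
        assert (1, "A") in nonsense  # TGG -> TAG
        assert (2, "A") in nonsense  # TGG -> TGA

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_possible_changes("ANT")

    def test_stop_codon_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_possible_changes("TAA")

    @given(st.text(alphabet="ACGT", min_size=3, max_size=3))
    @settings(max_examples=64, deadline=None)
    def test_effects_match_translation(self, codon):
        if codon in STOPS:
            return
        aa = str(Seq(codon).translate())
        changes = enumerate_possible_changes(codon)
        assert len(changes) == 9
        for pos, alt, effect in changes:
            assert alt != codon[pos]
            mut_aa = str(Seq(codon[:pos] + alt + codon[pos + 1 :]).translate())
            expected = (
                Effect.NONSENSE
                if mut_aa == "*"
                else Effect.SYNONYMOUS if mut_aa == aa else Effect.MISSENSE
            )
            assert effect is expected


class TestCountSynNonsynSites:
    def test_single_codon_atg(self):
        sc = count_syn_nonsyn_sites(GeneModel("g", "t", "ATG"))
        assert sc.N == 3.0 and sc.S == 0.0

    def test_single_codon_ttt(self):
        sc = count_syn_nonsyn_sites(GeneModel("g", "t", "TTT"))
        assert sc.nonsyn_changes == 8 and sc.syn_changes == 1
        assert sc.N == pytest.approx(8 / 3) and sc.S == pytest.approx(1 / 3)

    def test_terminal_stop_excluded(self):
        with_stop = count_syn_nonsyn_sites(GeneModel("g", "t", "ATGTTTTAA"))
        without = count_syn_nonsyn_sites(GeneModel("g", "t", "ATGTTT"))
        assert with_stop == without
        assert with_stop.n_codons_counted == 2

    def test_internal_stop_fails_validation(self):
        with pytest.raises(ValidationError):
            count_syn_nonsyn_sites(GeneModel("g", "t", "ATGTAAATG"))

    def test_length_not_multiple_of_three(self):
        with pytest.raises(ValidationError):
            count_syn_nonsyn_sites(GeneModel("g", "t", "ATGT"))

    def test_ambiguous_codon_skipped_and_decremented(self):
        sc = count_syn_nonsyn_sites(GeneModel("g", "t", "ATGNNNTTT"))
        assert sc.n_codons_counted == 2
        assert sc.n_codons_skipped == 1
        assert sc.nonsyn_changes + sc.syn_changes == 18

    def test_conservation_identity(self, rng):
        for _ in range(50):
            cds = random_cds(rng, int(rng.integers(1, 40)))
            sc = count_syn_nonsyn_sites(GeneModel("g", "t", cds))
            assert sc.nonsyn_changes + sc.syn_changes == 9 * sc.n_codons_counted
            assert sc.N + sc.S == pytest.approx(3 * sc.n_codons_counted, abs=1e-9)

    def test_oracle_equivalence_random_cdss(self, rng):
        for _ in range(100):
            cds = random_cds(rng, int(rng.integers(1, 60)))
            sc = count_syn_nonsyn_sites(GeneModel("g", "t", cds))
            oracle = brute_force_change_counts(cds)
            assert sc.syn_changes == oracle["syn"]
            assert sc.nonsyn_changes == oracle["missense"] + oracle["nonsense"]
            assert sc.missense_changes == oracle["missense"]
            assert sc.n_codons_counted == oracle["codons"]

    def test_determinism(self, rng):
        cds = random_cds(rng, 30)
        a = count_syn_nonsyn_sites(GeneModel("g", "t", cds))
        b = count_syn_nonsyn_sites(GeneModel("g", "t", cds))
        assert a == b


def _full_mf_table(gene: GeneModel, score: float) -> FunctionalityTable:
    """Score every possible missense change of the gene at one value."""
    entries = {}
    codons = [gene.cds[i : i + 3] for i in range(0, len(gene.cds), 3)]
    for codon_i, codon in enumerate(codons):
        if codon in STOPS:
            continue
        for pos, alt, effect in enumerate_possible_changes(codon):
            if effect is not Effect.MISSENSE:
                continue
            mut_aa = str(Seq(codon[:pos] + alt + codon[pos + 1 :]).translate())
            entries[(gene.gene_id, codon_i + 1, mut_aa)] = score
    return make_sift_table(entries)


class TestCountFunctionalSites:
    def test_ttt_all_damaging(self):
        gene = GeneModel("g", "t", "TTT")
        sc = count_functional_sites(gene, _full_mf_table(gene, 0.01))
        assert sc.mf_changes_sift == 8 and sc.lf_changes_sift == 0
        assert sc.MF_sift == pytest.approx(8 / 3)

    def test_ttt_all_benign(self):
        gene = GeneModel("g", "t", "TTT")
        sc = count_functional_sites(gene, _full_mf_table(gene, 0.5))
        assert sc.mf_changes_sift == 0 and sc.lf_changes_sift == 8

    def test_score_exactly_at_cutoff_is_damaging(self):
        gene = GeneModel("g", "t", "TTT")
        sc = count_functional_sites(gene, _full_mf_table(gene, 0.05))
        assert sc.mf_changes_sift == 8

    def test_stop_gain_changes_excluded_from_mf_lf(self):
        gene = GeneModel("g", "t", "TGG")  # has 2 stop-gain changes
        sc = count_functional_sites(gene, _full_mf_table(gene, 0.01))
        assert sc.mf_changes_sift + sc.lf_changes_sift == 7
        assert sc.nonsyn_changes == 9

    def test_unscored_changes_counted_separately(self):
        gene = GeneModel("g", "t", "ATGTTT")
        table = make_sift_table({("g", 2, "I"): 0.01})  # TTT->ATT (Ile) only
        sc = count_functional_sites(gene, table)
        assert sc.mf_changes_sift == 1
        assert sc.lf_changes_sift == 0
        assert sc.unscored_changes_sift == sc.missense_changes - 1

    def test_empty_table_warns_zero(self, caplog):
        gene = GeneModel("g", "t", "ATGTTT")
        sc = count_functional_sites(gene, FunctionalityTable(scheme=Scheme.SIFT))
        assert sc.mf_changes_sift == 0 and sc.lf_changes_sift == 0

    def test_scheme_mismatch_raises(self):
        gene = GeneModel("g", "t", "ATGTTT")
        with pytest.raises(SchemeMismatchError):
            count_functional_sites(
                gene, FunctionalityTable(scheme=Scheme.SIFT), Scheme.POLYPHEN
            )

    def test_polyphen_classes(self):
        gene = GeneModel("g", "t", "TTT")
        entries = {}
        codons = ["TTT"]
        for pos, alt, effect in enumerate_possible_changes("TTT"):
            if effect is Effect.MISSENSE:
                mut_aa = str(Seq("TTT"[:pos] + alt + "TTT"[pos + 1 :]).translate())
                entries[("g", 1, mut_aa)] = "possibly_damaging"
        sc = count_functional_sites(gene, make_pph_table(entries))
        assert sc.mf_changes_pph == 8 and sc.lf_changes_pph == 0

    def test_complete_table_mf_plus_lf_equals_missense_sites(self, rng):
        cds = random_cds(rng, 20)
        gene = GeneModel("g", "t", cds)
        sc = count_functional_sites(gene, _full_mf_table(gene, 0.03))
        assert sc.mf_changes_sift + sc.lf_changes_sift == sc.missense_changes
        assert sc.MF_sift + sc.LF_sift == pytest.approx(sc.N_missense, abs=1e-9)


class TestAggregation:
    def test_aggregate_sums_fields(self, rng):
        genes = [GeneModel(f"g{i}", f"t{i}", random_cds(rng, 10)) for i in range(5)]
        counts = [count_syn_nonsyn_sites(g) for g in genes]
        total = aggregate_site_counts(counts)
        assert total.syn_changes == sum(c.syn_changes for c in counts)
        assert total.n_codons_counted == 50

    def test_aggregate_respects_gene_set(self, rng):
        genes = [GeneModel(f"g{i}", f"t{i}", random_cds(rng, 10)) for i in range(5)]
        counts = [count_syn_nonsyn_sites(g) for g in genes]
        sub = aggregate_site_counts(counts, {"g0", "g1"})
        assert sub.n_codons_counted == 20


class TestIO:
    def test_fasta_round_trip(self, tmp_path, small_models):
        path = tmp_path / "cds.fasta"
        write_cds_fasta(small_models, path)
        back = read_cds_fasta(path)
        assert back == small_models

    def test_fasta_missing_gene_attr(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">t1 nothing=here\nATGTTT\n")
        with pytest.raises(ValidationError):
            read_cds_fasta(path)

    def test_functionality_table_round_trip(self, tmp_path):
        table = make_sift_table({("g1", 3, "W"): 0.02, ("g2", 1, "A"): 0.9})
        path = tmp_path / "sift.tsv"
        write_functionality_table(table, path)
        back = read_functionality_table(path, Scheme.SIFT)
        assert back.entries == pytest.approx(table.entries)

    def test_site_counts_round_trip(self, tmp_path, rng):
        genes = [GeneModel(f"g{i}", f"t{i}", random_cds(rng, 12)) for i in range(4)]
        counts = [compute_site_counts(g) for g in genes]
        path = tmp_path / "sites.tsv"
        write_site_counts_tsv(counts, path)
        back = read_site_counts_tsv(path)
        for c in counts:
            assert back[c.gene_id] == c

    def test_sift_score_out_of_range(self):
        with pytest.raises(ValidationError):
            make_sift_table({("g", 1, "A"): 1.5})

    def test_unknown_polyphen_class(self):
        with pytest.raises(ValidationError):
            make_pph_table({("g", 1, "A"): "bad_class"})
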
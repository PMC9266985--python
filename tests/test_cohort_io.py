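"""Mutation/clinical table parsing, the binary matrix, TMB, binarization."""

import numpy as np
import pandas as pd
import pytest

from comutsig.cohort_io import (
    FormatError,
    MutationRecord,
    MutationTable,
    binarize_clinical,
    build_mutation_matrix,
    compute_tmb,
    read_clinical,
    read_mutations,
    write_clinical,
    write_mutations,
)

MAF_HEADER = ("Tumor_Sample_Barcode\tHugo_Symbol\tChromosome\tStart_Position\t"
              "Reference_Allele\tTumor_Seq_Allele2\tVariant_Type\n")


def write_maf(tmp_path, rows, name="muts.maf"):
    p = tmp_path / name
    p.write_text(MAF_HEADER + "".join(r + "\n" for r in rows))
    return p


class TestReadMutations:
    def test_parses_classes_from_maf_dialect(self, tmp_path):
        p = write_maf(tmp_path, [
            "s1\tTP53\tchr17\t100\tC\tT\tSNP",
            "s1\tAPC\tchr5\t200\tA\t-\tDEL",
            "s2\tKRAS\tchr12\t300\tG\tT\tFUSION",
        ])
        t = read_mutations(p)
        assert len(t) == 3
        assert {r.variant_class for r in t} == {"SNV", "DEL", "FUSION"}

    def test_empty_file_with_header_is_empty_table(self, tmp_path):
        p = write_maf(tmp_path, [])
        t = read_mutations(p)
        assert len(t) == 0 and not t.invalid

    def test_exact_duplicate_rows_are_deduplicated(self, tmp_path):
        row = "s1\tTP53\tchr17\t100\tC\tT\tSNP"
        t = read_mutations(write_maf(tmp_path, [row, row]))
        assert len(t) == 1
        assert t.n_deduplicated == 1

    def test_missing_required_column_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("sample\tgene\n" "s1\tTP53\n")
        with pytest.raises(FormatError, match="missing required column"):
            read_mutations(p)

    def test_non_acgt_snv_collected_not_fatal(self, tmp_path):
        p = write_maf(tmp_path, [
            "s1\tTP53\tchr17\t100\tX\tT\tSNP",
            "s1\tAPC\tchr5\t200\tC\tT\tSNP",
        ])
        t = read_mutations(p)
        assert len(t) == 1
        assert len(t.invalid) == 1 and t.invalid[0][0] == 2  # file line number

    def test_round_trip_preserves_all_fields(self, toy_mutations, tmp_path):
        out = tmp_path / "native.tsv"
        write_mutations(toy_mutations, out)
        again = read_mutations(out)
        assert again.records == toy_mutations.records


class TestMutationMatrix:
    def test_indicator_and_lexicographic_gene_order(self):
        t = MutationTable([
            MutationRecord("s1", "TP53", "c", 1, "C", "T", "SNV"),
            MutationRecord("s1", "TP53", "c", 9, "C", "G", "SNV"),
            MutationRecord("s2", "APC", "c", 5, "A", "G", "SNV"),
        ])
        m = build_mutation_matrix(t, ["s1", "s2"], min_mutated_samples=1)
        assert m.genes == ["APC", "TP53"]
        assert m.values.tolist() == [[0, 1], [1, 0]]

    def test_prevalence_filter_drops_rare_genes(self):
        t = MutationTable([
            MutationRecord("s1", "TP53", "c", 1, "C", "T", "SNV"),
            MutationRecord("s2", "APC", "c", 5, "A", "G", "SNV"),
        ])
        m = build_mutation_matrix(t, ["s1", "s2"], min_mutated_samples=2)
        assert m.genes == [] and m.values.shape == (0, 2)

    def test_prevalence_threshold_is_inclusive(self, small_cohort):
        samples = [r.sample_id for r in small_cohort.clinical]
        m1 = build_mutation_matrix(small_cohort.mutations, samples, 1)
        counts = m1.values.sum(axis=1)
        assert counts.min() >= 1
        threshold = int(counts.min()) + 1
        m2 = build_mutation_matrix(small_cohort.mutations, samples, threshold)
        expect = [g for g, c in zip(m1.genes, counts) if c >= threshold]
        assert m2.genes == expect

    def test_unknown_sample_named_in_error(self, toy_mutations):
        with pytest.raises(ValueError, match="s3"):
            build_mutation_matrix(toy_mutations, ["s1", "s2"], 1)

    def test_column_sums_match_independent_record_scan(self, small_cohort):
        samples = [r.sample_id for r in small_cohort.clinical]
        m = build_mutation_matrix(small_cohort.mutations, samples, 1)
        col_sums = dict(zip(m.samples, m.values.sum(axis=0)))
        independent = {s: set() for s in samples}
        for r in small_cohort.mutations:
            independent[r.sample_id].add(r.gene)
        for s in samples:
            assert col_sums[s] == len(independent[s])

    def test_zero_mutation_samples_kept_as_zero_columns(self, toy_mutations):
        m = build_mutation_matrix(toy_mutations, ["s1", "s2", "s3", "s9"], 1)
        assert m.values[:, m.samples.index("s9")].sum() == 0


class TestTMB:
    def test_boundary_count_is_high(self):
        recs = [MutationRecord("s1", "G", "c", i + 1, "C", "T", "SNV")
                for i in range(20)]
        tmb = compute_tmb(MutationTable(recs), panel_mb=2.0)
        assert tmb.loc["s1", "tmb"] == 10.0
        assert tmb.loc["s1", "tmb_class"] == "high"

    def test_no_mutations_is_low(self):
        tmb = compute_tmb(MutationTable([]), panel_mb=2.0, samples=["s1"])
        assert tmb.loc["s1", "tmb"] == 0.0
        assert tmb.loc["s1", "tmb_class"] == "low"

    def test_cnv_and_fusion_excluded_from_burden(self):
        recs = [MutationRecord("s1", "G", "c", i + 1, "C", "T", "SNV")
                for i in range(19)]
        recs.append(MutationRecord("s1", "G2", "c", 99, "C", "T", "CNV"))
        tmb = compute_tmb(MutationTable(recs), panel_mb=2.0)
        assert tmb.loc["s1", "tmb"] == pytest.approx(9.5)
        assert tmb.loc["s1", "tmb_class"] == "low"

    def test_linear_in_mutation_count(self):
        recs = [MutationRecord("s1", "G", "c", i + 1, "C", "T", "SNV")
                for i in range(8)]
        one = compute_tmb(MutationTable(recs[:4]), panel_mb=1.5)
        two = compute_tmb(MutationTable(recs), panel_mb=1.5)
        assert two.loc["s1", "tmb"] == pytest.approx(2 * one.loc["s1", "tmb"])

    def test_nonpositive_panel_rejected(self):
        with pytest.raises(ValueError, match="panel_mb"):
            compute_tmb(MutationTable([]), panel_mb=0.0)


class TestBinarizeClinical:
    def read(self, tmp_path, rows):
        p = tmp_path / "clin.tsv"
        p.write_text(
            "sample\tage\tgender\tstage\tgrade\tsite\tmsi\tfamily_history\n"
            + "".join(r + "\n" for r in rows)
        )
        return read_clinical(p)

    def test_age_cut_at_sixty(self, tmp_path):
        recs = self.read(tmp_path, [
            "s1\t59\tmale\tIII\tlow\trectum\tMSS\t",
            "s2\t60\tmale\tIII\tlow\trectum\tMSS\t",
        ])
        clin = binarize_clinical(recs)
        assert clin.row("age_old").tolist() == [0.0, 1.0]

    def test_sidedness_vocabulary(self, tmp_path):
        recs = self.read(tmp_path, [
            "s1\t50\tmale\tIII\tlow\tcecum\tMSS\t",
            "s2\t50\tmale\tIII\tlow\tsigmoid colon\tMSS\t",
            "s3\t50\tmale\tIII\tlow\tappendix\tMSS\t",
        ])
        side = binarize_clinical(recs).row("sidedness_right")
        assert side[0] == 1.0 and side[1] == 0.0 and np.isnan(side[2])

    def test_family_history_needs_first_degree_relative(self, tmp_path):
        recs = self.read(tmp_path, [
            "s1\t50\tmale\tIII\tlow\trectum\tMSS\tsibling:lung:70",
            "s2\t50\tmale\tIII\tlow\trectum\tMSS\t",
            "s3\t50\tmale\tIII\tlow\trectum\tMSS\t.",
            "s4\t50\tmale\tIII\tlow\trectum\tMSS\tcousin:lung:70",
        ])
        fh = binarize_clinical(recs).row("family_history")
        assert fh[0] == 1.0 and fh[1] == 0.0 and np.isnan(fh[2])
        assert fh[3] == 0.0  # second-degree relative does not count

    def test_msi_and_tmb_inputs(self, tmp_path):
        recs = self.read(tmp_path, [
            "s1\t50\tfemale\tIV\thigh\trectum\tMSI-H\t",
            "s2\t50\tfemale\tIV\thigh\trectum\t.\t",
        ])
        clin = binarize_clinical(recs, tmb_class={"s1": "high", "s2": "low"})
        assert clin.row("msi_high")[0] == 1.0 and np.isnan(clin.row("msi_high")[1])
        assert clin.row("tmb_high").tolist() == [1.0, 0.0]

    def test_total_on_simulated_cohort_with_missingness(self, small_cohort):
        clin = binarize_clinical(small_cohort.clinical)
        assert clin.values.shape == (8, 80)
        valid = np.isnan(clin.values) | np.isin(clin.values, [0.0, 1.0])
        assert valid.all()

    def test_clinical_round_trip(self, small_cohort, tmp_path):
        out = tmp_path / "clin.tsv"
        write_clinical(small_cohort.clinical, out)
        again = read_clinical(out)
        assert again == small_cohort.clinical
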
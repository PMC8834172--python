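"""Domain table IO and per-domain conservation scoring."""

import numpy as np
import pandas as pd
import pytest

from scnpair.align import PairwiseAlignment, global_align, percent_identity
from scnpair.domains import (
    DomainAnnotation,
    DomainTableError,
    read_conservation_report,
    read_domain_table,
    read_uniprot_feature_gff,
    score_domains,
    proteinwide_identity,
    write_conservation_report,
    write_domain_table,
)
from scnpair.records import ProteinRecord
from scnpair.synthetic import (
    DomainDivergenceSpec,
    ParalogFamilySpec,
    simulate_paralog_family,
)


def table(tmp_path, rows, header="label\tclass\tchannel_domain\tstart\tend"):
    path = tmp_path / "domains.tsv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadDomainTable:
    def test_well_formed_table_sorted_by_start(self, tmp_path):
        path = table(
            tmp_path,
            [
                "DII-S4\tTM_segment\tII\t120\t145",
                "N-term\tN_terminus\t\t1\t90",
                "loopA\textracellular_loop\tI\t95\t110",
            ],
        )
        doms = read_domain_table(path)
        assert [d.label for d in doms] == ["N-term", "loopA", "DII-S4"]
        assert doms[2].channel_domain == "II"
        assert not any(d.short_peptide for d in doms)

    def test_end_before_start_names_the_row(self, tmp_path):
        path = table(tmp_path, ["bad\tother\t\t50\t40"])
        with pytest.raises(DomainTableError, match="bad"):
            read_domain_table(path)

    def test_short_span_marked_as_short_peptide(self, tmp_path):
        path = table(tmp_path, ["tiny\tpore_loop\t\t10\t13", "ok\tother\t\t20\t24"])
        doms = read_domain_table(path)
        assert doms[0].short_peptide and not doms[1].short_peptide

    def test_overlap_error_lists_offenders(self, tmp_path):
        path = table(
            tmp_path, ["a\tother\t\t1\t50", "b\tother\t\t40\t80", "c\tother\t\t90\t99"]
        )
        with pytest.raises(DomainTableError, match="a overlaps b"):
            read_domain_table(path)

    def test_out_of_bounds_span_rejected(self, tmp_path):
        path = table(tmp_path, ["far\tother\t\t90\t150"])
        with pytest.raises(DomainTableError, match="reference length"):
            read_domain_table(path, ref_length=100)

    def test_write_read_round_trip(self, tmp_path):
        doms = [
            DomainAnnotation("a", "TM_segment", 5, 30, "I"),
            DomainAnnotation("b", "cytoplasmic_linker", 40, 42, short_peptide=True),
        ]
        path = tmp_path / "out.tsv"
        write_domain_table(doms, path)
        back = read_domain_table(path)
        assert [(d.label, d.klass, d.start, d.end, d.channel_domain, d.short_peptide) for d in back] == [
            ("a", "TM_segment", 5, 30, "I", False),
            ("b", "cytoplasmic_linker", 40, 42, None, True),
        ]

    def test_uniprot_gff_import(self, tmp_path):
        gff = tmp_path / "features.gff"
        gff.write_text(
            "##gff-version 3\n"
            "P35498\tUniProtKB\tTopological domain\t1\t125\t.\t.\t.\tNote=Cytoplasmic\n"
            "P35498\tUniProtKB\tTransmembrane\t126\t144\t.\t.\t.\tNote=Helical\n"
            "P35498\tUniProtKB\tChain\t1\t2000\t.\t.\t.\tID=PRO_1\n"
        )
        doms = read_uniprot_feature_gff(gff)
        assert len(doms) == 2
        assert doms[0].klass == "cytoplasmic_linker"
        assert doms[1].klass == "TM_segment"
        assert (doms[1].start, doms[1].end) == (126, 144)


def hand_alignment(ref_row, a_row, b_row, blosum):
    return (
        PairwiseAlignment(row_ref=ref_row, row_qry=a_row, score=0, scheme=blosum),
        PairwiseAlignment(row_ref=ref_row, row_qry=b_row, score=0, scheme=blosum),
    )


class TestScoreDomains:
    def test_identical_paralogs_score_100_no_flags(self, blosum):
        ref = ProteinRecord("r", "ACDEFGHIKL")
        aln = global_align(ref, ProteinRecord("p", ref.residues), blosum)
        recs = score_domains(aln, aln, [DomainAnnotation("all", "other", 1, 10)])
        assert recs[0].identity_a == recs[0].identity_b == 100.0
        assert recs[0].delta == 0.0 and not recs[0].flagged

    def test_differentially_diverged_domain_is_flagged(self, blosum):
        spec = ParalogFamilySpec(
            ref_length=260,
            domains=(
                DomainDivergenceSpec("hot", "other", 1, 200, 0.5, 0.05),
                DomainDivergenceSpec("cold", "other", 221, 260, 0.05, 0.05),
            ),
            inter_domain_divergence=0.05,
            seed=21,
        )
        truth = simulate_paralog_family(spec)
        aln_a = global_align(truth.reference, truth.paralog_a, blosum)
        aln_b = global_align(truth.reference, truth.paralog_b, blosum)
        recs = score_domains(aln_a, aln_b, list(truth.annotations))
        flagged = {r.annotation.label for r in recs if r.flagged}
        assert flagged == {"hot"} == set(truth.expected_flagged)

    def test_delta_of_exactly_20_is_not_flagged(self, blosum):
        # 10-residue domain: paralog A matches 7, paralog B matches 9 -> delta 20.0
        ref_row = "AAAAAAAAAA"
        a_row = "AAAAAAACCC"
        b_row = "AAAAAAAAAC"
        aln_a, aln_b = hand_alignment(ref_row, a_row, b_row, blosum)
        rec = score_domains(aln_a, aln_b, [DomainAnnotation("d", "other", 1, 10)])[0]
        assert rec.delta == pytest.approx(20.0)
        assert not rec.flagged

    def test_delta_just_over_20_is_flagged(self, blosum):
        ref_row = "AAAAAAAAA"  # 9 residues: 6/9 vs 8/9 -> delta 22.2
        aln_a, aln_b = hand_alignment(ref_row, "AAAAAACCC", "AAAAAAAAC", blosum)
        rec = score_domains(aln_a, aln_b, [DomainAnnotation("d", "other", 1, 9)])[0]
        assert rec.flagged

    def test_mismatched_references_rejected(self, blosum):
        aln_a = PairwiseAlignment(row_ref="ACD", row_qry="ACD", score=0, scheme=blosum)
        aln_b = PairwiseAlignment(row_ref="ACE", row_qry="ACE", score=0, scheme=blosum)
        with pytest.raises(DomainTableError, match="different reference"):
            score_domains(aln_a, aln_b, [DomainAnnotation("d", "other", 1, 3)])

    def test_paralog_gaps_count_as_mismatches(self, blosum):
        aln_a, aln_b = hand_alignment("ACDEF", "AC--F", "ACDEF", blosum)
        rec = score_domains(aln_a, aln_b, [DomainAnnotation("d", "other", 1, 5)])[0]
        assert rec.identity_a == pytest.approx(60.0)
        assert rec.identity_b == 100.0

    def test_column_sum_consistency(self, blosum):
        """Matches summed over a covering partition equal protein-wide matches."""
        rng = np.random.default_rng(17)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        ref = ProteinRecord("r", "".join(aa[i] for i in rng.integers(0, 20, 60)))
        qry = ProteinRecord("q", "".join(aa[i] for i in rng.integers(0, 20, 55)))
        aln = global_align(ref, qry, blosum)
        parts = [DomainAnnotation(f"p{i}", "other", 1 + 15 * i, 15 * (i + 1)) for i in range(4)]
        recs = score_domains(aln, aln, parts)
        # identity_a of each part is over that part's reference residues (15 each)
        total_matches = sum(r.identity_a / 100 * 15 for r in recs)
        pw = proteinwide_identity(aln)
        assert total_matches == pytest.approx(pw / 100 * 60)

    def test_monotonicity_in_divergence(self):
        """Mean identity never increases as divergence_a grows."""
        means = []
        for d in (0.1, 0.3, 0.6):
            ids = [
                simulate_paralog_family(
                    ParalogFamilySpec(
                        ref_length=300,
                        domains=(DomainDivergenceSpec("d", "other", 1, 300, d, 0.0),),
                        seed=s,
                    )
                ).realized_identity_a["d"]
                for s in range(10)
            ]
            means.append(np.mean(ids))
        assert means[0] > means[1] > means[2]


class TestProteinwideIdentity:
    def test_identical_sequences(self, blosum):
        aln = global_align(ProteinRecord("a", "MKVL"), ProteinRecord("b", "MKVL"), blosum)
        assert proteinwide_identity(aln) == 100.0

    def test_disjoint_toy_alphabets_give_zero(self, blosum):
        aln = global_align(ProteinRecord("a", "AAAA"), ProteinRecord("b", "DDDD"), blosum)
        assert proteinwide_identity(aln) == 0.0


class TestReport:
    def test_report_row_count_and_summary(self, tmp_path, blosum):
        ref = ProteinRecord("r", "ACDEFGHIKL" * 3)
        aln = global_align(ref, ProteinRecord("p", ref.residues), blosum)
        doms = [DomainAnnotation(f"d{i}", "other", 1 + 10 * i, 10 * (i + 1)) for i in range(3)]
        recs = score_domains(aln, aln, doms)
        out = tmp_path / "report.tsv"
        summary = write_conservation_report(recs, out)
        df = read_conservation_report(out)
        assert len(df) == 3
        assert "0 flagged" in summary

    def test_round_trip_preserves_values(self, tmp_path, blosum):
        aln_a = PairwiseAlignment(row_ref="AAAAA", row_qry="AACCC", score=0, scheme=blosum)
        aln_b = PairwiseAlignment(row_ref="AAAAA", row_qry="AAAAA", score=0, scheme=blosum)
        recs = score_domains(aln_a, aln_b, [DomainAnnotation("d", "other", 1, 5)])
        out = tmp_path / "report.tsv"
        write_conservation_report(recs, out)
        df = read_conservation_report(out)
        assert df.loc[0, "identity_a"] == pytest.approx(40.0)
        assert df.loc[0, "identity_b"] == pytest.approx(100.0)
        assert df.loc[0, "delta"] == pytest.approx(60.0)
        assert bool(df.loc[0, "flagged"])

    def test_empty_record_list_rejected(self, tmp_path):
        with pytest.raises(DomainTableError):
            write_conservation_report([], tmp_path / "x.tsv")
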
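"""Alignment handling, P3 base frequencies and I-P3 identification."""

import pytest

from mitobias import code, simulate
from mitobias.comparative import (
    CodonAlignment,
    identify_ip3_sites,
    load_and_filter_records,
    p3_base_frequencies,
    ungap_on_reference,
)
from mitobias.mutagenesis import GenomeParseError


def aln(rows: dict[str, str], gene="G1", reference=None) -> CodonAlignment:
    taxa = tuple(rows)
    return CodonAlignment(gene=gene, taxa=taxa,
                          rows=tuple(rows.values()),
                          reference_id=reference or taxa[0])


class TestUngapOnReference:
    def test_reference_gap_columns_removed(self):
        a = ungap_on_reference(aln({"ref": "A-CG", "t1": "ATCG"}))
        assert a.row("ref") == "ACG"
        assert a.row("t1") == "ACG"  # the T falls with its column

    def test_gap_free_alignment_unchanged(self):
        original = aln({"ref": "ATG", "t1": "ATA"})
        assert ungap_on_reference(original).rows == original.rows

    def test_gap_block_removed(self):
        a = ungap_on_reference(aln({"ref": "AT---G", "t1": "ATCCCG"}))
        assert a.length == 3 and a.row("t1") == "ATG"

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            aln({"t1": "ATG"}, reference="nope")


class TestP3BaseFrequencies:
    def test_constructed_composition(self):
        # every Gly codon ends in A
        a = aln({"t1": "GGAGGA", "t2": "GGAGGA"})
        freqs = p3_base_frequencies([a])
        gly = freqs[freqs["trna_family"] == "G"]
        assert len(gly) == 1
        assert gly.iloc[0]["base"] == "A"
        assert gly.iloc[0]["frequency"] == 1.0
        assert gly.iloc[0]["count"] == 4

    def test_frequencies_sum_to_one_per_family(self, evolution_run):
        _, alignment, _ = evolution_run
        freqs = p3_base_frequencies([alignment])
        sums = freqs.groupby("trna_family")["frequency"].sum()
        assert (abs(sums - 1.0) < 1e-12).all()

    def test_matches_brute_force_on_fixture(self):
        a = aln({"t1": "GGAGGTCTA", "t2": "GGCGGTCTG"})
        freqs = p3_base_frequencies([a]).set_index(["trna_family", "base"])
        assert freqs.loc[("G", "A"), "count"] == 1
        assert freqs.loc[("G", "C"), "count"] == 1
        assert freqs.loc[("G", "T"), "count"] == 2
        assert freqs.loc[("L2", "A"), "count"] == 1
        assert freqs.loc[("G", "T"), "frequency"] == pytest.approx(0.5)

    def test_gap_and_stop_codons_excluded(self):
        a = aln({"t1": "GG-AGATAA", "t2": "GGAAGATAA"})
        freqs = p3_base_frequencies([a])
        # AGA and TAA are stops; the gapped GG- codon is dropped
        assert freqs["count"].sum() == 1

    def test_frame_violation_names_gene(self):
        with pytest.raises(ValueError, match="G1"):
            p3_base_frequencies([aln({"t1": "GGAA", "t2": "GGAA"})])


class TestIdentifyIP3:
    def test_fully_degenerate_gly_site(self):
        a = aln({"t1": "GGA", "t2": "GGC", "t3": "GGG", "t4": "GGT"})
        sites = identify_ip3_sites([a])
        assert len(sites) == 1
        row = sites.iloc[0]
        assert row["amino_acid"] == "Gly"
        assert row["observed_p3_bases"] == "ACGT"
        assert bool(row["fully_degenerate"])

    def test_position_2_mismatch_disqualifies(self):
        a = aln({"t1": "GGA", "t2": "GAA", "t3": "GGG"})
        assert identify_ip3_sites([a]).empty

    def test_amino_acid_must_be_constant(self):
        # TG prefix splits Cys (TGY) from Trp (TGR): not an I-P3
        a = aln({"t1": "TGC", "t2": "TGA"})
        assert identify_ip3_sites([a]).empty

    def test_serine_resolved_to_family(self):
        s1 = identify_ip3_sites([aln({"t1": "TCA", "t2": "TCC"})]).iloc[0]
        s2 = identify_ip3_sites([aln({"t1": "AGC", "t2": "AGT"})]).iloc[0]
        assert s1["trna_family"] == "S1" and s1["degeneracy_class"] == code.FOURFOLD
        assert s2["trna_family"] == "S2"
        assert bool(s2["fully_degenerate"])  # {C,T} is the full S2 set

    def test_leucine_excluded_by_default(self):
        a = aln({"t1": "CTA", "t2": "CTG"})
        assert identify_ip3_sites([a]).empty
        assert len(identify_ip3_sites([a], exclude_leucine=False)) == 1

    def test_stop_codon_rejects_site(self):
        a = aln({"t1": "AGC", "t2": "AGA"})  # AGA is a mitochondrial stop
        assert identify_ip3_sites([a]).empty

    def test_p3_gap_excludes_taxon_not_site(self):
        a = aln({"t1": "GGA", "t2": "GG-", "t3": "GGC"})
        sites = identify_ip3_sites([a])
        assert len(sites) == 1
        assert sites.iloc[0]["observed_p3_bases"] == "AC"

    def test_invariant_under_taxon_reordering_and_duplication(self):
        rows = {"t1": "GGAAAA", "t2": "GGCAAG", "t3": "GGTAAA"}
        base = identify_ip3_sites([aln(rows)])
        reordered = identify_ip3_sites(
            [aln(dict(reversed(list(rows.items()))))]
        )
        duplicated = identify_ip3_sites([aln({**rows, "t4": rows["t3"]})])
        cols = ["codon_index", "amino_acid", "observed_p3_bases",
                "fully_degenerate"]
        assert base[cols].equals(reordered[cols])
        assert base[cols].equals(duplicated[cols])

    def test_translation_consistency(self, evolution_run):
        _, alignment, _ = evolution_run
        sites = identify_ip3_sites([alignment], with_columns=True)
        for row in sites.itertuples():
            codons = {
                alignment.row(t)[3 * (row.codon_index - 1): 3 * row.codon_index]
                for t in alignment.taxa
            }
            aas = {code.translate(c) for c in codons}
            assert aas == {row.amino_acid}


class TestRecordFiltering:
    @staticmethod
    def _thirteen_gene_record(seed: int) -> str:
        genes = tuple(
            simulate.GeneSpec(name, 12)
            for name in sorted(
                ["ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
                 "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB"]
            )
        )
        return simulate.generate_toy_genome(seed=seed, genes=genes, spacer=5)

    def test_complete_unique_records_retained(self):
        records = {f"R{i}": self._thirteen_gene_record(i) for i in (1, 2, 3)}
        genomes, report = load_and_filter_records(records)
        assert len(genomes) == 3
        assert (report["status"] == "parsed").all()

    def test_record_missing_gene_discarded(self, toy_genome_text):
        records = {"full": self._thirteen_gene_record(1),
                   "partial": toy_genome_text}
        genomes, report = load_and_filter_records(records)
        assert len(genomes) == 1
        status = report.set_index("record")["status"]
        assert status["partial"] == "missing_genes"
        detail = report.set_index("record").loc["partial", "detail"]
        assert "ND5" in detail

    def test_duplicate_cds_removes_all_members(self):
        records = {
            "A": self._thirteen_gene_record(1),
            "B": self._thirteen_gene_record(1),  # byte-identical CDSs
            "C": self._thirteen_gene_record(2),
        }
        genomes, report = load_and_filter_records(records)
        assert len(genomes) == 1  # only C survives; A and B are both removed
        status = report.set_index("record")["status"]
        assert (status[["A", "B"]] == "duplicate_cds").all()
        assert status["C"] == "parsed"

    def test_zero_retained_is_pipeline_error(self, toy_genome_text):
        with pytest.raises(GenomeParseError, match="no records"):
            load_and_filter_records({"only": toy_genome_text})
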
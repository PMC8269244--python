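"""Reference-database curation: ANI-based revision, dereplication,
contig filters, size table and on-disk round-trip."""

import pytest

from shallowmeta.align import AlignmentHit
from shallowmeta.refdb import (
    ANIRecord,
    CurationError,
    CurationParams,
    GenomeRecord,
    REASON_GENUS_RETAINED,
    REASON_RECLASSIFIED,
    REASON_UNRESOLVED,
    build_size_table,
    curate,
    dereplicate,
    filter_contigs_by_length,
    read_database,
    remove_host_contigs,
    revise_taxonomy,
    write_database,
)

from conftest import genome, random_seq


@pytest.fixture
def genomes():
    return {
        "REF1": genome("REF1", "Species one", "GenusA", is_reference=True),
        "REF2": genome("REF2", "Species two", "GenusB", is_reference=True),
        "Q1": genome("Q1", "Escherichia coli", "Escherichia"),
        "Q2": genome("Q2", "Species one-like", "GenusA"),
        "Q3": genome("Q3", "Lonely species", "NoSuchGenus"),
    }


class TestReviseTaxonomy:
    def test_strong_ani_hit_reclassifies(self, genomes):
        ani = [ANIRecord("Q1", "REF1", 96.2, 80.0, 78.0)]
        labels, log = revise_taxonomy(genomes, ani)
        assert labels["Q1"].species == "Species one"
        assert labels["Q1"].genus == "GenusA"
        entry = next(e for e in log if e.accession == "Q1")
        assert entry.reason == REASON_RECLASSIFIED

    def test_weak_ani_same_genus_retains_declared(self, genomes):
        ani = [ANIRecord("Q2", "REF1", 90.0, 85.0, 85.0)]
        labels, log = revise_taxonomy(genomes, ani)
        assert labels["Q2"].species == "Species one-like"
        assert next(e for e in log if e.accession == "Q2").reason == REASON_GENUS_RETAINED

    def test_coverage_gate_precedes_ani_gate(self, genomes):
        # high ANI but low query coverage: no reclassification, genus rule applies
        ani = [ANIRecord("Q2", "REF1", 96.0, 60.0, 85.0)]
        labels, log = revise_taxonomy(genomes, ani)
        assert labels["Q2"].species == "Species one-like"
        assert next(e for e in log if e.accession == "Q2").reason == REASON_GENUS_RETAINED

    def test_no_evidence_and_foreign_genus_flags_unresolved(self, genomes):
        labels, log = revise_taxonomy(genomes, [])
        assert labels["Q3"].species == "Lonely species"
        reasons = {e.accession: e.reason for e in log}
        assert reasons["Q1"] == reasons["Q3"] == REASON_UNRESOLVED

    def test_reference_genomes_keep_labels_and_stay_out_of_log(self, genomes):
        ani = [ANIRecord("REF2", "REF1", 99.9, 99.0, 99.0)]
        labels, log = revise_taxonomy(genomes, ani)
        assert labels["REF2"].species == "Species two"
        assert all(e.accession not in ("REF1", "REF2") for e in log)

    def test_closest_reference_tie_break(self, genomes):
        # equal ANI: higher min(cov) wins over accession order
        ani = [
            ANIRecord("Q1", "REF2", 96.0, 90.0, 90.0),
            ANIRecord("Q1", "REF1", 96.0, 80.0, 95.0),
        ]
        labels, _ = revise_taxonomy(genomes, ani)
        assert labels["Q1"].species == "Species two"

    def test_unknown_accession_rejected(self, genomes):
        with pytest.raises(CurationError, match="unknown accession"):
            revise_taxonomy(genomes, [ANIRecord("GHOST", "REF1", 95.0, 80.0, 80.0)])

    def test_reason_vocabulary_is_closed(self, genomes):
        ani = [
            ANIRecord("Q1", "REF1", 96.2, 80.0, 78.0),
            ANIRecord("Q2", "REF1", 90.0, 85.0, 85.0),
        ]
        _, log = revise_taxonomy(genomes, ani)
        assert {e.reason for e in log} <= {
            REASON_RECLASSIFIED, REASON_GENUS_RETAINED, REASON_UNRESOLVED
        }


class TestDereplicate:
    @pytest.fixture
    def labelled(self, genomes):
        ani = [
            ANIRecord("Q2", "REF1", 99.5, 95.0, 95.0),
            ANIRecord("Q1", "REF1", 96.0, 80.0, 80.0),
        ]
        labels, _ = revise_taxonomy(genomes, ani)
        return genomes, labels, ani

    def test_near_identical_genome_dropped(self, labelled):
        genomes, labels, ani = labelled
        retained = dereplicate(genomes, labels, ani)
        assert "Q2" not in retained

    def test_below_threshold_retained(self, genomes):
        ani = [ANIRecord("Q2", "REF1", 98.9, 95.0, 95.0)]
        labels, _ = revise_taxonomy(genomes, ani)
        assert "Q2" in dereplicate(genomes, labels, ani)

    def test_reference_always_retained(self, labelled):
        genomes, labels, ani = labelled
        retained = dereplicate(genomes, labels, ani)
        assert {"REF1", "REF2"} <= retained

    def test_no_species_reference_always_retained(self, labelled):
        genomes, labels, ani = labelled
        assert "Q3" in dereplicate(genomes, labels, ani)

    def test_raising_threshold_never_shrinks_retained_set(self, labelled):
        genomes, labels, ani = labelled
        previous = set()
        for threshold in (94.0, 96.0, 99.0, 99.6, 100.0):
            params = CurationParams(derep_threshold=threshold)
            retained = dereplicate(genomes, labels, ani, params)
            assert previous <= retained
            previous = retained


class TestContigFilters:
    def test_viral_floor_is_one_kb_strictly_shorter(self):
        g = genome(
            "V1", "Virus x", "VirusGenus", kingdom="viral",
            contigs=(("a", "A" * 900), ("b", "A" * 1_000)),
        )
        out = filter_contigs_by_length(g)
        assert [cid for cid, _ in out.contigs] == ["b"]

    def test_prokaryotic_floor_five_kb(self):
        g = genome("P1", "Bact", "G", contigs=(("a", "A" * 4_999), ("b", "A" * 5_000)))
        out = filter_contigs_by_length(g)
        assert [cid for cid, _ in out.contigs] == ["b"]
        assert out.total_length == 5_000

    def test_eukaryotic_genome_with_no_survivors_dropped(self):
        g = genome(
            "E1", "Yeast", "G", kingdom="eukaryotic",
            contigs=(("a", "A" * 11_999),),
        )
        assert filter_contigs_by_length(g) is None

    def test_host_contig_removed_on_identity_and_coverage(self):
        g = genome("P1", "Bact", "G", contigs=(("a", "A" * 6_000), ("b", "C" * 6_000)))
        hit = AlignmentHit(
            query_id="a", subject_accession="host", subject_contig="chr1",
            percent_identity=95.0, align_length=4_800, evalue=1e-50, bit_score=1000,
            query_cov=80.0, q_start=1, q_end=4_800, s_start=1, s_end=4_800,
        )
        out = remove_host_contigs(g, [hit])
        assert [cid for cid, _ in out.contigs] == ["b"]

    def test_low_coverage_host_hit_ignored(self):
        g = genome("P1", "Bact", "G", contigs=(("a", "A" * 6_000),))
        hit = AlignmentHit(
            query_id="a", subject_accession="host", subject_contig="chr1",
            percent_identity=95.0, align_length=600, evalue=1e-50, bit_score=100,
            query_cov=10.0, q_start=1, q_end=600, s_start=1, s_end=600,
        )
        assert remove_host_contigs(g, [hit]).contigs == g.contigs

    def test_no_host_hits_leaves_genome_unchanged(self):
        g = genome("P1", "Bact", "G")
        assert remove_host_contigs(g, []).contigs == g.contigs

    def test_unknown_contig_in_host_hit_rejected(self):
        g = genome("P1", "Bact", "G")
        hit = AlignmentHit(
            query_id="ghost", subject_accession="host", subject_contig="chr1",
            percent_identity=95.0, align_length=600, evalue=1e-50, bit_score=100,
            query_cov=90.0, q_start=1, q_end=600, s_start=1, s_end=600,
        )
        with pytest.raises(CurationError, match="ghost"):
            remove_host_contigs(g, [hit])


class TestSizeTable:
    def test_single_genome(self, genomes):
        labels, _ = revise_taxonomy({"REF1": genomes["REF1"]}, [])
        table = build_size_table({"REF1": genomes["REF1"]}, labels)
        assert table == {"Species one": genomes["REF1"].total_length}

    def test_mean_of_two_genomes(self):
        g1 = genome("A", "Sp", "G", contigs=(("c", "A" * 2_000_000),))
        g2 = genome("B", "Sp", "G", contigs=(("c", "A" * 4_000_000),))
        labels, _ = revise_taxonomy({"A": g1, "B": g2}, [])
        table = build_size_table({"A": g1, "B": g2}, labels)
        assert table["Sp"] == 3_000_000

    def test_table_covers_exactly_the_labelled_species(self, genomes):
        labels, _ = revise_taxonomy(genomes, [])
        table = build_size_table(genomes, labels)
        assert set(table) == {lab.species for lab in labels.values()}


class TestCuratePipeline:
    @pytest.fixture
    def curated(self, genomes):
        ani = [
            ANIRecord("Q1", "REF1", 96.2, 80.0, 78.0),
            ANIRecord("Q2", "REF1", 99.5, 95.0, 95.0),
        ]
        return curate(genomes, ani), genomes, ani

    def test_idempotent(self, curated):
        db, genomes, ani = curated
        again = curate(db.genomes, [r for r in ani if r.query in db.genomes], )
        assert set(again.genomes) == set(db.genomes)
        assert again.size_table == db.size_table

    def test_no_retained_contig_violates_floor(self, curated):
        db, _, _ = curated
        params = CurationParams()
        for g in db.genomes.values():
            floor = params.min_contig_length[g.kingdom]
            assert all(len(seq) >= floor for _cid, seq in g.contigs)

    def test_change_log_matches_revision_output(self, curated):
        db, genomes, ani = curated
        _, log = revise_taxonomy(genomes, ani)
        assert len(db.change_log) == len(log)


class TestRoundTrip:
    def test_write_then_read_is_lossless(self, genomes, tmp_path):
        ani = [ANIRecord("Q1", "REF1", 96.2, 80.0, 78.0)]
        db = curate(genomes, ani)
        write_database(db, tmp_path / "db")
        back = read_database(tmp_path / "db")
        assert set(back.genomes) == set(db.genomes)
        for acc in db.genomes:
            assert back.genomes[acc].contigs == db.genomes[acc].contigs
            assert back.labels[acc] == db.labels[acc]
        assert back.size_table == db.size_table
        assert back.change_log == db.change_log

    def test_empty_database_round_trips(self, tmp_path):
        db = curate({}, [])
        write_database(db, tmp_path / "empty")
        back = read_database(tmp_path / "empty")
        assert back.genomes == {} and back.size_table == {}
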
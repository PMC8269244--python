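"""Read QC, host depletion, subsampling, per-read classification and
profile aggregation/normalization."""

import collections

import pytest

from shallowmeta.align import AlignmentHit
from shallowmeta.readprofiler import (
    ClassifierParams,
    ProfilerError,
    Read,
    ReadClassification,
    SubjectLabel,
    UNDEFINED_SPECIES,
    aggregate_profile,
    classify_read,
    deplete_host,
    mean_phred,
    normalize_by_genome_size,
    quality_filter,
    quality_filter_pairs,
    subsample,
)


def q(chars: float, n: int) -> str:
    return chr(int(chars) + 33) * n


def read(rid="r", length=150, phred=30):
    return Read(rid, "A" * length, q(phred, length))


def hit(accession, identity, bits=200.0, **kw):
    base = dict(
        query_id="r", subject_accession=accession, subject_contig=accession,
        percent_identity=identity, align_length=150, evalue=1e-30, bit_score=bits,
        query_cov=100.0, q_start=1, q_end=150, s_start=1, s_end=150,
    )
    base.update(kw)
    return AlignmentHit(**base)


LABELS = {
    "L_A": SubjectLabel("Lactobacillus", "Lactobacillus A", "31", "prokaryotic"),
    "L_B": SubjectLabel("Lactobacillus", "Lactobacillus B", "32", "prokaryotic"),
    "B_C": SubjectLabel("Bifidobacterium", "Bifidobacterium C", "41", "prokaryotic"),
    "V_X": SubjectLabel("Siphovirus", "Phage X", "51", "viral"),
    "V_Y": SubjectLabel("Siphovirus", "Phage Y", "52", "viral"),
}


class TestQualityFilter:
    def test_good_read_retained(self):
        kept, stats = quality_filter([read()])
        assert len(kept) == 1 and stats["retained"] == 1

    def test_149_bp_read_removed(self):
        kept, stats = quality_filter([read(length=149)])
        assert kept == [] and stats["removed_length"] == 1

    def test_mean_quality_just_below_cutoff_removed(self):
        # 150 bases: 149 at Q25 and one at Q10 pulls the mean to 24.9
        qual = q(25, 149) + q(10, 1)
        assert mean_phred(qual) < 25
        kept, stats = quality_filter([Read("r", "A" * 150, qual)])
        assert kept == [] and stats["removed_quality"] == 1

    def test_length_quality_mismatch_rejected(self):
        with pytest.raises(ProfilerError, match="mismatch"):
            quality_filter([Read("r", "ACGT", "II")])

    def test_paired_mode_drops_both_mates(self):
        r1 = [read("a/1"), read("b/1", length=149)]
        r2 = [read("a/2"), read("b/2")]
        k1, k2, stats = quality_filter_pairs(r1, r2)
        assert [r.id for r in k1] == ["a/1"]
        assert [r.id for r in k2] == ["a/2"]
        assert stats["removed_pairs"] == 1


class TestDepleteHost:
    def test_confident_host_hit_removes_read(self):
        hits = {"r": [hit("host", 99.0)]}
        assert deplete_host([read()], hits) == []

    def test_low_coverage_host_hit_keeps_read(self):
        hits = {"r": [hit("host", 99.0, query_cov=50.0)]}
        assert len(deplete_host([read()], hits)) == 1

    def test_no_host_configured_is_identity(self):
        reads = [read("a"), read("b")]
        assert deplete_host(reads, None) == reads


class TestSubsample:
    def test_requesting_more_than_available_returns_all(self):
        reads = [read(f"r{i}") for i in range(50)]
        assert len(subsample(reads, n=100, seed=1)) == 50

    def test_fixed_seed_is_reproducible(self):
        reads = [read(f"r{i}") for i in range(1_000)]
        a = subsample(reads, n=100, seed=7)
        b = subsample(reads, n=100, seed=7)
        assert a == b
        assert subsample(reads, n=100, seed=8) != a

    def test_pairs_travel_together(self):
        r1 = [read(f"r{i}/1") for i in range(100)]
        r2 = [read(f"r{i}/2") for i in range(100)]
        s1, s2 = subsample(r1, n=10, seed=3, mates=r2)
        assert [x.id.split("/")[0] for x in s1] == [x.id.split("/")[0] for x in s2]

    def test_inclusion_frequency_is_uniform(self):
        reads = [read(f"r{i}") for i in range(10)]
        counts = collections.Counter()
        for seed in range(1_000):
            for r in subsample(reads, n=5, seed=seed):
                counts[r.id] += 1
        # each read should appear in about half the resamples
        for rid in counts:
            assert 0.42 <= counts[rid] / 1_000 <= 0.58


class TestClassifyRead:
    def test_single_best_hit_above_species_cutoff(self, small_tree):
        c = classify_read([hit("L_A", 96.0)], small_tree, LABELS)
        assert (c.species_label, c.assigned_rank, c.method) == (
            "Lactobacillus A", "species", "best_hit"
        )

    def test_equal_hits_to_congeneric_species_resolve_by_lca(self, small_tree):
        c = classify_read([hit("L_A", 97.0), hit("L_B", 97.0)], small_tree, LABELS)
        assert c.assigned_rank == "genus" and c.method == "lca"
        assert c.taxid == "30" and c.species_label == UNDEFINED_SPECIES

    def test_equal_hits_across_genera_resolve_above_genus(self, small_tree):
        c = classify_read([hit("L_A", 97.0), hit("B_C", 97.0)], small_tree, LABELS)
        assert c.assigned_rank == "higher" and c.method == "lca"
        assert c.taxid == "20"

    def test_intermediate_identity_is_genus_level_undefined_species(self, small_tree):
        c = classify_read([hit("L_A", 60.0)], small_tree, LABELS)
        assert c.assigned_rank == "genus"
        assert c.species_label == UNDEFINED_SPECIES
        assert c.genus_label == "Lactobacillus"
        assert c.taxid == "30"

    def test_identity_exactly_at_species_cutoff_is_genus_level(self, small_tree):
        c = classify_read([hit("L_A", 94.0)], small_tree, LABELS)
        assert c.assigned_rank == "genus"

    def test_below_genus_cutoff_unclassified(self, small_tree):
        c = classify_read([hit("L_A", 15.0)], small_tree, LABELS)
        assert c.assigned_rank == "unclassified" and c.taxid is None

    def test_viral_ties_use_best_bit_score_not_lca(self, small_tree):
        hits = [hit("V_X", 98.0, bits=180.0), hit("V_Y", 98.0, bits=220.0)]
        c = classify_read(hits, small_tree, LABELS)
        assert c.method == "viral_best_hit"
        assert c.species_label == "Phage Y"

    def test_viral_ties_fall_back_to_lca_when_enabled(self, small_tree):
        hits = [hit("V_X", 98.0), hit("V_Y", 98.0)]
        params = ClassifierParams(viral_lca_disabled=False)
        c = classify_read(hits, small_tree, LABELS, params)
        assert c.method == "lca" and c.taxid == "50"

    def test_no_hits_unclassified(self, small_tree):
        c = classify_read([], small_tree, LABELS, read_id="r9")
        assert c.assigned_rank == "unclassified" and c.read_id == "r9"

    def test_unknown_accession_rejected(self, small_tree):
        with pytest.raises(ProfilerError, match="GHOST"):
            classify_read([hit("GHOST", 96.0)], small_tree, LABELS)

    def test_hit_order_invariance(self, small_tree):
        hits = [hit("L_A", 97.0), hit("L_B", 97.0), hit("B_C", 95.0)]
        a = classify_read(hits, small_tree, LABELS)
        b = classify_read(list(reversed(hits)), small_tree, LABELS)
        assert a == b

    def test_tie_epsilon_widens_the_best_hit_set(self, small_tree):
        hits = [hit("L_A", 97.0), hit("L_B", 96.5)]
        strict = classify_read(hits, small_tree, LABELS)
        loose = classify_read(
            hits, small_tree, LABELS, ClassifierParams(identity_tie_epsilon=1.0)
        )
        assert strict.assigned_rank == "species"
        assert loose.assigned_rank == "genus" and loose.method == "lca"

    def test_raising_species_cutoff_never_adds_species_calls(self, small_tree):
        hit_sets = [
            [hit("L_A", identity)] for identity in (90.5, 92.0, 93.5, 95.0, 96.5, 98.0)
        ]
        counts = []
        for cutoff in range(90, 99):
            params = ClassifierParams(species_min_identity=float(cutoff))
            n = sum(
                classify_read(hs, small_tree, LABELS, params).assigned_rank == "species"
                for hs in hit_sets
            )
            counts.append(n)
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def classification(species, rank="species", taxid="31", genus="Lactobacillus"):
    return ReadClassification(
        read_id=f"{species}:{rank}", taxid=taxid, assigned_rank=rank,
        method="best_hit", best_identity=97.0, species_label=species,
        genus_label=genus, taxon_name=species,
    )


class TestAggregateProfile:
    def test_relative_abundance(self):
        cls = [classification("S1")] * 80 + [classification("S2", taxid="32")] * 20
        profile = aggregate_profile(cls)
        assert profile.relative == {"S1": 80.0, "S2": 20.0}

    def test_all_unclassified(self):
        cls = [
            ReadClassification(f"r{i}", None, "unclassified", "none", 0.0, None)
            for i in range(5)
        ]
        profile = aggregate_profile(cls)
        assert profile.counts == {} and profile.unclassified_count == 5

    def test_genus_rollup_conserves_species_counts(self, small_tree):
        cls = (
            [classification("Lactobacillus A", taxid="31")] * 3
            + [classification("Lactobacillus B", taxid="32")] * 2
            + [classification("Bifidobacterium C", taxid="41", genus="Bifidobacterium")] * 4
        )
        profile = aggregate_profile(cls, small_tree)
        genus = profile.rank_tables["genus"]
        assert genus == {"Lactobacillus": 5, "Bifidobacterium": 4}

    def test_undefined_species_binned_per_genus(self):
        cls = [
            ReadClassification("r1", "30", "genus", "best_hit", 60.0,
                               UNDEFINED_SPECIES, "Lactobacillus", "Lactobacillus"),
            ReadClassification("r2", "40", "genus", "best_hit", 55.0,
                               UNDEFINED_SPECIES, "Bifidobacterium", "Bifidobacterium"),
        ]
        profile = aggregate_profile(cls)
        assert set(profile.counts) == {
            f"Lactobacillus {UNDEFINED_SPECIES}",
            f"Bifidobacterium {UNDEFINED_SPECIES}",
        }

    def test_relative_sums_to_100(self):
        cls = [classification(f"S{i}", taxid="31") for i in range(7) for _ in range(i + 1)]
        profile = aggregate_profile(cls)
        assert sum(profile.relative.values()) == pytest.approx(100.0, abs=1e-9)


class TestNormalize:
    def test_closed_form_two_species(self):
        profile = aggregate_profile(
            [classification("A")] * 100 + [classification("B", taxid="32")] * 100
        )
        normalize_by_genome_size(profile, {"A": 2_000_000, "B": 4_000_000})
        assert profile.normalized["A"] == pytest.approx(200 / 3, abs=1e-9)
        assert profile.normalized["B"] == pytest.approx(100 / 3, abs=1e-9)

    def test_equal_sizes_leave_relative_unchanged(self):
        profile = aggregate_profile(
            [classification("A")] * 30 + [classification("B", taxid="32")] * 70
        )
        normalize_by_genome_size(profile, {"A": 3_000_000, "B": 3_000_000})
        assert profile.normalized == pytest.approx(profile.relative)

    def test_single_species_is_100(self):
        profile = aggregate_profile([classification("A")] * 10)
        normalize_by_genome_size(profile, {"A": 1_000_000})
        assert profile.normalized == {"A": 100.0}

    def test_normalized_sums_to_100(self):
        profile = aggregate_profile(
            [classification("A")] * 13 + [classification("B", taxid="32")] * 29
        )
        normalize_by_genome_size(profile, {"A": 1_500_000, "B": 6_200_000})
        assert sum(profile.normalized.values()) == pytest.approx(100.0, abs=1e-9)

    def test_non_positive_size_rejected(self):
        profile = aggregate_profile([classification("A")])
        with pytest.raises(ProfilerError, match="non-positive"):
            normalize_by_genome_size(profile, {"A": 0})

    def test_missing_species_fall_back_to_mean_size_with_warning(self):
        profile = aggregate_profile(
            [classification("A")] * 10 + [classification("Novel", taxid="32")] * 10
        )
        with pytest.warns(UserWarning, match="missing from size table"):
            normalize_by_genome_size(profile, {"A": 2_000_000, "B": 2_000_000})
        assert sum(profile.normalized.values()) == pytest.approx(100.0)
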
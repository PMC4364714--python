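"""Generator contracts: reproducibility, length arithmetic, coverage
identities and distributional calibration of the synthetic inputs."""

import numpy as np
import pytest
from scipy import stats

from gutcrest import synthio


class TestMakeReference:
    def test_length_and_alphabet(self):
        ref = synthio.make_reference(100, 0.5, seed=7)
        assert ref.length == 100
        assert set(ref.sequence) <= set("ACGT")

    def test_degenerate_gc(self):
        ref = synthio.make_reference(1000, 0.0, seed=1)
        assert set(ref.sequence) <= set("AT")

    def test_deterministic(self):
        a = synthio.make_reference(5000, 0.42, seed=3)
        b = synthio.make_reference(5000, 0.42, seed=3)
        assert a.sequence == b.sequence

    def test_gc_fraction_realised(self):
        ref = synthio.make_reference(100_000, 0.42, seed=5)
        gc = sum(ref.sequence.count(b) for b in "GC") / ref.length
        assert abs(gc - 0.42) < 0.02

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            synthio.make_reference(0)


class TestBuildInsertionAllele:
    def test_reference_scale_length_arithmetic(self):
        # 2 Mb host + 26 kb duplication + 700 kb concatemer
        ref = synthio.make_reference(2_000_000, seed=2)
        units = synthio.default_transgene_units(7000, seed=2)
        allele = synthio.build_insertion_allele(
            ref, 1_000_000, units, [50, 50], dup_length=26_000
        )
        assert len(allele.sequence) == 2_726_000
        assert allele.truth.array_length == 700_000
        assert allele.truth.unit_copies == {"Tyr-minigene": 50, "SRYp-YFP": 50}

    def test_zero_duplication_single_unit(self):
        ref = synthio.make_reference(10_000, seed=4)
        unit = synthio.make_transgene_unit("U", 1500, seed=4)
        allele = synthio.build_insertion_allele(ref, 5_000, [unit], [1], 0)
        assert len(allele.sequence) == ref.length + unit.length

    def test_duplicated_flank_appears_twice(self):
        ref = synthio.make_reference(10_000, seed=4)
        unit = synthio.make_transgene_unit("U", 1000, seed=4)
        allele = synthio.build_insertion_allele(ref, 5_000, [unit], [2], 500)
        dup = ref.sequence[5_000:5_500]
        t = allele.truth
        left = allele.sequence[5_000:5_500]
        right = allele.sequence[5_500 + t.array_length : 6_000 + t.array_length]
        assert left == dup and right == dup

    def test_zero_copies_rejected(self):
        ref = synthio.make_reference(10_000, seed=4)
        unit = synthio.make_transgene_unit("U", 1000, seed=4)
        with pytest.raises(ValueError):
            synthio.build_insertion_allele(ref, 5_000, [unit], [0], 100)

    def test_site_out_of_range_rejected(self):
        ref = synthio.make_reference(10_000, seed=4)
        unit = synthio.make_transgene_unit("U", 1000, seed=4)
        with pytest.raises(ValueError):
            synthio.build_insertion_allele(ref, 9_950, [unit], [1], 100)


class TestSimulatePairedReads:
    def test_pair_count_coverage_identity(self):
        ref = synthio.make_reference(1_000_000, seed=6)
        sim = synthio.simulate_paired_reads([ref], coverage=30.0, read_len=100, seed=7)
        expected = 30.0 * 1_000_000 / (4 * 100)
        assert abs(len(sim.fragments) - expected) / expected < 0.01

    def test_reads_are_substrings_without_errors(self, small_insertion):
        sim = small_insertion["sim"]
        table = synthio.read_sequences(sim).head(200)
        allele_seq = small_insertion["allele"].sequence
        comp = str.maketrans("ACGT", "TGCA")
        for row in table.itertuples():
            assert row.seq1 in allele_seq
            assert row.seq2.translate(comp)[::-1] in allele_seq

    def test_chimeric_fraction_matches_fragment_oracle(self, small_insertion):
        from gutcrest.insertion_mapper import collect_chimeric_pairs

        sim = small_insertion["sim"]
        truth = small_insertion["allele"].truth
        # clean-straddle fragments (junction >= one read length inside both
        # ends) are exactly the ones whose reads map to opposite sides
        oracle = int(
            sim.junction_spanning_fragments(truth, margin=sim.read_len).sum()
        )
        chimeric = collect_chimeric_pairs(
            sim.alignments, "host", list(small_insertion["unit_lengths"])
        )
        assert oracle > 0
        assert abs(len(chimeric) - oracle) / oracle < 0.30

    def test_junction_fragments_always_non_proper(self, small_insertion):
        sim = small_insertion["sim"]
        truth = small_insertion["allele"].truth
        spanning = set(
            sim.fragments.loc[sim.junction_spanning_fragments(truth), "read"]
        )
        aln = sim.alignments[sim.alignments["mate_index"] == 1]
        proper_reads = set(aln.loc[aln["proper"], "read"])
        assert not (spanning & proper_reads)

    def test_deterministic_given_seed(self):
        ref = synthio.make_reference(50_000, seed=8)
        a = synthio.simulate_paired_reads([ref], 5.0, seed=9)
        b = synthio.simulate_paired_reads([ref], 5.0, seed=9)
        assert a.fragments.equals(b.fragments)

    def test_bad_parameters_rejected(self):
        ref = synthio.make_reference(10_000, seed=1)
        with pytest.raises(ValueError):
            synthio.simulate_paired_reads([ref], 0.0)
        with pytest.raises(ValueError):
            synthio.simulate_paired_reads([ref], 5.0, insert_mean=150.0)


class TestSimulateCohort:
    def test_penetrance_matches_gaussian_tail(self):
        # male mean one sd-fifth below threshold -> Phi(1/5) penetrance
        cohort = synthio.simulate_cohort(
            20_000, 0, mu_male=79, sigma=5, threshold=80, seed=10
        )
        expected = stats.norm.cdf((80 - 79) / 5)
        observed = cohort.animals["megacolon"].mean()
        assert abs(observed - expected) < 0.01

    def test_tight_female_distribution_has_zero_penetrance(self):
        cohort = synthio.simulate_cohort(
            0, 500, mu_female=95, sigma=0.001, threshold=80, seed=1
        )
        assert cohort.animals["megacolon"].sum() == 0

    def test_single_sex_cohort(self):
        cohort = synthio.simulate_cohort(0, 10, seed=1)
        assert (cohort.animals["sex"] == "F").all()

    def test_fraction_bounds_and_determinism(self):
        a = synthio.simulate_cohort(50, 50, sigma=30, seed=2)
        assert a.animals["ganglionic_fraction"].between(0, 100).all()
        b = synthio.simulate_cohort(50, 50, sigma=30, seed=2)
        assert a.animals.equals(b.animals)

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError):
            synthio.simulate_cohort(-1, 10)


class TestSimulateTracks:
    def test_stationary_when_speed_zero(self):
        tracks = synthio.simulate_tracks(3, speed_mu=0, speed_sd=0, seed=1)
        for t in tracks:
            assert np.allclose(t.positions, t.positions[0])

    def test_high_concentration_headings_follow_reference(self):
        tracks = synthio.simulate_tracks(
            5, speed_mu=1.0, speed_sd=0.0, kappa=1e7, reference_angle=0.7, seed=2
        )
        for t in tracks:
            d = np.diff(t.positions, axis=0)
            headings = np.arctan2(d[:, 1], d[:, 0])
            assert np.allclose(headings, 0.7, atol=1e-2)

    def test_mean_speed_recovered(self):
        from gutcrest.migration_stats import track_speed

        tracks = synthio.simulate_tracks(200, speed_mu=0.58, speed_sd=0.1, seed=3)
        mean_speed = np.mean([track_speed(t) for t in tracks])
        assert abs(mean_speed - 0.58) / 0.58 < 0.05

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            synthio.simulate_tracks(1, kappa=-1)


class TestSimulateCounts:
    def test_poisson_limit_at_zero_dispersion(self):
        cm = synthio.simulate_counts(
            2000, dispersion=0.0, base_mean=100, base_sigma=0.0, seed=4
        )
        c = cm.counts.to_numpy(float)
        ratio = c.var(axis=1, ddof=1).mean() / c.mean()
        assert 0.9 < ratio < 1.1

    def test_nb_mean_variance_relation(self):
        phi = 0.2
        cm = synthio.simulate_counts(
            4000, dispersion=phi, base_mean=200, base_sigma=0.0, seed=5
        )
        c = cm.counts.to_numpy(float)
        m = c.mean()
        v = c.var(axis=1, ddof=1).mean()
        expected = m + phi * m**2
        assert abs(v - expected) / expected < 0.1

    def test_truth_recorded_and_reciprocal_rule(self):
        cm = synthio.simulate_counts(
            100, de_spec={"gene0000": 5.0, "gene0001": 0.2}, seed=6
        )
        assert cm.true_fold["gene0000"] == 5.0
        assert cm.true_fold["gene0002"] == 1.0
        with pytest.raises(ValueError):
            synthio.simulate_counts(10, de_spec={"gene0000": -2.0})


class TestWriters:
    def test_sam_round_trip(self, tmp_path, small_insertion):
        import pysam

        from gutcrest.insertion_mapper import load_alignments_sam

        sim = small_insertion["sim"]
        # subsample for speed: keep the first 500 fragments
        keep = sim.fragments.head(500)
        sub = synthio.ReadSimulation(
            alignments=sim.alignments[sim.alignments["read"].isin(keep["read"])],
            fragments=keep,
            contig_lengths=sim.contig_lengths,
            read_len=sim.read_len,
            insert_mean=sim.insert_mean,
            insert_sd=sim.insert_sd,
            alleles=sim.alleles,
        )
        path = tmp_path / "truth.sam"
        synthio.write_sam(sub, path)
        with pysam.AlignmentFile(str(path)) as f:
            n = sum(1 for _ in f)
        assert n == 1000
        aln, lengths = load_alignments_sam(path)
        assert lengths["host"] == 300_000
        assert (aln["mapped"].sum()) == sub.alignments["mapped"].sum()

    def test_fastq_and_fasta_written(self, tmp_path):
        ref = synthio.make_reference(5_000, seed=1)
        sim = synthio.simulate_paired_reads([ref], 2.0, seed=2)
        synthio.write_fasta([ref], tmp_path / "ref.fasta")
        synthio.write_fastq(sim, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        r1 = (tmp_path / "r1.fastq").read_text().splitlines()
        assert len(r1) == 4 * len(sim.fragments)
        assert (tmp_path / "ref.fasta").read_text().startswith(">host")
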
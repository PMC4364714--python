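"""Insertion-architecture inference: depth profiles, duplication calls,
chimeric-pair collection, junction clustering and copy-number arithmetic."""

import numpy as np
import pandas as pd
import pytest

from gutcrest import synthio
from gutcrest.insertion_mapper import (
    DepthProfile,
    DuplicationCall,
    InsertionMapper,
    call_junctions,
    collect_chimeric_pairs,
    compute_depth,
    detect_duplication,
    estimate_copies_and_size,
    genotype_from_band_ratio,
)


def profile_from_norm(norm, window=1000, baseline=300.0, contig="host"):
    return DepthProfile(
        window=window, raw={contig: np.asarray(norm, float) * baseline}, baseline=baseline
    )


class TestComputeDepth:
    def test_counts_conserved_and_uniform_windows(self):
        ref = synthio.make_reference(200_000, seed=21)
        sim = synthio.simulate_paired_reads([ref, ref], coverage=30.0, seed=22)
        profile = compute_depth(
            sim.alignments, window=1000, contig_lengths=sim.contig_lengths
        )
        assert profile.total_reads() == int(sim.alignments["mapped"].sum())
        norm = profile.normalized["host"][:-1]  # last window is partial
        # Poisson window bounds: ~300 read starts per 1 kb window at 30x,
        # so nearly every window sits in [0.8, 1.2] and none strays far
        inside = ((norm >= 0.8) & (norm <= 1.2)).mean()
        assert inside >= 0.99
        assert (norm >= 0.7).all() and (norm <= 1.3).all()

    def test_homozygous_duplication_doubles_depth(self, small_insertion):
        sim = small_insertion["sim"]
        truth = small_insertion["allele"].truth
        profile = compute_depth(
            sim.alignments,
            window=1000,
            host_contigs=["host"],
            contig_lengths=sim.contig_lengths,
        )
        w0 = truth.host_site // 1000
        w1 = truth.left_junction // 1000
        inside = profile.normalized["host"][w0:w1]
        assert abs(inside.mean() - 2.0) < 0.15

    def test_contig_without_reads_yields_zero_windows(self):
        ref = synthio.make_reference(50_000, seed=23)
        sim = synthio.simulate_paired_reads([ref], coverage=10.0, seed=24)
        lengths = dict(sim.contig_lengths, empty_contig=10_000)
        profile = compute_depth(sim.alignments, 1000, contig_lengths=lengths)
        assert (profile.raw["empty_contig"] == 0).all()

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            compute_depth(pd.DataFrame(columns=synthio.ALIGNMENT_COLUMNS), 1000)


class TestDetectDuplication:
    def test_flat_profile_no_call(self):
        profile = profile_from_norm(np.ones(100))
        assert detect_duplication(profile) == []

    def test_26_window_step_called_at_26kb(self):
        norm = np.ones(100)
        norm[40:66] = 2.0
        calls = detect_duplication(profile_from_norm(norm))
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end) == (40_000, 66_000)
        assert call.length == 26_000
        assert call.zygosity == "hom"

    def test_het_step_ratio(self):
        # one extra copy over two alleles -> 1.5x over 30 kb
        norm = np.ones(100)
        norm[10:40] = 1.5
        calls = detect_duplication(profile_from_norm(norm))
        assert len(calls) == 1
        assert calls[0].zygosity == "het"
        assert calls[0].length == 30_000

    def test_short_runs_ignored(self):
        norm = np.ones(100)
        norm[50:55] = 2.0  # 5 kb < 10 kb minimum
        assert detect_duplication(profile_from_norm(norm)) == []


class TestChimericPairs:
    def test_equals_brute_force_filter(self, small_insertion):
        sim = small_insertion["sim"]
        tg = list(small_insertion["unit_lengths"])
        pairs = collect_chimeric_pairs(sim.alignments, "host", tg)
        a = sim.alignments
        brute = a[
            a["mapped"].astype(bool)
            & a["mate_mapped"].astype(bool)
            & ~a["proper"].astype(bool)
            & (a["contig"] == "host")
            & a["mate_contig"].isin(set(tg))
        ]
        assert len(pairs) == len(brute)
        assert {p.read for p in pairs} == set(brute["read"])

    def test_concordant_pairs_excluded(self):
        ref = synthio.make_reference(50_000, seed=31)
        sim = synthio.simulate_paired_reads([ref], coverage=10.0, seed=32)
        assert collect_chimeric_pairs(sim.alignments, "host", ["Tyr-minigene"]) == []


class TestCallJunctions:
    def test_no_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="insufficient junction evidence"):
            call_junctions([])

    def test_breakpoints_near_truth(self, small_insertion):
        sim = small_insertion["sim"]
        truth = small_insertion["allele"].truth
        pairs = collect_chimeric_pairs(
            sim.alignments, "host", list(small_insertion["unit_lengths"])
        )
        lj, rj = call_junctions(pairs, insert_mean=400, insert_sd=35)
        assert abs(lj.breakpoint - truth.left_junction) <= 400
        assert abs(rj.breakpoint - truth.right_junction) <= 400
        assert lj.support + rj.support == len(pairs)

    def test_support_equals_cluster_sizes(self, small_insertion):
        sim = small_insertion["sim"]
        pairs = collect_chimeric_pairs(
            sim.alignments, "host", list(small_insertion["unit_lengths"])
        )
        lj, rj = call_junctions(pairs)
        assert lj.support == sum(1 for p in pairs if p.host_strand == "+")
        assert rj.support == sum(1 for p in pairs if p.host_strand == "-")


class TestCopiesAndSize:
    def test_zero_transgene_depth_zero_size(self):
        profile = DepthProfile(
            window=1000,
            raw={"host": np.full(50, 300.0), "U": np.zeros(7)},
            baseline=300.0,
        )
        report = estimate_copies_and_size(profile, "hom", {"U": 7000})
        assert report.unit_copies == {"U": 0.0}
        assert report.total_size == 0

    def test_hom_depth50_gives_50_copies(self):
        profile = DepthProfile(
            window=1000,
            raw={"host": np.full(50, 300.0), "U": np.full(7, 300.0 * 50)},
            baseline=300.0,
        )
        report = estimate_copies_and_size(profile, "hom", {"U": 7000})
        assert report.unit_copies["U"] == pytest.approx(50.0)
        assert report.total_size == 350_000

    def test_het_doubles_per_allele_copies(self):
        profile = DepthProfile(
            window=1000,
            raw={"host": np.full(50, 300.0), "U": np.full(7, 300.0 * 5)},
            baseline=300.0,
        )
        report = estimate_copies_and_size(profile, "het", {"U": 7000})
        assert report.unit_copies["U"] == pytest.approx(10.0)

    def test_unknown_zygosity_requires_duplication(self):
        profile = profile_from_norm(np.ones(10))
        with pytest.raises(ValueError, match="zygosity"):
            estimate_copies_and_size(profile, "unknown", {"U": 7000})


class TestGenotypeBandRatio:
    @pytest.mark.parametrize(
        "tg,chrom,cal,expected",
        [(0.5, 1.0, 0.5, 1), (1.0, 1.0, 0.5, 2), (0.0, 1.0, 0.5, 0)],
    )
    def test_allele_counts(self, tg, chrom, cal, expected):
        assert genotype_from_band_ratio(tg, chrom, cal) == expected

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            genotype_from_band_ratio(-1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            genotype_from_band_ratio(1.0, 0.0, 0.5)


class TestEndToEnd:
    def test_full_recovery_small_scale(self, small_insertion):
        sim = small_insertion["sim"]
        truth = small_insertion["allele"].truth
        mapper = InsertionMapper().fit(
            sim.alignments,
            host_contig="host",
            transgene_contigs=list(small_insertion["unit_lengths"]),
            unit_lengths=small_insertion["unit_lengths"],
            contig_lengths=sim.contig_lengths,
        )
        dup = mapper.duplications_[0]
        assert abs(dup.length - truth.dup_length) <= 1000
        assert dup.zygosity == "hom"
        lj, rj = mapper.junctions_
        assert abs(lj.breakpoint - truth.left_junction) <= 400
        assert abs(rj.breakpoint - truth.right_junction) <= 400
        expected_size = truth.array_length
        assert abs(mapper.report_.total_size_raw - expected_size) / expected_size < 0.1

    def test_depth_sum_equals_reads(self, small_insertion):
        sim = small_insertion["sim"]
        profile = compute_depth(
            sim.alignments, 1000, contig_lengths=sim.contig_lengths
        )
        assert profile.total_reads() == int(sim.alignments["mapped"].sum())

    def test_more_coverage_does_not_worsen_breakpoints(self):
        """Mean absolute breakpoint error (over seeds) does not grow with
        coverage."""
        ref = synthio.make_reference(150_000, seed=41)
        units = synthio.default_transgene_units(2000, seed=41)
        allele = synthio.build_insertion_allele(ref, 70_000, units, [3, 3], 12_000)
        truth = allele.truth

        def mean_error(coverage):
            errs = []
            for seed in range(5):
                sim = synthio.simulate_paired_reads(
                    [allele, allele], coverage, seed=100 + seed
                )
                pairs = collect_chimeric_pairs(
                    sim.alignments, "host", [u.name for u in units]
                )
                lj, rj = call_junctions(pairs)
                errs.append(abs(lj.breakpoint - truth.left_junction))
                errs.append(abs(rj.breakpoint - truth.right_junction))
            return np.mean(errs)

        assert mean_error(40.0) <= mean_error(10.0) + 20.0
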
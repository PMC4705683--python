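"""Synthetic genome, translocation, read simulation and alignment emulation."""

import numpy as np
import pysam
import pytest

from silicosv.refmodel import reverse_complement
from silicosv.simdata import (
    SimulationConfig,
    SimulationError,
    TranslocationSpec,
    apply_translocation,
    candidate_mask,
    emulate_primary_alignment,
    identity_sample,
    make_genome,
    random_translocation,
    simulate_read_pairs,
)


def small_cfg(**kw):
    defaults = dict(
        n_chromosomes=2, chrom_length=100_000, bands_per_chrom=5,
        coverage=10.0, junction_margin=2_000, seed=11,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestGenome:
    def test_structure_and_band_partition(self):
        cfg = small_cfg()
        genome, table = make_genome(cfg)
        assert set(genome) == {"1", "2"}
        assert len(table) == 10
        for chrom in ("1", "2"):
            bands = [b for b in table if b.chrom == chrom]
            assert bands[0].start == 1 and bands[-1].end == 100_000
            covered = sum(b.length for b in bands)
            assert covered == 100_000

    def test_same_seed_byte_identical(self):
        g1, _ = make_genome(small_cfg())
        g2, _ = make_genome(small_cfg())
        assert g1 == g2
        g3, _ = make_genome(small_cfg(seed=12))
        assert g1 != g3

    def test_gc_content_near_half_for_uniform_model(self):
        cfg = small_cfg(n_chromosomes=1, chrom_length=1_000_000, bands_per_chrom=2)
        genome, _ = make_genome(cfg)
        seq = genome["1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.02)


class TestTranslocation:
    def test_derivative_length_arithmetic(self):
        cfg = SimulationConfig(n_chromosomes=2, chrom_length=1_000_000, bands_per_chrom=4,
                               junction_margin=10_000, seed=3)
        genome, table = make_genome(cfg)
        spec = TranslocationSpec("1", 400_000, "2", 600_000,
                                 band_a="1p11", band_b="2q11")
        sample = apply_translocation(genome, table, spec)
        assert len(sample.chroms["der1"]) == 800_001
        assert len(sample.chroms["der2"]) == 1_199_999
        assert sample.total_length() == 2_000_000  # reciprocal event conserves content

    def test_sequence_left_of_junction_is_chrom_a_prefix(self):
        genome, table = make_genome(small_cfg())
        spec = TranslocationSpec("1", 30_000, "2", 50_000, "1q11", "2q12")
        sample = apply_translocation(genome, table, spec)
        assert sample.chroms["der1"][:30_000] == genome["1"][:30_000]
        assert sample.chroms["der1"][30_000:] == genome["2"][49_999:]

    def test_boundary_junction_rejected(self):
        genome, table = make_genome(small_cfg())
        band = table["1q11"]
        spec = TranslocationSpec("1", band.end, "2", 50_000, "1q11", "2q12")
        with pytest.raises(SimulationError, match="boundary"):
            apply_translocation(genome, table, spec)

    def test_intra_chromosomal_rejected(self):
        genome, table = make_genome(small_cfg())
        with pytest.raises(SimulationError):
            apply_translocation(
                genome, table, TranslocationSpec("1", 30_000, "1", 50_000, "1q11", "1q12")
            )

    def test_random_junctions_respect_margin(self):
        cfg = small_cfg()
        genome, table = make_genome(cfg)
        for seed in range(10):
            spec = random_translocation(genome, table, cfg, np.random.default_rng(seed))
            for chrom, pos, label in ((spec.chrom_a, spec.pos_a, spec.band_a),
                                      (spec.chrom_b, spec.pos_b, spec.band_b)):
                band = table[label]
                assert band.start + cfg.junction_margin <= pos <= band.end - cfg.junction_margin

    def test_lift_round_trip(self):
        genome, table = make_genome(small_cfg())
        spec = TranslocationSpec("1", 30_000, "2", 50_000, "1q11", "2q12")
        sample = apply_translocation(genome, table, spec)
        for chrom in ("der1", "der2"):
            for pos0 in (0, 10_000, len(sample.chroms[chrom]) - 1):
                src, src0 = sample.lift(chrom, pos0)
                assert sample.chroms[chrom][pos0] == genome[src][src0]


def simulate_small(**kw):
    cfg = small_cfg(**kw)
    genome, table = make_genome(cfg)
    spec = TranslocationSpec("1", 30_000, "2", 50_000, "1q11", "2q12")
    sample = apply_translocation(genome, table, spec)
    return cfg, sample, simulate_read_pairs(sample, cfg)


class TestReads:
    def test_expected_pair_count(self):
        cfg, sample, rs = simulate_small()
        expect = cfg.coverage * sample.total_length() / (2 * cfg.read_length)
        assert len(rs) == pytest.approx(expect, rel=0.01)

    def test_error_free_reads_are_exact_substrings(self):
        cfg, sample, rs = simulate_small(error_rate=1e-9, quality_jitter_sd=0.0)
        normal = np.flatnonzero((rs.klass == 0) & ~rs.truth["spans_junction"].to_numpy())[:40]
        reads = rs.materialize(normal)
        donor = rs.sample.chroms
        names = rs.donor_chroms
        for (rid, s1, q1, s2, q2), i in zip(reads, normal):
            chrom = donor[names[rs.m_chrom[i, 0]]]
            assert s1 == chrom[rs.m_start[i, 0] : rs.m_start[i, 0] + 100]
            assert reverse_complement(s2) == chrom[rs.m_start[i, 1] : rs.m_start[i, 1] + 100]

    def test_insert_moments_match_config(self):
        cfg, _, rs = simulate_small()
        normal = rs.klass == 0
        flens = rs.frag_len[normal]
        se = cfg.insert_sd / np.sqrt(len(flens))
        assert abs(flens.mean() - cfg.insert_mean) < 3 * se + 0.5  # +0.5 for rounding
        assert np.std(flens) == pytest.approx(cfg.insert_sd, rel=0.05)

    def test_spanning_flags_match_coordinate_oracle(self):
        cfg, sample, rs = simulate_small()
        boundaries = {c: sample.boundaries(c) for c in rs.donor_chroms}
        normal = np.flatnonzero(rs.klass == 0)
        flags = rs.truth["spans_junction"].to_numpy()
        for i in normal[:2000]:
            cname = rs.donor_chroms[rs.m_chrom[i, 0]]
            s, L = rs.m_start[i, 0], rs.frag_len[i]
            expect = any(s <= b < s + L - 1 for b in boundaries[cname])
            assert flags[i] == expect

    def test_spanning_frequency_matches_analytic_expectation(self):
        cfg, sample, rs = simulate_small(coverage=30.0)
        n_span = int(rs.truth["spans_junction"].sum())
        n_normal = int((rs.klass == 0).sum())
        density = n_normal / sample.total_length()
        expect = density * (cfg.insert_mean - 1) * len(sample.junctions)
        assert abs(n_span - expect) < 4 * np.sqrt(expect)

    def test_fastq_write_deterministic(self, tmp_path):
        cfg, sample, rs = simulate_small()
        idx = np.arange(50)
        p1 = rs.write_fastq(tmp_path / "a", idx)
        p2 = rs.write_fastq(tmp_path / "b", idx)
        assert open(p1[0]).read() == open(p2[0]).read()
        assert open(p1[1]).read() == open(p2[1]).read()

    def test_quality_strings_track_error_rate(self):
        cfg, _, rs = simulate_small(error_rate=0.01, quality_jitter_sd=0.0)
        _, s1, q1, _, _ = rs.materialize([0])[0]
        # Q20 for a 1% substitution rate
        assert set(q1) == {chr(20 + 33)}


class TestPrimaryAlignmentEmulation:
    def test_extracted_candidates_match_truth_mask(self, tmp_path):
        cfg, sample, rs = simulate_small()
        sam = emulate_primary_alignment(rs, tmp_path / "s.sam", max_concordant=500)
        from silicosv.readio import extract_candidates

        got = {r.read_id for r in extract_candidates(sam)}
        expect = {rs.read_id(int(i)) for i in np.flatnonzero(candidate_mask(rs))}
        assert got == expect

    def test_proper_pairs_have_config_insert_distribution(self, tmp_path):
        cfg, sample, rs = simulate_small()
        sam = emulate_primary_alignment(rs, tmp_path / "s.sam", max_concordant=2000)
        from silicosv.readio import compute_library_stats

        stats = compute_library_stats(sam)
        assert stats.mean_insert == pytest.approx(cfg.insert_mean, rel=0.05)
        assert stats.sd_insert == pytest.approx(cfg.insert_sd, rel=0.15)

    def test_germline_sample_has_no_discordant_normals(self, tmp_path):
        cfg = small_cfg()
        genome, table = make_genome(cfg)
        rs = simulate_read_pairs(identity_sample(genome, table), cfg)
        mask = candidate_mask(rs)
        normal_candidates = mask & (rs.klass == 0)
        assert not normal_candidates.any()

    def test_sam_parses_with_pysam_and_counts(self, tmp_path):
        cfg, sample, rs = simulate_small()
        sam = emulate_primary_alignment(rs, tmp_path / "s.sam", max_concordant=100)
        n_cand = int(candidate_mask(rs).sum())
        with pysam.AlignmentFile(str(sam), check_sq=False) as fh:
            records = list(fh)
        assert len(records) == 2 * (n_cand + 100)
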
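"""All-hits micro-aligner versus an exhaustive all-offset oracle."""

import numpy as np
import pytest

from silicosv.microalign import (
    DEFAULT_MAX_MISMATCH_RATE,
    ReadPairBatch,
    ReferenceIndex,
    align_pairs,
    align_read,
)
from silicosv.refmodel import reverse_complement

COMP = str.maketrans("ACGT", "TGCA")


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# independent oracle: score the read at every offset of both strands


def oracle_hits(read, ref, k=15, rate=DEFAULT_MAX_MISMATCH_RATE):
    hits = set()
    for strand, oriented in (("+", read), ("-", read.translate(COMP)[::-1])):
        rl = len(oriented)
        for d in range(-rl + 1, len(ref)):
            r_lo, r_hi = max(0, d), min(len(ref), d + rl)
            if r_hi - r_lo < k:
                continue
            match = [
                ref[r] == oriented[r - d] for r in range(r_lo, r_hi)
            ]
            # seed condition: an exact k-mer somewhere on this diagonal
            run = best = 0
            for m in match:
                run = run + 1 if m else 0
                best = max(best, run)
            if best < k:
                continue
            # best segment by exhaustive enumeration: max score, then min
            # start, then max length
            n = len(match)
            best_key, seg = None, None
            for i in range(n):
                for j in range(i + 1, n + 1):
                    sc = sum(1 if m else -2 for m in match[i:j])
                    key = (sc, -i, j - i)
                    if best_key is None or key > best_key:
                        best_key, seg = key, (i, j)
            i, j = seg
            m_len = j - i
            mism = m_len - sum(match[i:j])
            if m_len < k or mism > rate * m_len:
                continue
            hits.add((r_lo + i + 1, strand, m_len, mism))
    return hits


def implementation_hits(read, ref, k=15, rate=DEFAULT_MAX_MISMATCH_RATE):
    index = ReferenceIndex("r", ref, k=k)
    return {(h.pos, h.strand, h.m_len, h.n_mismatch) for h in align_read(read, index, rate)}


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_planted_reads_match_oracle(self, seed):
        """Random reads planted with mutations/clips agree with the
        brute-force all-offset scan."""
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, 600)
        pos = int(rng.integers(0, 500))
        read = list(ref[pos : pos + 80])
        for _ in range(int(rng.integers(0, 4))):  # a few substitutions
            i = int(rng.integers(len(read)))
            read[i] = "ACGT"[int(rng.integers(4))]
        read = "".join(read)
        if rng.random() < 0.5:
            read = reverse_complement(read)
        assert implementation_hits(read, ref) == oracle_hits(read, ref)

    @pytest.mark.parametrize("seed", range(8, 12))
    def test_chimeric_reads_match_oracle(self, seed):
        """Reads straddling two loci (soft-clip case) agree with the oracle."""
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, 500)
        a, b = int(rng.integers(0, 200)), int(rng.integers(250, 400))
        split = int(rng.integers(20, 60))
        read = ref[a : a + split] + ref[b : b + 80 - split]
        assert implementation_hits(read, ref) == oracle_hits(read, ref)

    @pytest.mark.parametrize("seed", range(12, 15))
    def test_random_reads_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_seq(rng, 400)
        read = random_seq(rng, 60)
        assert implementation_hits(read, ref) == oracle_hits(read, ref)


class TestExamples:
    def test_error_free_copy_full_match(self, rng):
        ref = random_seq(rng, 2000)
        index = ReferenceIndex("m", ref)
        hits = align_read(ref[300:400], index)
        assert [(h.pos, h.strand, h.cigar, h.n_mismatch) for h in hits] == [(301, "+", "100M", 0)]

    def test_junction_straddler_soft_clipped(self, rng):
        seg_a, seg_b = random_seq(rng, 1000), random_seq(rng, 1000)
        model = seg_a + seg_b
        index = ReferenceIndex("m", model)
        # read: last 60 bp of segment A + first 40 bp of segment B
        read = seg_a[-60:] + seg_b[:40]
        cigars = {(h.pos, h.cigar) for h in align_read(read, index)}
        assert (941, "100M") in cigars or (941, "60M40S") in cigars
        # on a reference holding only segment A the read must soft-clip
        index_a = ReferenceIndex("a", seg_a)
        hits_a = align_read(read, index_a)
        assert [(h.pos, h.cigar) for h in hits_a] == [(941, "60M40S")]

    def test_two_placements_give_two_hits_mapq_zero(self, rng):
        unit = random_seq(rng, 100)
        ref = unit + random_seq(rng, 300) + unit
        index = ReferenceIndex("m", ref)
        hits = align_read(unit, index)
        assert sorted(h.pos for h in hits if h.strand == "+") == [1, 401]
        header, recs = align_pairs([("p", unit, "I" * 100, random_seq(rng, 100), "I" * 100)], index)
        mate1 = [r for r in recs if r.is_read1 and not r.is_unmapped]
        assert all(r.mapping_quality == 0 for r in mate1)
        assert sum(not r.is_secondary for r in mate1) == 1

    def test_unique_hit_gets_mapq_60_and_template_length(self, rng):
        ref = random_seq(rng, 3000)
        index = ReferenceIndex("m", ref)
        pair = ("p", ref[100:200], "I" * 100, reverse_complement(ref[500:600]), "I" * 100)
        _, recs = align_pairs([pair], index)
        prim = [r for r in recs if not r.is_secondary]
        assert [r.mapping_quality for r in prim] == [60, 60]
        assert sorted(r.template_length for r in prim) == [-500, 500]

    def test_seed_longer_than_read_errors(self, rng):
        index = ReferenceIndex("m", random_seq(rng, 100), k=15)
        with pytest.raises(ValueError, match="seed length"):
            align_read("ACGTACGTAC", index)

    def test_cigar_lengths_sum_to_read_length_and_stay_in_bounds(self, rng):
        ref = random_seq(rng, 500)
        for trial in range(20):
            r = np.random.default_rng(trial)
            pos = int(r.integers(0, 420))
            read = ref[pos : pos + 80]
            for h in align_read(read, ReferenceIndex("m", ref)):
                lens = sum(int(x) for x in h.cigar.replace("M", " ").replace("S", " ").split())
                assert lens == 80
                assert h.pos + h.m_len - 1 <= 500


class TestBatch:
    def test_batch_path_equals_per_read_path(self, rng):
        ref = random_seq(rng, 1500)
        index = ReferenceIndex("m", ref)
        pairs = []
        for i in range(10):
            a = int(rng.integers(0, 1300))
            b = int(rng.integers(0, 1300))
            pairs.append((f"p{i}", ref[a : a + 100], "I" * 100,
                          reverse_complement(ref[b : b + 100]), "I" * 100))
        batch = ReadPairBatch(pairs)
        _, batch_recs = align_pairs(batch, index)
        _, iter_recs = align_pairs(iter(pairs), index)
        key = lambda r: (r.query_name, r.flag, r.reference_start, r.cigarstring)
        assert sorted(map(key, batch_recs)) == sorted(map(key, iter_recs))

    def test_mixed_read_lengths_rejected(self):
        with pytest.raises(ValueError, match="read length"):
            ReadPairBatch([("a", "A" * 50, "I" * 50, "C" * 60, "I" * 60)])
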
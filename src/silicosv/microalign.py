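"""Minimal all-hits read aligner for small model references.

The scoring pipeline only consumes alignment positions, CIGAR match
fractions, map quality and template lengths, so a deliberately small
ungapped aligner is sufficient: exact k-mer seeding against an indexed
reference followed by ungapped verification of each candidate diagonal.
Externally produced SAM/BAM against the same references can be used
interchangeably.

Verification rule (shared with the tests' brute-force oracle): overlay the
read on the reference at the candidate diagonal, score each column +1 for a
match and -2 for a mismatch, and take the maximum-scoring contiguous
segment (ties: smallest start, then longest).  The segment becomes the
CIGAR M run, with unextendable tails soft-clipped.  A hit is reported when
the diagonal carries at least one exact k-mer match (the seed), the M run
is at least k long, and its mismatch rate is at most ``max_mismatch_rate``.

Map quality follows a two-value convention: 60 for a mate with a unique
hit, 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

__all__ = ["AlignmentHit", "ReferenceIndex", "align_read", "align_pairs", "write_sam"]

_CODE = np.full(256, 4, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i

DEFAULT_K = 15
DEFAULT_MAX_MISMATCH_RATE = 0.05


def encode(seq: str) -> np.ndarray:
    """Sequence to uint8 codes A=0 C=1 G=2 T=3, anything else 4 (never matches)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def _kmer_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer value of every k-mer window; second array flags valid windows."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    valid = (windows < 4).all(axis=1)
    return windows @ powers, valid


@dataclass(frozen=True)
class AlignmentHit:
    """One ungapped placement of a (strand-oriented) read on a reference."""

    reference_name: str
    pos: int                 # 1-based position of the first aligned (M) base
    strand: str              # "+" or "-"
    cigar: str
    n_mismatch: int
    m_len: int
    read_start: int          # 0-based offset of the M run within the oriented read

    @property
    def score(self) -> int:
        return self.m_len - 3 * self.n_mismatch


class ReferenceIndex:
    """Sorted k-mer index over one model reference sequence."""

    def __init__(self, name: str, sequence: str, k: int = DEFAULT_K):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.name = name
        self.k = k
        self.codes = encode(sequence)
        self.length = len(self.codes)
        values, valid = _kmer_values(self.codes, k)
        order = np.argsort(values[valid], kind="stable")
        self._kmers = values[valid][order]
        self._positions = np.flatnonzero(valid)[order].astype(np.int64)

    def seed_positions(self, kmer_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Reference positions of each query k-mer; returns (query_idx, ref_pos)."""
        left = np.searchsorted(self._kmers, kmer_values, side="left")
        right = np.searchsorted(self._kmers, kmer_values, side="right")
        counts = right - left
        if counts.sum() == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qidx = np.repeat(np.arange(len(kmer_values)), counts)
        flat = np.concatenate([np.arange(l, r) for l, r in zip(left, right) if r > l])
        return qidx, self._positions[flat]


def _best_segment(match: np.ndarray) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment of +1/-2 column scores.

    Returns (start, length, mismatches); ties broken toward the smallest
    start, then the longest segment.  Vectorized over all O(L^2) segments.
    """
    scores = np.where(match, 1, -2).astype(np.int64)
    prefix = np.concatenate(([0], np.cumsum(scores)))
    n = len(scores)
    # segment [i, j) has score prefix[j] - prefix[i]
    seg = prefix[None, 1:] - prefix[: n, None]          # seg[i, j-1]
    i_idx = np.arange(n)[:, None]
    j_idx = np.arange(1, n + 1)[None, :]
    valid = j_idx > i_idx
    length = j_idx - i_idx
    # composite key: score desc, start asc, length desc
    key = seg * (4 * n * n) - i_idx * (2 * n) + length
    key = np.where(valid, key, np.iinfo(np.int64).min)
    flat = int(np.argmax(key))
    start, j = flat // (n), flat % n + 1
    seg_len = j - start
    mismatches = int(seg_len - match[start:j].sum())
    return start, seg_len, mismatches


def _hits_for_codes(
    read_codes: np.ndarray,
    index: ReferenceIndex,
    strand: str,
    max_mismatch_rate: float,
) -> list[AlignmentHit]:
    k = index.k
    if len(read_codes) < k:
        raise ValueError(f"seed length {k} exceeds read length {len(read_codes)}")
    values, valid = _kmer_values(read_codes, k)
    if not valid.any():
        return []
    qoff = np.flatnonzero(valid)
    qidx, ref_pos = index.seed_positions(values[valid])
    if len(qidx) == 0:
        return []
    diagonals = np.unique(ref_pos - qoff[qidx])
    hits = []
    for d in diagonals:
        hit = _verify_diagonal(read_codes, index, int(d), strand, max_mismatch_rate)
        if hit is not None:
            hits.append(hit)
    return hits


def align_read(
    seq: str,
    index: ReferenceIndex,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> list[AlignmentHit]:
    """All hits of one read on both strands of the indexed reference."""
    fwd = encode(seq)
    hits = _hits_for_codes(fwd, index, "+", max_mismatch_rate)
    hits += _hits_for_codes(reverse_complement_codes(fwd), index, "-", max_mismatch_rate)
    return hits


def _primary(hits: list[AlignmentHit]) -> AlignmentHit | None:
    if not hits:
        return None
    return max(hits, key=lambda h: (h.score, -h.pos, h.strand == "+"))


class ReadPairBatch:
    """Pre-encoded read pairs with per-strand k-mer values, reusable across
    references.  Reads in one batch must share one length."""

    def __init__(self, pairs, k: int = DEFAULT_K):
        self.k = k
        self.ids: list[str] = []
        self.seqs: list[tuple[str, str]] = []
        self.quals: list[tuple[str, str]] = []
        codes = []
        for read_id, seq1, qual1, seq2, qual2 in pairs:
            self.ids.append(read_id)
            self.seqs.append((seq1, seq2))
            self.quals.append((qual1, qual2))
            codes.append((encode(seq1), encode(seq2)))
        self.n = len(self.ids)
        if self.n == 0:
            self.codes = np.empty((0, 2, 2, 0), dtype=np.uint8)
            self.kmers = np.empty((0, 0), dtype=np.int64)
            return
        rl = {len(c) for pair in codes for c in pair}
        if len(rl) != 1:
            raise ValueError("all reads in a batch must share one read length")
        self.read_length = rl.pop()
        if k > self.read_length:
            raise ValueError(f"seed length {k} exceeds read length {self.read_length}")
        # axis layout: (pair, mate, strand, base)
        self.codes = np.empty((self.n, 2, 2, self.read_length), dtype=np.uint8)
        for i, (c1, c2) in enumerate(codes):
            self.codes[i, 0, 0] = c1
            self.codes[i, 0, 1] = reverse_complement_codes(c1)
            self.codes[i, 1, 0] = c2
            self.codes[i, 1, 1] = reverse_complement_codes(c2)
        flat = self.codes.reshape(-1, self.read_length)
        windows = np.lib.stride_tricks.sliding_window_view(flat, k, axis=1).astype(np.int64)
        powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
        values = windows @ powers
        values[(windows >= 4).any(axis=2)] = -1  # N-containing seeds never match
        self.kmers = values  # (n*4, offsets)

    def oriented(self, i: int, mate: int, strand: int) -> tuple[str, str]:
        seq, qual = self.seqs[i][mate], self.quals[i][mate]
        if strand == 1:
            from .refmodel import reverse_complement

            return reverse_complement(seq), qual[::-1]
        return seq, qual


def _batch_hits(batch: ReadPairBatch, index: ReferenceIndex, max_mismatch_rate: float):
    """All hits per (pair, mate): one searchsorted over the whole batch."""
    hits: dict[tuple[int, int], list[AlignmentHit]] = {}
    if batch.n == 0:
        return hits
    n_off = batch.kmers.shape[1]
    flat = batch.kmers.reshape(-1)
    kmers = index._kmers
    left = np.searchsorted(kmers, flat, side="left")
    found = np.flatnonzero((left < len(kmers)) & (kmers[np.minimum(left, len(kmers) - 1)] == flat))
    if len(found) == 0:
        return hits
    right = np.searchsorted(kmers, flat[found], side="right")
    counts = right - left[found]
    row = np.repeat(found // n_off, counts)          # index into (pair*4) rows
    off = np.repeat(found % n_off, counts)
    flat_pos = np.concatenate(
        [np.arange(l, r) for l, r in zip(left[found], right)]
    )
    diag = index._positions[flat_pos] - off
    key = np.stack([row, diag], axis=1)
    uniq = np.unique(key, axis=0)
    for r, d in uniq:
        i, mate, strand = int(r) // 4, (int(r) // 2) % 2, int(r) % 2
        hit = _verify_diagonal(batch.codes[i, mate, strand], index, int(d),
                               "+" if strand == 0 else "-", max_mismatch_rate)
        if hit is not None:
            hits.setdefault((i, mate), []).append((strand, hit))
    return hits


def _verify_diagonal(
    read_codes: np.ndarray,
    index: ReferenceIndex,
    d: int,
    strand: str,
    max_mismatch_rate: float,
) -> AlignmentHit | None:
    rl = len(read_codes)
    k = index.k
    r_lo = max(0, d)
    r_hi = min(index.length, d + rl)
    if r_hi - r_lo < k:
        return None
    q_lo, q_hi = r_lo - d, r_hi - d
    ref_seg = index.codes[r_lo:r_hi]
    read_seg = read_codes[q_lo:q_hi]
    match = (ref_seg == read_seg) & (read_seg < 4) & (ref_seg < 4)
    start, m_len, mism = _best_segment(match)
    if m_len < k or mism > max_mismatch_rate * m_len:
        return None
    read_start = q_lo + start
    lead, tail = read_start, rl - (read_start + m_len)
    cigar = (f"{lead}S" if lead else "") + f"{m_len}M" + (f"{tail}S" if tail else "")
    return AlignmentHit(
        reference_name=index.name,
        pos=r_lo + start + 1,
        strand=strand,
        cigar=cigar,
        n_mismatch=mism,
        m_len=m_len,
        read_start=read_start,
    )


def _oriented(seq: str, qual: str, hit: AlignmentHit) -> tuple[str, str]:
    if hit.strand == "-":
        from .refmodel import reverse_complement

        return reverse_complement(seq), qual[::-1]
    return seq, qual


def align_pairs(
    pairs,
    index: ReferenceIndex,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
):
    """Align read pairs; yields pysam records (primaries first, then secondaries).

    ``pairs`` iterates (read_id, seq1, qual1, seq2, qual2).  Map quality is
    60 for a unique hit and 0 for multi-hits; template length is set on
    primary records when both mates map.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": index.name, "LN": index.length}],
        }
    )
    batch = pairs if isinstance(pairs, ReadPairBatch) else ReadPairBatch(pairs, k=index.k)
    if batch.k != index.k:
        raise ValueError("batch seed length differs from index seed length")
    all_hits = _batch_hits(batch, index, max_mismatch_rate)
    records = []
    for i in range(batch.n):
        read_id = batch.ids[i]
        hits = [
            [h for _, h in all_hits.get((i, 0), [])],
            [h for _, h in all_hits.get((i, 1), [])],
        ]
        prim = [_primary(h) for h in hits]
        mapqs = [60 if len(h) == 1 else 0 for h in hits]
        seqs, quals = batch.seqs[i], batch.quals[i]
        tlen = 0
        if prim[0] is not None and prim[1] is not None:
            lo = min(p.pos for p in prim)
            hi = max(p.pos + p.m_len - 1 for p in prim)
            tlen = hi - lo + 1
        for mate in (0, 1):
            mhits = hits[mate]
            other = prim[1 - mate]
            for hit in mhits:
                is_primary = hit == prim[mate]
                rec = pysam.AlignedSegment(header)
                rec.query_name = read_id
                seq, qual = _oriented(seqs[mate], quals[mate], hit)
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                rec.reference_id = 0
                rec.reference_start = hit.pos - 1
                rec.cigarstring = hit.cigar
                rec.mapping_quality = mapqs[mate]
                rec.is_paired = True
                rec.is_read1 = mate == 0
                rec.is_read2 = mate == 1
                rec.is_reverse = hit.strand == "-"
                rec.is_secondary = not is_primary
                rec.set_tag("NM", hit.n_mismatch)
                if other is not None:
                    rec.next_reference_id = 0
                    rec.next_reference_start = other.pos - 1
                    rec.mate_is_reverse = other.strand == "-"
                else:
                    rec.mate_is_unmapped = True
                if is_primary and tlen:
                    sign = 1 if prim[mate].pos <= prim[1 - mate].pos else -1
                    rec.template_length = sign * tlen
                records.append(rec)
            if prim[mate] is None:
                # unmapped mate record keeps the pair visible in output
                rec = pysam.AlignedSegment(header)
                rec.query_name = read_id
                rec.query_sequence = seqs[mate]
                rec.query_qualities = pysam.qualitystring_to_array(quals[mate])
                rec.is_paired = True
                rec.is_read1 = mate == 0
                rec.is_read2 = mate == 1
                rec.is_unmapped = True
                if other is not None:
                    rec.next_reference_id = 0
                    rec.next_reference_start = other.pos - 1
                records.append(rec)
    return header, records


def write_sam(header, records, path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)
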
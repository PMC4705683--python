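"""Synthetic inputs with the structure the detection method assumes.

The generator builds everything the pipeline needs without any download: a
random-composition genome partitioned into named cytogenetic bands, a donor
genome carrying one reciprocal inter-chromosomal translocation at a known
junction (never on a band boundary), and Illumina-like paired reads with a
normal insert-size distribution and per-base substitution errors whose
quality strings are consistent with the error model.

Because the pipeline consumes a *previously aligned* sample, the generator
also emulates the primary alignment step directly from the read truth
table: reads wholly inside a conserved segment are emitted as mapped
records at their lifted reference coordinates, pairs whose mates lift to
different chromosomes become discordant records, junction-straddling reads
become unmapped records, and the simulated noise classes (chimeric pairs,
small-insert junk, random garbage) are emitted as the mismapped/unmapped
background that real candidate read sets contain.  This stands in for
running an external aligner, which at these reference sizes would add
nothing the scoring stages consume.

All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .karyoband import BandTable, CytoBand

__all__ = [
    "SimulationConfig",
    "TranslocationSpec",
    "SampleGenome",
    "ReadSet",
    "make_genome",
    "random_translocation",
    "apply_translocation",
    "identity_sample",
    "simulate_read_pairs",
    "emulate_primary_alignment",
]

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

KLASS_NORMAL, KLASS_CHIMERA, KLASS_JUNK, KLASS_GARBAGE = 0, 1, 2, 3
KLASS_NAMES = {0: "normal", 1: "chimera", 2: "junk", 3: "garbage"}


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the Illumina-style profile used throughout the package:
    100 bp reads with 400 +/- 50 bp inserts at 30x coverage over 1 Mb
    chromosomes.  ``error_rate`` sets the mean per-base substitution rate;
    base qualities are drawn around the matching Phred value.  The noise
    rates control the mismapped/unmapped background classes that populate
    decoy model regions.
    """

    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    bands_per_chrom: int = 5
    read_length: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    coverage: float = 30.0
    error_rate: float = 0.005
    quality_model: str = "constant"      # "constant" or "decay"
    quality_jitter_sd: float = 3.0
    quality_decay: float = 0.05          # Phred lost per base for "decay"
    variant_fraction: float = 1.0        # fraction of fragments from the variant genome
    chimera_rate: float = 0.005
    junk_rate: float = 0.0008
    garbage_rate: float = 0.0005
    junk_insert_range: tuple[int, int] = (120, 260)
    junction_margin: int = 10_000        # min distance of a junction from band edges
    seed: int = 0

    def validate(self) -> None:
        if self.coverage <= 0:
            raise SimulationError("coverage must be positive")
        if self.insert_mean <= self.read_length:
            raise SimulationError("insert mean must exceed read length")
        if self.bands_per_chrom < 2:
            raise SimulationError("need >= 2 bands per chromosome")
        if self.chimera_rate + self.junk_rate + self.garbage_rate >= 1:
            raise SimulationError("noise rates must sum to < 1")
        if self.quality_model not in ("constant", "decay"):
            raise SimulationError(f"unknown quality model {self.quality_model!r}")

    @property
    def base_quality(self) -> float:
        return -10.0 * np.log10(max(self.error_rate, 1e-6))


def _band_names(n: int) -> list[str]:
    """Arm/band names for one chromosome: e.g. n=5 -> p12 p11 q11 q12 q13."""
    n_p = n // 2
    p = [f"p{11 + i}" for i in range(n_p)][::-1]
    q = [f"q{11 + i}" for i in range(n - n_p)]
    return p + q


def make_genome(cfg: SimulationConfig) -> tuple[dict[str, str], BandTable]:
    """Random-composition chromosomes with an exact band partition; seeded."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    bands: list[CytoBand] = []
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        codes = rng.integers(0, 4, cfg.chrom_length, dtype=np.uint8)
        genome[chrom] = _BASES[codes].tobytes().decode("ascii")
        names = _band_names(cfg.bands_per_chrom)
        length = cfg.chrom_length
        pos = 1
        for i, name in enumerate(names):
            span = length // len(names) + (1 if i < length % len(names) else 0)
            bands.append(CytoBand(chrom, pos, pos + span - 1, name))
            pos += span
        if pos != length + 1:
            raise SimulationError("band partition does not cover chromosome")
    return genome, BandTable(bands, genome_label=f"sim-seed{cfg.seed}")


@dataclass(frozen=True)
class TranslocationSpec:
    chrom_a: str
    pos_a: int    # 1-based last base of chrom_a retained on the derivative
    chrom_b: str
    pos_b: int    # 1-based first base of chrom_b joined after pos_a
    band_a: str
    band_b: str

    @property
    def band_pair(self) -> frozenset[str]:
        return frozenset((self.band_a, self.band_b))


@dataclass
class Junction:
    der_chrom: str
    offset: int                 # 1-based position of the last base of segment 1
    band_pair: frozenset[str]


@dataclass
class SampleGenome:
    """A donor genome: derived chromosomes plus the reference they came from.

    Each chromosome is described by its source segments (reference chrom,
    0-based start, length), which makes lifting donor coordinates back to
    reference coordinates exact.
    """

    chroms: dict[str, str]
    segments: dict[str, list[tuple[str, int, int]]]
    junctions: list[Junction]
    reference: dict[str, str]
    band_table: BandTable
    spec: TranslocationSpec | None = None

    def total_length(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def lift(self, chrom: str, pos0: int) -> tuple[str, int]:
        """Donor 0-based position -> (reference chrom, reference 0-based pos)."""
        offset = 0
        for src, start, length in self.segments[chrom]:
            if pos0 < offset + length:
                return src, start + (pos0 - offset)
            offset += length
        raise IndexError(f"position {pos0} beyond chromosome {chrom}")

    def boundaries(self, chrom: str) -> list[int]:
        """0-based indices of the last base of each internal segment."""
        out, acc = [], 0
        segs = self.segments[chrom]
        for src, start, length in segs[:-1]:
            acc += length
            out.append(acc - 1)
        return out

    @property
    def true_band_pair(self) -> frozenset[str] | None:
        return self.spec.band_pair if self.spec else None


def _band_at(table: BandTable, chrom: str, pos: int) -> CytoBand:
    for band in table:
        if band.chrom == chrom and band.start <= pos <= band.end:
            return band
    raise SimulationError(f"no band covers {chrom}:{pos}")


def random_translocation(
    genome: dict[str, str],
    table: BandTable,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> TranslocationSpec:
    """Random inter-chromosomal translocation, junctions well inside bands."""
    chroms = list(genome)
    if len(chroms) < 2:
        raise SimulationError("need >= 2 chromosomes for an inter-chromosomal event")
    ca, cb = [chroms[i] for i in rng.choice(len(chroms), size=2, replace=False)]

    def pick(chrom: str) -> tuple[int, str]:
        candidates = [b for b in table if b.chrom == chrom and b.length > 2 * cfg.junction_margin]
        if not candidates:
            raise SimulationError(f"no band on {chrom} can host a junction with margin")
        band = candidates[int(rng.integers(len(candidates)))]
        pos = int(rng.integers(band.start + cfg.junction_margin, band.end - cfg.junction_margin + 1))
        return pos, band.label

    pos_a, band_a = pick(ca)
    pos_b, band_b = pick(cb)
    return TranslocationSpec(ca, pos_a, cb, pos_b, band_a, band_b)


def apply_translocation(
    genome: dict[str, str],
    table: BandTable,
    spec: TranslocationSpec,
    margin: int = 1,
) -> SampleGenome:
    """Build the donor genome carrying the reciprocal translocation.

    der(A) = A[1..pos_a] ++ B[pos_b..end] and der(B) = B[1..pos_b-1] ++
    A[pos_a+1..end]; sequence content is conserved.  Junctions must fall
    strictly inside a band (by at least ``margin`` bp from its edges).
    """
    if spec.chrom_a == spec.chrom_b:
        raise SimulationError("translocation must be inter-chromosomal")
    for chrom, pos in ((spec.chrom_a, spec.pos_a), (spec.chrom_b, spec.pos_b)):
        band = _band_at(table, chrom, pos)
        if pos - band.start < margin or band.end - pos < margin:
            raise SimulationError(
                f"junction {chrom}:{pos} falls on or too near the boundary of band {band.label}"
            )
    a, b = genome[spec.chrom_a], genome[spec.chrom_b]
    der_a_name, der_b_name = f"der{spec.chrom_a}", f"der{spec.chrom_b}"
    chroms = {}
    segments = {}
    for name, seq in genome.items():
        if name not in (spec.chrom_a, spec.chrom_b):
            chroms[name] = seq
            segments[name] = [(name, 0, len(seq))]
    chroms[der_a_name] = a[: spec.pos_a] + b[spec.pos_b - 1 :]
    segments[der_a_name] = [
        (spec.chrom_a, 0, spec.pos_a),
        (spec.chrom_b, spec.pos_b - 1, len(b) - spec.pos_b + 1),
    ]
    chroms[der_b_name] = b[: spec.pos_b - 1] + a[spec.pos_a :]
    segments[der_b_name] = [
        (spec.chrom_b, 0, spec.pos_b - 1),
        (spec.chrom_a, spec.pos_a, len(a) - spec.pos_a),
    ]
    junctions = [
        Junction(der_a_name, spec.pos_a, spec.band_pair),
        Junction(der_b_name, spec.pos_b - 1, spec.band_pair),
    ]
    return SampleGenome(
        chroms=chroms,
        segments=segments,
        junctions=junctions,
        reference=dict(genome),
        band_table=table,
        spec=spec,
    )


def identity_sample(genome: dict[str, str], table: BandTable) -> SampleGenome:
    """A donor genome identical to the reference (germline sample)."""
    return SampleGenome(
        chroms=dict(genome),
        segments={name: [(name, 0, len(seq))] for name, seq in genome.items()},
        junctions=[],
        reference=dict(genome),
        band_table=table,
    )


@dataclass
class ReadSet:
    """Simulated paired reads as coordinate arrays plus a truth table.

    Sequences are materialized on demand (vectorized) so genome-scale read
    sets stay cheap when only a subset is ever written out.
    """

    cfg: SimulationConfig
    sample: SampleGenome
    klass: np.ndarray                    # per pair
    m_source: np.ndarray                 # (n, 2): 0 donor, 1 reference, 2 random
    m_chrom: np.ndarray                  # (n, 2) index into source chrom list
    m_start: np.ndarray                  # (n, 2) 0-based
    frag_len: np.ndarray
    truth: pd.DataFrame = field(repr=False)
    seed: int = 0

    def __len__(self) -> int:
        return len(self.klass)

    @property
    def donor_chroms(self) -> list[str]:
        return list(self.sample.chroms)

    @property
    def reference_chroms(self) -> list[str]:
        return list(self.sample.reference)

    def read_id(self, i: int) -> str:
        return f"p{i:07d}_{KLASS_NAMES[int(self.klass[i])]}"

    def materialize(self, indices=None) -> list[tuple[str, str, str, str, str]]:
        """Build (read_id, seq1, qual1, seq2, qual2) for the given pairs.

        Base-call errors and quality strings are drawn from a child RNG of
        the read-set seed, so repeating the same call reproduces the same
        bytes.  Mate 2 is reported as sequenced: the reverse complement of
        the fragment end.
        """
        if indices is None:
            indices = np.arange(len(self))
        indices = np.asarray(indices, dtype=np.int64)
        rng = np.random.default_rng([self.seed, 0xE44])
        rl = self.cfg.read_length
        n = len(indices)
        donor = [np.frombuffer(self.sample.chroms[c].encode(), dtype=np.uint8) for c in self.donor_chroms]
        refer = [np.frombuffer(self.sample.reference[c].encode(), dtype=np.uint8) for c in self.reference_chroms]
        code_lut = np.full(256, 4, dtype=np.uint8)
        for v, base in enumerate(b"ACGT"):
            code_lut[base] = v
        out_codes = np.empty((n, 2, rl), dtype=np.uint8)
        for mate in (0, 1):
            src = self.m_source[indices, mate]
            chrom = self.m_chrom[indices, mate]
            start = self.m_start[indices, mate]
            for source, pool in ((0, donor), (1, refer)):
                for ci, arr in enumerate(pool):
                    sel = (src == source) & (chrom == ci)
                    if not sel.any():
                        continue
                    offs = start[sel, None] + np.arange(rl)[None, :]
                    out_codes[sel, mate] = code_lut[arr[offs]]
            randsel = src == 2
            if randsel.any():
                out_codes[randsel, mate] = rng.integers(0, 4, (int(randsel.sum()), rl), dtype=np.uint8)
        # mate 2 is sequenced from the other strand: reverse complement
        m2 = out_codes[:, 1, ::-1]
        out_codes[:, 1] = np.where(m2 < 4, 3 - m2, m2)
        quals = self._draw_qualities(rng, n)
        perr = np.power(10.0, -quals / 10.0)
        err = rng.random((n, 2, rl)) < perr
        shift = rng.integers(1, 4, (n, 2, rl), dtype=np.uint8)
        out_codes = np.where(err & (out_codes < 4), (out_codes + shift) % 4, out_codes)
        seq_bytes = _BASES[out_codes]
        qual_bytes = (quals + 33).astype(np.uint8)
        result = []
        for row, i in enumerate(indices):
            result.append(
                (
                    self.read_id(int(i)),
                    seq_bytes[row, 0].tobytes().decode(),
                    qual_bytes[row, 0].tobytes().decode(),
                    seq_bytes[row, 1].tobytes().decode(),
                    qual_bytes[row, 1].tobytes().decode(),
                )
            )
        return result

    def _draw_qualities(self, rng: np.random.Generator, n: int) -> np.ndarray:
        rl = self.cfg.read_length
        base = np.full(rl, self.cfg.base_quality)
        if self.cfg.quality_model == "decay":
            base = base - self.cfg.quality_decay * np.arange(rl)
        q = base[None, None, :] + rng.normal(0, self.cfg.quality_jitter_sd, (n, 2, rl))
        return np.clip(np.rint(q), 2, 41).astype(np.int16)

    def write_fastq(self, prefix, indices=None) -> tuple[str, str]:
        fq1, fq2 = f"{prefix}_1.fastq", f"{prefix}_2.fastq"
        with open(fq1, "w") as f1, open(fq2, "w") as f2:
            for rid, s1, q1, s2, q2 in self.materialize(indices):
                f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
                f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")
        return fq1, fq2


def simulate_read_pairs(sample: SampleGenome, cfg: SimulationConfig, seed: int | None = None) -> ReadSet:
    """Simulate the full paired-end read set for one donor genome.

    Fragment count is coverage * genome_length / (2 * read_length).
    Fragments are sampled uniformly (length-weighted across chromosomes)
    with normal insert sizes truncated at the read length; a configurable
    fraction of fragments is drawn from the reference instead of the donor
    to emulate tumor heterogeneity.  The truth table records, per pair, the
    donor origin, lifted reference coordinates per mate, and whether the
    fragment spans (or a read straddles) a translocation junction.
    """
    cfg.validate()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 0x51])
    rl = cfg.read_length
    total_len = sample.total_length()
    n_pairs = int(round(cfg.coverage * total_len / (2 * rl)))
    if n_pairs < 1:
        raise SimulationError("coverage too low: fewer than one fragment")

    probs = [cfg.chimera_rate, cfg.junk_rate, cfg.garbage_rate]
    klass = rng.choice(
        [KLASS_CHIMERA, KLASS_JUNK, KLASS_GARBAGE, KLASS_NORMAL],
        size=n_pairs,
        p=probs + [1 - sum(probs)],
    ).astype(np.int8)

    m_source = np.zeros((n_pairs, 2), dtype=np.int8)
    m_chrom = np.zeros((n_pairs, 2), dtype=np.int16)
    m_start = np.zeros((n_pairs, 2), dtype=np.int64)
    frag_len = np.zeros(n_pairs, dtype=np.int64)

    donor_names = list(sample.chroms)
    donor_lens = np.array([len(sample.chroms[c]) for c in donor_names])
    ref_names = list(sample.reference)
    ref_lens = np.array([len(sample.reference[c]) for c in ref_names])

    # --- normal fragments -------------------------------------------------
    normal = np.flatnonzero(klass == KLASS_NORMAL)
    n_norm = len(normal)
    lengths = np.maximum(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, n_norm)).astype(np.int64), rl
    )
    from_variant = rng.random(n_norm) < cfg.variant_fraction
    for use_donor, names, lens in ((True, donor_names, donor_lens), (False, ref_names, ref_lens)):
        sel = np.flatnonzero(from_variant == use_donor)
        if len(sel) == 0:
            continue
        cidx = rng.choice(len(names), size=len(sel), p=lens / lens.sum())
        max_start = lens[cidx] - lengths[sel]
        # fragments longer than the chromosome are clipped to it
        lengths[sel] = np.where(max_start < 0, lens[cidx], lengths[sel])
        max_start = np.maximum(lens[cidx] - lengths[sel], 0)
        starts = (rng.random(len(sel)) * (max_start + 1)).astype(np.int64)
        rows = normal[sel]
        m_source[rows] = 0 if use_donor else 1
        m_chrom[rows, 0] = m_chrom[rows, 1] = cidx
        m_start[rows, 0] = starts
        m_start[rows, 1] = starts + lengths[sel] - rl
        frag_len[rows] = lengths[sel]

    # --- chimeric pairs: mates from two different reference chromosomes ---
    chim = np.flatnonzero(klass == KLASS_CHIMERA)
    if len(chim) and len(ref_names) >= 2:
        c1 = rng.integers(0, len(ref_names), len(chim))
        delta = rng.integers(1, len(ref_names), len(chim))
        c2 = (c1 + delta) % len(ref_names)
        m_source[chim] = 1
        m_chrom[chim, 0], m_chrom[chim, 1] = c1, c2
        m_start[chim, 0] = (rng.random(len(chim)) * (ref_lens[c1] - rl + 1)).astype(np.int64)
        m_start[chim, 1] = (rng.random(len(chim)) * (ref_lens[c2] - rl + 1)).astype(np.int64)

    # --- small-insert junk: one reference locus, tiny fragment ------------
    junk = np.flatnonzero(klass == KLASS_JUNK)
    if len(junk):
        jlen = rng.integers(cfg.junk_insert_range[0], cfg.junk_insert_range[1] + 1, len(junk))
        jlen = np.maximum(jlen, rl)
        cidx = rng.choice(len(ref_names), size=len(junk), p=ref_lens / ref_lens.sum())
        starts = (rng.random(len(junk)) * (ref_lens[cidx] - jlen + 1)).astype(np.int64)
        m_source[junk] = 1
        m_chrom[junk, 0] = m_chrom[junk, 1] = cidx
        m_start[junk, 0] = starts
        m_start[junk, 1] = starts + jlen - rl
        frag_len[junk] = jlen

    # --- garbage: random sequence, no genomic origin ----------------------
    garb = np.flatnonzero(klass == KLASS_GARBAGE)
    m_source[garb] = 2

    truth = _build_truth(sample, cfg, klass, m_source, m_chrom, m_start, frag_len, donor_names, ref_names)
    return ReadSet(
        cfg=cfg,
        sample=sample,
        klass=klass,
        m_source=m_source,
        m_chrom=m_chrom,
        m_start=m_start,
        frag_len=frag_len,
        truth=truth,
        seed=seed,
    )


def _build_truth(sample, cfg, klass, m_source, m_chrom, m_start, frag_len, donor_names, ref_names):
    rl = cfg.read_length
    n = len(klass)
    ref_chrom = np.full((n, 2), None, dtype=object)
    ref_pos = np.zeros((n, 2), dtype=np.int64)       # 1-based; 0 = undefined
    crosses = np.zeros((n, 2), dtype=bool)
    spans = np.zeros(n, dtype=bool)

    boundaries = {c: sample.boundaries(c) for c in donor_names}
    ref_name_arr = np.array(ref_names, dtype=object)
    for mate in (0, 1):
        donor_sel = m_source[:, mate] == 0
        for ci, cname in enumerate(donor_names):
            rows = np.flatnonzero(donor_sel & (m_chrom[:, mate] == ci))
            if len(rows) == 0:
                continue
            starts = m_start[rows, mate]
            crossed = np.zeros(len(rows), dtype=bool)
            for b in boundaries[cname]:
                crossed |= (starts <= b) & (b <= starts + rl - 2)
            crosses[rows, mate] = crossed
            # vectorized lift of non-crossing reads through the segment map
            segs = sample.segments[cname]
            seg_off = np.concatenate(([0], np.cumsum([s[2] for s in segs])))
            seg_src = np.array([s[0] for s in segs], dtype=object)
            seg_start = np.array([s[1] for s in segs], dtype=np.int64)
            ok = rows[~crossed]
            s_ok = m_start[ok, mate]
            idx = np.searchsorted(seg_off, s_ok, side="right") - 1
            ref_chrom[ok, mate] = seg_src[idx]
            ref_pos[ok, mate] = seg_start[idx] + (s_ok - seg_off[idx]) + 1
        refr = np.flatnonzero(m_source[:, mate] == 1)
        ref_chrom[refr, mate] = ref_name_arr[m_chrom[refr, mate]]
        ref_pos[refr, mate] = m_start[refr, mate] + 1

    norm = np.flatnonzero((klass == KLASS_NORMAL) & (m_source[:, 0] == 0))
    for ci, cname in enumerate(donor_names):
        rows = norm[m_chrom[norm, 0] == ci]
        if len(rows) == 0:
            continue
        starts, flens = m_start[rows, 0], frag_len[rows]
        for b in boundaries[cname]:
            spans[rows] |= (starts <= b) & (b < starts + flens - 1)

    return pd.DataFrame(
        {
            "pair_id": [f"p{i:07d}_{KLASS_NAMES[int(klass[i])]}" for i in range(n)],
            "klass": [KLASS_NAMES[int(k)] for k in klass],
            "chrom1": ref_chrom[:, 0],
            "pos1": ref_pos[:, 0],
            "chrom2": ref_chrom[:, 1],
            "pos2": ref_pos[:, 1],
            "frag_len": frag_len,
            "spans_junction": spans,
            "read1_crosses": crosses[:, 0],
            "read2_crosses": crosses[:, 1],
        }
    )


def candidate_mask(readset: ReadSet) -> np.ndarray:
    """Pairs a primary aligner would leave discordant or (half-)unmapped."""
    t = readset.truth
    unmapped1 = (readset.klass >= KLASS_JUNK) | t["read1_crosses"].to_numpy()
    unmapped2 = (readset.klass >= KLASS_JUNK) | t["read2_crosses"].to_numpy()
    both_mapped = ~(unmapped1 | unmapped2)
    diff_chrom = both_mapped & (t["chrom1"].to_numpy() != t["chrom2"].to_numpy())
    return diff_chrom | unmapped1 | unmapped2


def emulate_primary_alignment(
    readset: ReadSet,
    sam_path,
    max_concordant: int | None = 20_000,
    seed: int | None = None,
) -> str:
    """Write the aligned-sample SAM a primary aligner would have produced.

    All candidate pairs (discordant / unmapped) are emitted; concordant
    pairs are emitted up to ``max_concordant`` (seeded subsample) since the
    pipeline only uses them for library statistics.
    """
    cfg = readset.cfg
    rl = cfg.read_length
    seed = readset.seed if seed is None else seed
    rng = np.random.default_rng([seed, 0xA11])
    t = readset.truth
    cand = candidate_mask(readset)
    conc = np.flatnonzero(~cand)
    if max_concordant is not None and len(conc) > max_concordant:
        conc = np.sort(rng.choice(conc, size=max_concordant, replace=False))
    emit = np.concatenate([np.flatnonzero(cand), conc])
    emit.sort()
    reads = readset.materialize(emit)

    ref_names = readset.reference_chroms
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": c, "LN": len(readset.sample.reference[c])} for c in ref_names],
        }
    )
    tid = {c: i for i, c in enumerate(ref_names)}
    chrom1 = t["chrom1"].to_numpy()
    chrom2 = t["chrom2"].to_numpy()
    pos1 = t["pos1"].to_numpy()
    pos2 = t["pos2"].to_numpy()
    frag = t["frag_len"].to_numpy()
    x1 = t["read1_crosses"].to_numpy()
    x2 = t["read2_crosses"].to_numpy()
    from .refmodel import reverse_complement

    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for (rid, s1, q1, s2, q2), i in zip(reads, emit):
            k = int(readset.klass[i])
            mapped1 = k in (KLASS_NORMAL, KLASS_CHIMERA) and not x1[i]
            mapped2 = k in (KLASS_NORMAL, KLASS_CHIMERA) and not x2[i]
            proper = (
                k == KLASS_NORMAL
                and mapped1
                and mapped2
                and chrom1[i] == chrom2[i]
            )
            for mate, (seq, qual, mapped, chrom, pos, mchrom, mpos, mmapped) in enumerate(
                (
                    (s1, q1, mapped1, chrom1[i], pos1[i], chrom2[i], pos2[i], mapped2),
                    (s2, q2, mapped2, chrom2[i], pos2[i], chrom1[i], pos1[i], mapped1),
                )
            ):
                rec = pysam.AlignedSegment(header)
                rec.query_name = rid
                rec.is_paired = True
                rec.is_read1 = mate == 0
                rec.is_read2 = mate == 1
                reverse = mapped and mate == 1  # mate 2 sequenced from the reverse strand
                if reverse:
                    seq, qual = reverse_complement(seq), qual[::-1]
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                if mapped:
                    rec.reference_id = tid[chrom]
                    rec.reference_start = int(pos) - 1
                    rec.cigarstring = f"{rl}M"
                    rec.mapping_quality = 60 if k == KLASS_NORMAL else 20
                    rec.is_reverse = reverse
                else:
                    rec.is_unmapped = True
                if mmapped:
                    rec.next_reference_id = tid[mchrom]
                    rec.next_reference_start = int(mpos) - 1
                    rec.mate_is_reverse = mate == 0
                else:
                    rec.mate_is_unmapped = True
                if proper:
                    rec.is_proper_pair = True
                    rec.template_length = int(frag[i]) * (1 if mate == 0 else -1)
                out.write(rec)
    return str(sam_path)


def write_genome_fasta(genome: dict[str, str], path) -> str:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    return str(path)
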
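"""End-to-end orchestration: select regions, build references, realign, score, call.

The stages mirror the method's workflow: prior breakpoint knowledge picks a
set of band pairs; each pair becomes an in silico model reference; the
sample's discordant/unmapped read pairs are realigned against every model;
each model region is scored (EM mixture + window clustering -> Tx) and the
Tx scores are clustered to call likely breakpoint regions, optionally
subtracting germline hits.  Every stage persists its intermediate so a run
can be resumed or inspected, and a manifest records parameters and seeds.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import __version__
from .karyoband import BandTable, BreakpointFrequencyTable, inter_chromosomal_pairs
from .microalign import ReadPairBatch, ReferenceIndex, align_pairs, write_sam
from .readio import LibraryStats, compute_library_stats, extract_candidates, write_candidate_fastq
from .refmodel import InSilicoReference, build_reference, write_reference_set
from .svcall import CallSet, call_regions, subtract_germline, write_calls_bed, write_calls_tsv
from .svscore import RegionScore, score_model_region

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs for one pipeline run; paths may be None when driven in-memory."""

    out_dir: str = "."
    selection_mode: str = "all_pairs"      # "all_pairs" or "de"
    max_regions: int | None = None
    k_clusters: int = 4
    seed_len: int = 15
    max_mismatch_rate: float = 0.05
    noise_cutoff: float = 1.0 / 3.0
    window: int | None = None              # default: 2 x mean insert
    step: int | None = None
    stats_sample_size: int = 1_000_000
    seed: int = 0
    persist_alignments: bool = True
    de_config: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    scores: list[RegionScore]
    unscorable: list[str]
    callset: CallSet
    stats: LibraryStats
    band_pairs: dict[str, frozenset[str]]
    references: list[InSilicoReference]
    somatic: CallSet | None = None


def select_regions(
    table: BandTable,
    cfg: PipelineConfig,
    freqs: BreakpointFrequencyTable | None = None,
):
    """Choose the band pairs to model.

    ``all_pairs`` enumerates every inter-chromosomal pair (optionally
    capped), which is exact for small band universes such as simulations;
    ``de`` runs the differential-evolution selector against a breakpoint
    frequency table.
    """
    if cfg.selection_mode == "all_pairs":
        pairs = inter_chromosomal_pairs(table)
    elif cfg.selection_mode == "de":
        from .deselect import DEConfig, evolve, initialize_population

        if freqs is None:
            freqs = BreakpointFrequencyTable({}, table.labels)
        de_cfg = DEConfig(seed=cfg.seed, **cfg.de_config)
        pop = evolve(initialize_population(freqs, table, de_cfg), freqs, table, de_cfg)
        pairs = [tuple(table[lbl] for lbl in sorted(p)) for p in pop.unique_pairs()]
    else:
        raise ValueError(f"unknown selection mode {cfg.selection_mode!r}")
    if cfg.max_regions is not None:
        pairs = pairs[: cfg.max_regions]
    return pairs


def build_references(genome, pairs, out_dir=None):
    refs = [build_reference(genome, a, b) for a, b in pairs]
    if out_dir is not None:
        write_reference_set(refs, out_dir)
    return refs


def align_candidates_to_reference(
    candidates, ref: InSilicoReference, cfg: PipelineConfig, sam_path=None
):
    """Realign candidate pairs (or a prebuilt ReadPairBatch) against one model."""
    index = ReferenceIndex(ref.name, ref.sequence, k=cfg.seed_len)
    if isinstance(candidates, ReadPairBatch):
        batch = candidates
    else:
        batch = ReadPairBatch(
            (
                (r.read_id, r.mate1.seq, r.mate1.qual, r.mate2.seq, r.mate2.qual)
                for r in candidates
            ),
            k=cfg.seed_len,
        )
    header, records = align_pairs(batch, index, max_mismatch_rate=cfg.max_mismatch_rate)
    if sam_path is not None:
        write_sam(header, records, sam_path)
    return records


def score_references(candidates, refs, stats: LibraryStats, cfg: PipelineConfig, aln_dir=None):
    # encode and k-merize the candidate reads once; reuse across all references
    batch = ReadPairBatch(
        (
            (r.read_id, r.mate1.seq, r.mate1.qual, r.mate2.seq, r.mate2.qual)
            for r in candidates
        ),
        k=cfg.seed_len,
    )
    scores: list[RegionScore] = []
    unscorable: list[str] = []
    for ref in refs:
        sam_path = None
        if aln_dir is not None:
            sam_path = os.path.join(aln_dir, _safe(ref.name) + ".sam")
        records = align_candidates_to_reference(batch, ref, cfg, sam_path)
        score = score_model_region(
            ref.name,
            records,
            stats,
            ref_length=len(ref),
            junction_offset=ref.junction_offset,
            window=cfg.window,
            step=cfg.step,
            noise_cutoff=cfg.noise_cutoff,
            seed=cfg.seed,
        )
        if score is None:
            unscorable.append(ref.name)
        else:
            scores.append(score)
    return scores, unscorable


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "._-" else "_" for c in name)


def run_pipeline(
    genome,
    band_table: BandTable,
    sample_sam,
    cfg: PipelineConfig,
    freqs: BreakpointFrequencyTable | None = None,
    germline_sam=None,
) -> PipelineResult:
    """Run all stages on one previously aligned sample.

    ``genome`` is a chromosome-name -> sequence mapping (or pyfaidx Fasta);
    ``sample_sam`` a coordinate- or name-sorted SAM/BAM.  When
    ``germline_sam`` is given the germline is scored against the same
    references and its top-cluster band pairs are subtracted from the tumor
    calls.
    """
    t0 = time.time()
    out = cfg.out_dir
    os.makedirs(out, exist_ok=True)
    persist = cfg.persist_alignments

    pairs = select_regions(band_table, cfg, freqs)
    logger.info("selected %d model regions", len(pairs))
    refs = build_references(genome, pairs, os.path.join(out, "references") if persist else None)
    band_pairs = {r.name: r.band_pair for r in refs}

    stats = compute_library_stats(sample_sam, cfg.stats_sample_size, seed=cfg.seed)
    with open(os.path.join(out, "library_stats.json"), "w") as fh:
        json.dump(stats.to_dict(), fh, indent=1)

    candidates = extract_candidates(sample_sam)
    logger.info("extracted %d candidate pairs", len(candidates))
    if persist:
        write_candidate_fastq(candidates, os.path.join(out, "candidates"))

    aln_dir = None
    if persist:
        aln_dir = os.path.join(out, "alignments")
        os.makedirs(aln_dir, exist_ok=True)
    scores, unscorable = score_references(candidates, refs, stats, cfg, aln_dir)
    _write_scores(scores, unscorable, os.path.join(out, "scores.tsv"))

    callset = call_regions(scores, k=cfg.k_clusters, band_pairs=band_pairs)
    write_calls_tsv(callset, os.path.join(out, "calls.tsv"))
    write_calls_bed(callset, band_table, os.path.join(out, "calls.bed"))

    somatic = None
    if germline_sam is not None:
        g_stats = compute_library_stats(germline_sam, cfg.stats_sample_size, seed=cfg.seed)
        g_candidates = extract_candidates(germline_sam)
        g_scores, _ = score_references(g_candidates, refs, stats=g_stats, cfg=cfg, aln_dir=None)
        g_callset = call_regions(g_scores, k=cfg.k_clusters, band_pairs=band_pairs)
        somatic = subtract_germline(callset, g_callset)
        write_calls_tsv(somatic, os.path.join(out, "somatic_calls.tsv"))

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "selection_mode": cfg.selection_mode,
        "n_regions": len(refs),
        "n_candidates": len(candidates),
        "k_clusters": cfg.k_clusters,
        "noise_cutoff": cfg.noise_cutoff,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(os.path.join(out, "run_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    return PipelineResult(
        scores=scores,
        unscorable=unscorable,
        callset=callset,
        stats=stats,
        band_pairs=band_pairs,
        references=refs,
        somatic=somatic,
    )


def _write_scores(scores, unscorable, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\temr1\temr2\twmax\tnb\ttx\tpass\tn_reads\n")
        for s in scores:
            fh.write(
                f"{s.region}\t{s.emr1:.6f}\t{s.emr2:.6f}\t{s.wmax}\t{s.nb}\t"
                f"{s.tx:.6f}\t{int(s.passed)}\t{s.n_reads}\n"
            )
        for name in unscorable:
            fh.write(f"{name}\tNA\tNA\tNA\tNA\tNA\t0\t0\n")
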
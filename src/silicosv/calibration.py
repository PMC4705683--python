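"""Simulation-based validation: detection rate and false positive rate.

Each simulated dataset plants one reciprocal inter-chromosomal
translocation in a synthetic genome, emulates the aligned sample, and runs
the full pipeline over every inter-chromosomal band pair: one region models
the planted breakpoint, all others are decoys.  Pooled over datasets, the
fraction of decoy regions landing in the top Tx cluster estimates the
method's false positive rate, and the count of datasets whose planted
region reaches the top cluster measures detection.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass

from .pipeline import PipelineConfig, run_pipeline
from .simdata import (
    SimulationConfig,
    apply_translocation,
    emulate_primary_alignment,
    make_genome,
    random_translocation,
    simulate_read_pairs,
)

logger = logging.getLogger(__name__)


@dataclass
class DatasetResult:
    seed: int
    true_region: str | None       # region name of the planted band pair
    true_in_top: bool
    n_decoys: int
    decoys_in_top: int
    n_regions_scored: int

    @property
    def dataset_fpr(self) -> float:
        return self.decoys_in_top / self.n_decoys if self.n_decoys else 0.0


@dataclass
class CalibrationResult:
    datasets: list[DatasetResult]

    @property
    def pooled_fpr(self) -> float:
        """Decoys in top cluster / total decoys, pooled over datasets."""
        decoys = sum(d.n_decoys for d in self.datasets)
        hits = sum(d.decoys_in_top for d in self.datasets)
        return hits / decoys if decoys else 0.0

    @property
    def n_detected(self) -> int:
        """Datasets whose planted region reached the top cluster."""
        return sum(d.true_in_top for d in self.datasets)

    @property
    def total_decoys(self) -> int:
        return sum(d.n_decoys for d in self.datasets)


def run_simulated_dataset(
    seed: int,
    sim_cfg: SimulationConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
    work_dir: str | None = None,
) -> DatasetResult:
    """Simulate one dataset and run the full pipeline on it."""
    import numpy as np

    sim_cfg = sim_cfg or SimulationConfig()
    sim_cfg = SimulationConfig(**{**sim_cfg.__dict__, "seed": seed})
    genome, table = make_genome(sim_cfg)
    rng = np.random.default_rng([seed, 0x7A])
    spec = random_translocation(genome, table, sim_cfg, rng)
    sample = apply_translocation(genome, table, spec, margin=1)
    readset = simulate_read_pairs(sample, sim_cfg)

    def _run(tmp: str) -> DatasetResult:
        sam_path = f"{tmp}/sample.sam"
        emulate_primary_alignment(readset, sam_path)
        cfg = pipe_cfg or PipelineConfig(persist_alignments=False)
        cfg = PipelineConfig(**{**cfg.__dict__, "out_dir": f"{tmp}/run", "seed": seed})
        result = run_pipeline(genome, table, sam_path, cfg)
        true_pair = spec.band_pair
        true_region = next(
            (name for name, bp in result.band_pairs.items() if bp == true_pair), None
        )
        top = {r.region for r in result.callset.top()}
        decoys = [r for r in result.callset.records if r.region != true_region]
        # unscorable regions count as decoys that were never called
        n_decoys = len(result.band_pairs) - 1
        return DatasetResult(
            seed=seed,
            true_region=true_region,
            true_in_top=true_region in top,
            n_decoys=n_decoys,
            decoys_in_top=sum(r.top_cluster for r in decoys),
            n_regions_scored=len(result.scores),
        )

    if work_dir is not None:
        return _run(work_dir)
    with tempfile.TemporaryDirectory(prefix="silicosv-sim-") as tmp:
        return _run(tmp)


def run_calibration(
    seed: int,
    n_datasets: int = 20,
    sim_cfg: SimulationConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
) -> CalibrationResult:
    """Run ``n_datasets`` independently seeded simulated datasets."""
    datasets = []
    for i in range(n_datasets):
        ds_seed = (seed * 1000 + i) % (2**31)
        result = run_simulated_dataset(ds_seed, sim_cfg=sim_cfg, pipe_cfg=pipe_cfg)
        logger.info(
            "dataset %d/%d (seed %d): detected=%s FPR=%.3f",
            i + 1, n_datasets, ds_seed, result.true_in_top, result.dataset_fpr,
        )
        datasets.append(result)
    return CalibrationResult(datasets=datasets)
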
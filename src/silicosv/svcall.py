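"""Region calling from Tx scores: quartile-seeded k-means and germline subtraction.

Tx scores across model regions form a one-tailed distribution in which true
breakpoint regions sit in the upper tail.  A one-dimensional k-means with
k = 4 centroids, seeded at the first, second and third quartiles and the
maximum of the scores, isolates that tail deterministically; the cluster
with the highest mean Tx is taken as the call set.  On labelled simulations
the false positive rate is the fraction of decoy regions landing in that
top cluster.  For tumor/normal pairs, tumor calls whose band pair also
appears in the germline top cluster are removed, leaving somatic candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .svscore import RegionScore

__all__ = ["CallRecord", "CallSet", "kmeans_1d", "call_regions", "compute_fpr", "subtract_germline"]

logger = logging.getLogger(__name__)

DEFAULT_K = 4


@dataclass
class CallRecord:
    region: str
    band_pair: frozenset[str] | None
    tx: float
    cluster: int          # -1 when the region was not clustered
    top_cluster: bool
    somatic: bool = True


@dataclass
class CallSet:
    records: list[CallRecord]
    centroids: np.ndarray = field(default_factory=lambda: np.empty(0))
    clustered: bool = True

    def top(self) -> list[CallRecord]:
        return [r for r in self.records if r.top_cluster]

    def somatic_calls(self) -> list[CallRecord]:
        return [r for r in self.records if r.top_cluster and r.somatic]

    def top_band_pairs(self) -> set[frozenset[str]]:
        return {r.band_pair for r in self.top() if r.band_pair is not None}


def kmeans_1d(values: np.ndarray, k: int, max_iter: int = 200) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 1-D Lloyd's k-means with quartile seeding.

    Centroids start at the k-quantile points of the data; for k = 4 these
    are Q1, Q2, Q3 and the maximum.  Assignment ties go to the lower-index
    centroid; empty clusters keep their centroid.  Returns (assignments,
    centroids sorted ascending).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < k:
        raise ValueError(f"need >= {k} values for {k}-means")
    quantiles = np.arange(1, k + 1) / k
    centroids = np.quantile(values, quantiles)
    assign = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        dist = np.abs(values[:, None] - centroids[None, :])
        new_assign = np.argmin(dist, axis=1)  # argmin takes the lowest index on ties
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for c in range(k):
            members = values[assign == c]
            if len(members):
                centroids[c] = members.mean()
        centroids = np.sort(centroids)
    return assign, centroids


def call_regions(
    scores: list[RegionScore],
    k: int = DEFAULT_K,
    band_pairs: dict[str, frozenset[str]] | None = None,
) -> CallSet:
    """Cluster passing regions on Tx and return the top cluster as calls.

    Regions failing the noise cutoff never enter clustering.  With fewer
    than 2 passing regions (or all scores identical) no clustering is
    performed and no region is called.  With between 2 and k passing
    regions, k falls back to the number of distinct scores.
    """
    band_pairs = band_pairs or {}
    passing = [s for s in scores if s.passed]
    failed = [s for s in scores if not s.passed]

    def record(s: RegionScore, cluster: int, top: bool) -> CallRecord:
        return CallRecord(
            region=s.region,
            band_pair=band_pairs.get(s.region),
            tx=s.tx,
            cluster=cluster,
            top_cluster=top,
        )

    tx = np.array([s.tx for s in passing])
    n_distinct = len(np.unique(tx))
    if len(passing) < 2 or n_distinct < 2:
        if len(passing) >= 2:
            logger.warning("all passing regions share one Tx value; no calls made")
        records = [record(s, -1, False) for s in passing + failed]
        return CallSet(records=records, clustered=False)

    k_eff = min(k, n_distinct)
    assign, centroids = kmeans_1d(tx, k_eff)
    cluster_means = np.array(
        [tx[assign == c].mean() if (assign == c).any() else -np.inf for c in range(k_eff)]
    )
    top_cluster = int(np.argmax(cluster_means))
    records = [
        record(s, int(c), bool(c == top_cluster)) for s, c in zip(passing, assign)
    ] + [record(s, -1, False) for s in failed]
    return CallSet(records=records, centroids=centroids, clustered=True)


def compute_fpr(callset: CallSet, truth: dict[str, bool]) -> float:
    """Fraction of decoy regions assigned to the top cluster.

    ``truth`` maps region name -> True for a genuine variant region, False
    for a decoy.  Every scored region must be labelled.
    """
    for rec in callset.records:
        if rec.region not in truth:
            raise ValueError(f"region {rec.region!r} missing from truth labels")
    decoys = [r for r in callset.records if not truth[r.region]]
    if not decoys:
        raise ValueError("no decoy regions: FPR undefined")
    return sum(r.top_cluster for r in decoys) / len(decoys)


def subtract_germline(tumor: CallSet, germline: CallSet) -> CallSet:
    """Mark tumor top-cluster regions also in the germline top cluster as non-somatic.

    Matching is by unordered band pair identity, the region granularity of
    the method.
    """
    germline_pairs = germline.top_band_pairs()
    records = []
    for rec in tumor.records:
        somatic = not (
            rec.top_cluster
            and rec.band_pair is not None
            and rec.band_pair in germline_pairs
        )
        records.append(
            CallRecord(
                region=rec.region,
                band_pair=rec.band_pair,
                tx=rec.tx,
                cluster=rec.cluster,
                top_cluster=rec.top_cluster,
                somatic=somatic,
            )
        )
    return CallSet(records=records, centroids=tumor.centroids, clustered=tumor.clustered)


def write_calls_tsv(callset: CallSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tband_a\tband_b\ttx\tcluster\ttop_cluster\tsomatic\n")
        for r in callset.records:
            a, b = (sorted(r.band_pair) if r.band_pair else (".", "."))
            fh.write(
                f"{r.region}\t{a}\t{b}\t{r.tx:.6f}\t{r.cluster}\t"
                f"{int(r.top_cluster)}\t{int(r.somatic)}\n"
            )


def write_calls_bed(callset: CallSet, band_table, path) -> None:
    """BED (0-based half-open) of the two band intervals per called region."""
    with open(path, "w") as fh:
        for r in callset.top():
            if r.band_pair is None:
                continue
            for label in sorted(r.band_pair):
                band = band_table[label]
                fh.write(f"{band.chrom}\t{band.start - 1}\t{band.end}\t{r.region}\n")
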
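"""24-nt siRNA locus construction and TE labeling.

Overlapping 24-bp read placements form candidate clusters; clusters below
the minimum read coverage (10 by default) are dropped, and surviving
clusters whose edge gap is within the merge window (150 bp) are merged
transitively into loci.  A TE is siRNA+ iff >=1 bp of it overlaps a locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .core import GenomicInterval
from .landscape import TEAnnotation

__all__ = ["SirnaCluster", "SirnaLocus", "call_clusters", "merge_loci", "label_tes"]

logger = logging.getLogger(__name__)

READ_LENGTH = 24


@dataclass
class SirnaCluster:
    interval: GenomicInterval
    read_count: int


@dataclass
class SirnaLocus:
    interval: GenomicInterval
    member_clusters: list[SirnaCluster] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.member_clusters)


def call_clusters(
    read_intervals: list[GenomicInterval],
    min_reads: int = 10,
    read_length: int = READ_LENGTH,
) -> list[SirnaCluster]:
    """Connected components of overlapping reads with >= min_reads members.

    Reads whose length differs from 24 bp are filtered out with a logged
    count before clustering.
    """
    reads = [r for r in read_intervals if len(r) == read_length]
    skipped = len(read_intervals) - len(reads)
    if skipped:
        logger.info("call_clusters: skipped %d non-%d-nt reads", skipped, read_length)
    clusters: list[SirnaCluster] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        chrom_reads = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end, cur_n = None, None, 0
        for r in chrom_reads:
            if cur_start is None or r.start >= cur_end:
                if cur_start is not None and cur_n >= min_reads:
                    clusters.append(
                        SirnaCluster(GenomicInterval(chrom, cur_start, cur_end), cur_n)
                    )
                cur_start, cur_end, cur_n = r.start, r.end, 1
            else:
                cur_end = max(cur_end, r.end)
                cur_n += 1
        if cur_start is not None and cur_n >= min_reads:
            clusters.append(
                SirnaCluster(GenomicInterval(chrom, cur_start, cur_end), cur_n)
            )
    return clusters


def merge_loci(
    clusters: list[SirnaCluster],
    merge_bp: int = 150,
    mode: str = "edge",
) -> list[SirnaLocus]:
    """Merge clusters within ``merge_bp`` of each other into loci.

    ``mode='edge'`` (default) measures the end-to-start gap, boundary
    inclusive: a 150-bp gap merges, 151 does not.  ``mode='center'``
    measures center-to-center distance instead.  Merging is transitive and
    idempotent; output loci are sorted and pairwise separated by more than
    the rule allows.
    """
    if mode not in ("edge", "center"):
        raise ValueError("mode must be 'edge' or 'center'")
    loci: list[SirnaLocus] = []
    by_chrom: dict[str, list[SirnaCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chrom_clusters = sorted(by_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end))
        current: list[SirnaCluster] = []
        cur_end = -1
        for cluster in chrom_clusters:
            if current:
                if mode == "edge":
                    gap = max(0, cluster.interval.start - cur_end)
                    near = gap <= merge_bp
                else:
                    prev = current[-1].interval
                    c1 = (prev.start + prev.end) / 2
                    c2 = (cluster.interval.start + cluster.interval.end) / 2
                    near = abs(c2 - c1) <= merge_bp
                if near:
                    current.append(cluster)
                    cur_end = max(cur_end, cluster.interval.end)
                    continue
                loci.append(_finish_locus(chrom, current))
                current = []
            current.append(cluster)
            cur_end = cluster.interval.end
        if current:
            loci.append(_finish_locus(chrom, current))
    return loci


def _finish_locus(chrom: str, members: list[SirnaCluster]) -> SirnaLocus:
    start = min(c.interval.start for c in members)
    end = max(c.interval.end for c in members)
    return SirnaLocus(GenomicInterval(chrom, start, end), list(members))


def label_tes(
    tes: list[TEAnnotation],
    loci: list[SirnaLocus],
) -> pd.DataFrame:
    """siRNA+/- flag per TE: + iff >=1 bp overlap with >=1 locus."""
    locus_ivs = [l.interval for l in loci]
    rows = []
    for te in tes:
        plus = any(te.interval.overlaps(iv) for iv in locus_ivs)
        rows.append(
            {"te_id": te.te_id, "sirna_label": "siRNA+" if plus else "siRNA-"}
        )
    return pd.DataFrame(rows)
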
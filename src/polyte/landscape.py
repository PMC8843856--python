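"""TE genic-landscape classification and density profiling.

Categories follow a coding-most-wins precedence: CDS > 5'UTR > 3'UTR >
intron > 2-kb promoter > 2-kb downstream > intergenic, with >=1-bp overlap
deciding membership.  Distances are measured from the TE's nearest edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GENIC_CATEGORIES, SUPERFAMILIES, GenomicInterval

__all__ = [
    "GeneModel",
    "TEAnnotation",
    "classify_genic_region",
    "classify_all",
    "flank_bin_profile",
    "window_density",
    "nearest_gene_distance",
    "merge_intervals",
]


@dataclass
class TEAnnotation:
    te_id: str
    interval: GenomicInterval
    superfamily: str = "other"

    def __post_init__(self) -> None:
        if self.superfamily not in SUPERFAMILIES:
            raise ValueError(
                f"superfamily {self.superfamily!r} not in {SUPERFAMILIES}"
            )


@dataclass
class GeneModel:
    """A gene with exon/CDS structure; UTRs and introns are derived.

    5'UTR = exonic minus CDS on the TSS side of the CDS span, 3'UTR on the
    other side; introns are the transcribed span minus exons.
    """

    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[GenomicInterval] = field(default_factory=list)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tes_pos(self) -> int:
        """Transcript end (opposite of TSS)."""
        return self.interval.end - 1 if self.strand != "-" else self.interval.start

    def start_codon(self) -> int:
        """Position of the translation start (falls back to the TSS)."""
        if not self.cds:
            return self.tss
        if self.strand != "-":
            return min(c.start for c in self.cds)
        return max(c.end for c in self.cds) - 1

    def stop_codon(self) -> int:
        if not self.cds:
            return self.tes_pos
        if self.strand != "-":
            return max(c.end for c in self.cds) - 1
        return min(c.start for c in self.cds)

    def _exon_pieces(self) -> list[tuple[int, int]]:
        return merge_intervals([(e.start, e.end) for e in self.exons]) or [
            (self.interval.start, self.interval.end)
        ]

    def utr_pieces(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) pieces as (start, end) tuples."""
        if not self.cds:
            return [], []
        cds_lo = min(c.start for c in self.cds)
        cds_hi = max(c.end for c in self.cds)
        utr = _subtract(self._exon_pieces(), merge_intervals([(c.start, c.end) for c in self.cds]))
        low_side = [p for p in utr if p[1] <= cds_lo]
        high_side = [p for p in utr if p[0] >= cds_hi]
        if self.strand != "-":
            return low_side, high_side
        return high_side, low_side

    def intron_pieces(self) -> list[tuple[int, int]]:
        return _subtract([(self.interval.start, self.interval.end)], self._exon_pieces())

    def cds_pieces(self) -> list[tuple[int, int]]:
        return merge_intervals([(c.start, c.end) for c in self.cds])

    def promoter(self, flank_bp: int = 2000, anchor: str = "tss") -> tuple[int, int]:
        """2-kb strand-aware upstream flank, anchored at the TSS by default
        (``anchor='start_codon'`` selects the translation start instead)."""
        pos = self.tss if anchor == "tss" else self.start_codon()
        if self.strand != "-":
            return max(0, pos - flank_bp), pos
        return pos + 1, pos + 1 + flank_bp

    def downstream(self, flank_bp: int = 2000) -> tuple[int, int]:
        if self.strand != "-":
            return self.interval.end, self.interval.end + flank_bp
        return max(0, self.interval.start - flank_bp), self.interval.start


def merge_intervals(pieces: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting (start, end) pieces to a minimal cover."""
    pieces = sorted((s, e) for s, e in pieces if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in pieces:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _subtract(cover: list[tuple[int, int]], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cover = merge_intervals(cover)
    minus = merge_intervals(minus)
    out: list[tuple[int, int]] = []
    for s, e in cover:
        cur = s
        for ms, me in minus:
            if me <= cur or ms >= e:
                continue
            if ms > cur:
                out.append((cur, ms))
            cur = max(cur, me)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def _overlaps_any(te: GenomicInterval, pieces: list[tuple[int, int]]) -> bool:
    return any(te.start < e and s < te.end for s, e in pieces)


def _gene_category(te: GenomicInterval, gene: GeneModel, flank_bp: int, anchor: str) -> str | None:
    """Category of a TE with respect to one gene, or None if out of reach."""
    five, three = gene.utr_pieces()
    if _overlaps_any(te, gene.cds_pieces()):
        return "CDS"
    if _overlaps_any(te, five):
        return "5UTR"
    if _overlaps_any(te, three):
        return "3UTR"
    if _overlaps_any(te, gene.intron_pieces()):
        return "intron"
    if te.overlaps(gene.interval):
        # inside the transcribed span but neither CDS/UTR/intron (e.g. a
        # non-coding exon with no CDS annotated): treat as intronic span
        return "intron"
    if _overlaps_any(te, [gene.promoter(flank_bp, anchor)]):
        return "promoter2kb"
    if _overlaps_any(te, [gene.downstream(flank_bp)]):
        return "downstream2kb"
    return None


def classify_genic_region(
    te: TEAnnotation,
    genes: list[GeneModel],
    flank_bp: int = 2000,
    promoter_anchor: str = "tss",
) -> str:
    """Single genic category for a TE; intergenic is the fall-through.

    A TE overlapping several genes goes to the gene with the larger
    body overlap (ties to the smaller gene start); TEs only reachable via
    flanks prefer promoter over downstream, then smaller gene start.
    """
    iv = te.interval
    body_hits: list[tuple[int, int, GeneModel]] = []
    flank_hits: list[tuple[int, int, GeneModel]] = []
    for gene in genes:
        if gene.interval.chrom != iv.chrom:
            continue
        ov = iv.overlap_bp(gene.interval)
        if ov > 0:
            body_hits.append((-ov, gene.interval.start, gene))
        elif _gene_category(iv, gene, flank_bp, promoter_anchor) is not None:
            flank_hits.append((0, gene.interval.start, gene))
    if body_hits:
        body_hits.sort(key=lambda t: (t[0], t[1]))
        cat = _gene_category(iv, body_hits[0][2], flank_bp, promoter_anchor)
        return cat or "intergenic"
    if flank_hits:
        cats = []
        for _, start, gene in sorted(flank_hits, key=lambda t: t[1]):
            cat = _gene_category(iv, gene, flank_bp, promoter_anchor)
            cats.append((GENIC_CATEGORIES.index(cat), start, cat))
        cats.sort()
        return cats[0][2]
    return "intergenic"


def classify_all(
    tes: list[TEAnnotation],
    genes: list[GeneModel],
    flank_bp: int = 2000,
    promoter_anchor: str = "tss",
) -> pd.DataFrame:
    rows = [
        {
            "te_id": te.te_id,
            "chrom": te.interval.chrom,
            "start": te.interval.start,
            "end": te.interval.end,
            "superfamily": te.superfamily,
            "genic_category": classify_genic_region(te, genes, flank_bp, promoter_anchor),
        }
        for te in tes
    ]
    return pd.DataFrame(rows)


def nearest_gene_distance(
    te: GenomicInterval | TEAnnotation,
    genes: list[GeneModel],
) -> tuple[float, str | None]:
    """Signed bp distance to the nearest gene and its id.

    0 if the TE overlaps the gene body; otherwise the gap to the nearer of
    start/stop codon, negative upstream / positive downstream of the gene
    (strand-aware).  (NaN, None) when no gene shares the chromosome.
    """
    iv = te.interval if isinstance(te, TEAnnotation) else te
    best: tuple[int, int, float, str] | None = None
    for gene in genes:
        if gene.interval.chrom != iv.chrom:
            continue
        if iv.overlaps(gene.interval):
            key = (0, gene.interval.start, 0.0, gene.gene_id)
        else:
            gap = iv.gap_to(gene.interval)
            before_gene = iv.end <= gene.interval.start
            upstream = before_gene if gene.strand != "-" else not before_gene
            signed = -float(gap) if upstream else float(gap)
            key = (gap, gene.interval.start, signed, gene.gene_id)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is None:
        return math.nan, None
    return best[2], best[3]


def flank_bin_profile(
    tes: list[TEAnnotation],
    genes: list[GeneModel],
    bin_bp: int = 100,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Counts of TEs per signed distance bin around gene start/stop codons.

    Each TE is assigned to its nearest gene; TEs upstream of the start
    codon (strand-aware) within ``flank_bp`` count in negative bins keyed
    by the distance from the TE's nearest edge to the start codon, and TEs
    downstream of the stop codon in positive bins.  The outer boundary is
    half-open: a TE exactly ``flank_bp`` away is excluded.
    """
    if flank_bp % bin_bp != 0:
        raise ValueError("bin_bp must divide flank_bp")
    n_bins = flank_bp // bin_bp
    upstream = np.zeros(n_bins, dtype=np.int64)
    downstream = np.zeros(n_bins, dtype=np.int64)
    by_id = {g.gene_id: g for g in genes}
    for te in tes:
        signed, gene_id = nearest_gene_distance(te, genes)
        if gene_id is None or not np.isfinite(signed) or signed == 0:
            continue
        gene = by_id[gene_id]
        iv = te.interval
        if signed < 0:
            # upstream: distance from TE's nearest edge to the start codon
            codon = gene.start_codon()
            d = (codon - iv.end + 1) if gene.strand != "-" else (iv.start - codon)
            if 0 <= d < flank_bp:
                upstream[d // bin_bp] += 1
        else:
            codon = gene.stop_codon()
            d = (iv.start - codon) if gene.strand != "-" else (codon - iv.end + 1)
            if 0 <= d < flank_bp:
                downstream[d // bin_bp] += 1
    rows = []
    for b in range(n_bins - 1, -1, -1):
        rows.append(
            {"side": "upstream", "bin_lo": b * bin_bp, "bin_hi": (b + 1) * bin_bp, "count": int(upstream[b])}
        )
    for b in range(n_bins):
        rows.append(
            {"side": "downstream", "bin_lo": b * bin_bp, "bin_hi": (b + 1) * bin_bp, "count": int(downstream[b])}
        )
    return pd.DataFrame(rows)


def window_density(
    features: list[GenomicInterval],
    window_bp: int = 100_000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Fraction of each tiling window covered by >=1 feature.

    Features are merged to a non-overlapping cover first, so overlapping
    bp count once.  Windows tile each chromosome from 0 to ``chrom_sizes``
    (default: the last covered bp rounded up to a whole window).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    rows = []
    for chrom in sorted(by_chrom):
        cover = merge_intervals(by_chrom[chrom])
        end = (chrom_sizes or {}).get(chrom, cover[-1][1] if cover else 0)
        n_windows = max(1, math.ceil(end / window_bp))
        covered = np.zeros(n_windows)
        for s, e in cover:
            w0 = s // window_bp
            w1 = (e - 1) // window_bp
            for w in range(w0, min(w1, n_windows - 1) + 1):
                lo = w * window_bp
                hi = lo + window_bp
                covered[w] += max(0, min(e, hi) - max(s, lo))
        for w in range(n_windows):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window_bp,
                    "end": (w + 1) * window_bp,
                    "density": covered[w] / window_bp,
                }
            )
    return pd.DataFrame(rows)
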
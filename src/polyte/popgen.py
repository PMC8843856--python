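"""Windowed population-genetic statistics.

Diversity estimators are computed from per-site allele counts: for a site
with ``c`` derived alleles out of ``m`` observed, the per-site mean pairwise
difference is ``2 c (m - c) / (m (m - 1))`` and summing over sites gives the
average number of pairwise differences pi.  Tajima's D normalises
``pi - theta_W`` with the standard constants; the Hudson-type Fst is a
ratio of averages ``(H_b - H_w) / H_b``.  The reduction-of-diversity
statistic is ``ROD = 1 - pi_target / pi_ref``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    GenotypePanel,
    PolyteError,
    PopulationAssignment,
    SiteCounts,
)

__all__ = [
    "HaplotypeBlock",
    "TajimaConstants",
    "WindowStats",
    "PairwiseStats",
    "pairwise_pi",
    "pi_from_counts",
    "watterson_theta",
    "tajima_constants",
    "tajimas_d",
    "tajimas_d_from_counts",
    "pairwise_fst",
    "fst_from_counts",
    "rod",
    "windowed_scan",
]


@dataclass
class HaplotypeBlock:
    """Binary haplotype matrix (n haplotypes x S segregating sites) for one window.

    Monomorphic columns are pruned at construction (so S equals the
    segregating-site count) unless ``prune=False``; cross-population
    statistics need unpruned blocks because a within-population-fixed site
    may still carry a between-population difference.
    """

    positions: np.ndarray
    matrix: np.ndarray
    window: GenomicInterval
    prune: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.matrix.shape[1] != len(self.positions):
            raise ValueError("positions length must match matrix columns")
        n = self.matrix.shape[0]
        colsum = self.matrix.sum(axis=0)
        keep = (colsum > 0) & (colsum < n)
        if self.prune and not keep.all():
            self.matrix = self.matrix[:, keep]
            self.positions = self.positions[keep]
        order = np.argsort(self.positions, kind="stable")
        if np.any(np.diff(self.positions) < 0):
            self.positions = self.positions[order]
            self.matrix = self.matrix[:, order]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def S(self) -> int:
        return self.matrix.shape[1]

    def site_counts(self) -> SiteCounts:
        return SiteCounts(
            self.positions.copy(),
            self.matrix.sum(axis=0).astype(np.int64),
            np.full(self.S, self.n, dtype=np.int64),
        )


@dataclass(frozen=True)
class TajimaConstants:
    """Sample-size constants of the D statistic."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise PolyteError("Tajima constants require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def _per_site_pi(counts: SiteCounts) -> np.ndarray:
    c = counts.derived.astype(np.float64)
    m = counts.total.astype(np.float64)
    out = np.zeros(len(counts), dtype=np.float64)
    ok = m >= 2
    out[ok] = 2.0 * c[ok] * (m[ok] - c[ok]) / (m[ok] * (m[ok] - 1.0))
    return out


def pi_from_counts(counts: SiteCounts, length_bp: int | None = None) -> tuple[float, float | None]:
    """Mean pairwise differences (summed over sites), optionally per bp."""
    pi_raw = float(_per_site_pi(counts).sum())
    pi_bp = pi_raw / length_bp if length_bp else None
    return pi_raw, pi_bp


def pairwise_pi(block: HaplotypeBlock) -> tuple[float, float]:
    """pi over a haplotype block: raw and per-bp of the block's window."""
    if block.n < 2:
        raise PolyteError("pairwise pi requires n >= 2 haplotypes")
    pi_raw, pi_bp = pi_from_counts(block.site_counts(), len(block.window))
    return pi_raw, float(pi_bp)


def watterson_theta(S: int, n: int) -> float:
    if n < 2:
        raise PolyteError("Watterson's theta requires n >= 2")
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return 0.0
    return S / tajima_constants(n).a1


def tajimas_d_from_counts(pi_raw: float, S: int, n: int) -> float:
    """D from summary statistics; NaN when undefined (S = 0 or n < 4)."""
    if S == 0 or n < 4:
        return math.nan
    const = tajima_constants(n)
    theta_w = S / const.a1
    var = const.e1 * S + const.e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_raw - theta_w) / math.sqrt(var)


def tajimas_d(block: HaplotypeBlock) -> float:
    pi_raw, _ = pairwise_pi(block)
    return tajimas_d_from_counts(pi_raw, block.S, block.n)


def _hudson_components(a: SiteCounts, b: SiteCounts) -> tuple[float, float]:
    if len(a) != len(b) or np.any(a.positions != b.positions):
        raise PolyteError("Fst requires identical site positions in both populations")
    ca, ma = a.derived.astype(float), a.total.astype(float)
    cb, mb = b.derived.astype(float), b.total.astype(float)
    ok = (ma >= 2) & (mb >= 2)
    ca, ma, cb, mb = ca[ok], ma[ok], cb[ok], mb[ok]
    pa = ca / ma
    pb = cb / mb
    hw_a = 2.0 * ca * (ma - ca) / (ma * (ma - 1.0))
    hw_b = 2.0 * cb * (mb - cb) / (mb * (mb - 1.0))
    h_within = 0.5 * (hw_a + hw_b)
    h_between = pa * (1.0 - pb) + pb * (1.0 - pa)
    return float(h_between.sum()), float(h_within.sum())


def _wc_components(a: SiteCounts, b: SiteCounts) -> tuple[float, float]:
    """Weir-Cockerham variance components for allele-count data, two demes."""
    if len(a) != len(b) or np.any(a.positions != b.positions):
        raise PolyteError("Fst requires identical site positions in both populations")
    na, nb = a.total.astype(float), b.total.astype(float)
    ok = (na >= 2) & (nb >= 2)
    na, nb = na[ok], nb[ok]
    pa = a.derived.astype(float)[ok] / na
    pb = b.derived.astype(float)[ok] / nb
    n_tot = na + nb
    pbar = (na * pa + nb * pb) / n_tot
    nc = (n_tot - (na**2 + nb**2) / n_tot)  # r - 1 = 1
    msp = na * (pa - pbar) ** 2 + nb * (pb - pbar) ** 2
    msg = (na * pa * (1 - pa) + nb * pb * (1 - pb)) / (n_tot - 2.0)
    num = msp - msg
    den = msp + (nc - 1.0) * msg
    return float(num.sum()), float(den.sum())


def fst_from_counts(a: SiteCounts, b: SiteCounts, estimator: str = "hudson") -> float:
    """Pairwise Fst; NaN when there is no between-population variation."""
    if estimator == "hudson":
        h_between, h_within = _hudson_components(a, b)
        if h_between == 0:
            return math.nan
        return (h_between - h_within) / h_between
    if estimator == "wc":
        num, den = _wc_components(a, b)
        if den == 0:
            return math.nan
        return num / den
    raise ValueError(f"unknown Fst estimator {estimator!r}")


def pairwise_fst(
    block_a: HaplotypeBlock, block_b: HaplotypeBlock, estimator: str = "hudson"
) -> float:
    if block_a.n < 2 or block_b.n < 2:
        raise PolyteError("Fst requires n >= 2 in each population")
    # Blocks prune monomorphic columns independently; re-align on the union
    # of positions with zero-derived fill so both populations cover it.
    pos = np.union1d(block_a.positions, block_b.positions)

    def lift(block: HaplotypeBlock) -> SiteCounts:
        derived = np.zeros(len(pos), dtype=np.int64)
        idx = np.searchsorted(pos, block.positions)
        derived[idx] = block.matrix.sum(axis=0)
        return SiteCounts(pos, derived, np.full(len(pos), block.n, dtype=np.int64))

    return fst_from_counts(lift(block_a), lift(block_b), estimator=estimator)


def rod(pi_target: float, pi_ref: float) -> float:
    """Reduction of diversity, ``1 - pi_target / pi_ref``; NaN if pi_ref = 0."""
    if pi_target < 0 or pi_ref < 0:
        raise ValueError("pi values must be >= 0")
    if pi_ref == 0:
        return math.nan
    return 1.0 - pi_target / pi_ref


@dataclass
class WindowStats:
    window: GenomicInterval
    population: str
    n_sites: int
    pi_raw: float
    pi_bp: float
    theta_w: float
    tajima_d: float


@dataclass
class PairwiseStats:
    window: GenomicInterval
    pop_pair: tuple[str, str]
    fst: float
    pi_target: float
    pi_ref: float
    log_pi_ratio: float
    rod: float


def log_pi_ratio(pi_target: float, pi_ref: float) -> float:
    if pi_target <= 0 or pi_ref <= 0:
        return math.nan
    return math.log(pi_ref / pi_target)


def _tile_windows(span_end: int, window_bp: int, step_bp: int) -> list[tuple[int, int]]:
    if window_bp < step_bp:
        raise PolyteError("window_bp must be >= step_bp")
    windows = []
    start = 0
    while start < span_end:
        windows.append((start, start + window_bp))
        start += step_bp
    return windows


def windowed_scan(
    panel: GenotypePanel,
    populations: PopulationAssignment,
    window_bp: int = 5000,
    step_bp: int = 5000,
    maf_min: float = 0.05,
    fst_estimator: str = "hudson",
    span_end: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed per-population and per-pair statistics over a SNP panel.

    Windows tile the chromosome from coordinate 0.  Sites failing the MAF
    floor (computed over the full panel) are excluded.  Windows with no
    retained sites are emitted with NaN statistics.
    """
    if panel.n_sites == 0:
        raise PolyteError("empty genotype panel")
    populations.require_pairs()
    pop_labels = populations.populations
    counts_by_pop = {
        pop: panel.subset_samples(populations.members(pop)).site_counts()
        for pop in pop_labels
    }
    maf_keep = panel.site_counts().maf_mask(maf_min)
    counts_by_pop = {
        pop: SiteCounts(c.positions[maf_keep], c.derived[maf_keep], c.total[maf_keep])
        for pop, c in counts_by_pop.items()
    }
    end = span_end if span_end is not None else int(panel.positions.max()) + 1
    window_rows = []
    pair_rows = []
    pairs = [
        (pop_labels[i], pop_labels[j])
        for i in range(len(pop_labels))
        for j in range(i + 1, len(pop_labels))
    ]
    for wstart, wend in _tile_windows(end, window_bp, step_bp):
        window = GenomicInterval(panel.chrom, wstart, wend)
        local = {pop: c.in_range(wstart, wend) for pop, c in counts_by_pop.items()}
        per_pop: dict[str, tuple[float, float]] = {}
        for pop, counts in local.items():
            if len(counts) == 0:
                # no retained sites: row present, statistics undefined
                per_pop[pop] = (math.nan, math.nan)
                window_rows.append(
                    WindowStats(window, pop, 0, math.nan, math.nan, math.nan, math.nan)
                )
                continue
            seg = counts.segregating_mask()
            S = int(seg.sum())
            pi_raw, pi_bp = pi_from_counts(counts, window_bp)
            n_alleles = int(counts.total.max())
            d = tajimas_d_from_counts(pi_raw, S, n_alleles) if S else math.nan
            per_pop[pop] = (pi_raw, float(pi_bp))
            window_rows.append(
                WindowStats(window, pop, S, pi_raw, float(pi_bp), watterson_theta(S, max(n_alleles, 2)), d)
            )
        for target, ref in pairs:
            pi_t = per_pop[target][1]
            pi_r = per_pop[ref][1]
            fst = (
                fst_from_counts(local[target], local[ref], estimator=fst_estimator)
                if len(local[target])
                else math.nan
            )
            pair_rows.append(
                PairwiseStats(
                    window,
                    (target, ref),
                    fst,
                    pi_t,
                    pi_r,
                    log_pi_ratio(pi_t, pi_r),
                    rod(pi_t, pi_r) if pi_r > 0 else math.nan,
                )
            )
    win_df = pd.DataFrame(
        {
            "chrom": [w.window.chrom for w in window_rows],
            "start": [w.window.start for w in window_rows],
            "end": [w.window.end for w in window_rows],
            "population": [w.population for w in window_rows],
            "n_sites": [w.n_sites for w in window_rows],
            "pi_raw": [w.pi_raw for w in window_rows],
            "pi_bp": [w.pi_bp for w in window_rows],
            "theta_w": [w.theta_w for w in window_rows],
            "tajima_d": [w.tajima_d for w in window_rows],
        }
    )
    pair_df = pd.DataFrame(
        {
            "chrom": [p.window.chrom for p in pair_rows],
            "start": [p.window.start for p in pair_rows],
            "end": [p.window.end for p in pair_rows],
            "target_pop": [p.pop_pair[0] for p in pair_rows],
            "ref_pop": [p.pop_pair[1] for p in pair_rows],
            "fst": [p.fst for p in pair_rows],
            "pi_target": [p.pi_target for p in pair_rows],
            "pi_ref": [p.pi_ref for p in pair_rows],
            "log_pi_ratio": [p.log_pi_ratio for p in pair_rows],
            "rod": [p.rod for p in pair_rows],
        }
    )
    return win_df, pair_df
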
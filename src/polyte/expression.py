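"""Gene expression vs. TE proximity: distance binning and contrasts."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PolyteError
from .landscape import GeneModel, TEAnnotation

__all__ = [
    "nearest_te_distance",
    "all_nearest_te_distances",
    "bin_mean_expression",
    "sirna_stratified_contrast",
    "timepoint_contrast",
]

logger = logging.getLogger(__name__)


def nearest_te_distance(
    gene: GeneModel,
    tes: list[TEAnnotation],
) -> tuple[float, str | None]:
    """Distance (bp) from a gene to its nearest TE, with the TE's id.

    0 when a TE overlaps the gene body (so TEs in introns or UTRs map to
    distance zero); otherwise the minimum edge gap over all TEs on the
    chromosome.  (NaN, None) when no TE shares the chromosome.
    """
    body = gene.interval
    best: tuple[int, int, str] | None = None
    for te in tes:
        if te.interval.chrom != body.chrom:
            continue
        gap = 0 if te.interval.overlaps(body) else te.interval.gap_to(body)
        key = (gap, te.interval.start, te.te_id)
        if best is None or key < best:
            best = key
    if best is None:
        return math.nan, None
    return float(best[0]), best[2]


def all_nearest_te_distances(
    genes: list[GeneModel],
    tes: list[TEAnnotation],
) -> pd.DataFrame:
    rows = []
    n_undefined = 0
    for gene in genes:
        d, te_id = nearest_te_distance(gene, tes)
        if te_id is None:
            n_undefined += 1
            continue
        rows.append({"gene_id": gene.gene_id, "distance": d, "te_id": te_id})
    if n_undefined:
        logger.info("nearest_te_distance: %d genes had no TE on their chromosome", n_undefined)
    return pd.DataFrame(rows, columns=["gene_id", "distance", "te_id"])


@dataclass
class DistanceBinSummary:
    bin_lo: int
    bin_hi: float
    n_genes: int
    mean_fpkm: float
    stratum: str = "all"


def _bin_index(distance: float, bin_bp: int, max_bp: int) -> int:
    if distance >= max_bp:
        return max_bp // bin_bp  # terminal open bin
    return int(distance // bin_bp)


def bin_mean_expression(
    distances: pd.DataFrame,
    expression: pd.DataFrame,
    timepoint: str,
    bin_bp: int = 500,
    max_bp: int = 5000,
    stratum: str = "all",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Mean FPKM per TE-distance bin at one timepoint.

    ``distances`` needs gene_id and distance columns.  Genes at distance
    >= max_bp pool into a terminal open bin.  Empty bins are reported with
    n_genes = 0 and NaN mean.
    """
    if timepoint not in expression.columns:
        raise PolyteError(f"timepoint {timepoint!r} not in expression table")
    merged = distances.merge(
        expression[[timepoint]], left_on="gene_id", right_index=True, how="inner"
    )
    values = merged[timepoint].to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    n_bins = max_bp // bin_bp + 1
    idx = np.array(
        [_bin_index(d, bin_bp, max_bp) for d in merged["distance"]], dtype=int
    )
    rows = []
    for b in range(n_bins):
        sel = values[idx == b]
        rows.append(
            {
                "bin_lo": b * bin_bp,
                "bin_hi": (b + 1) * bin_bp if b < n_bins - 1 else math.inf,
                "stratum": stratum,
                "n_genes": int(len(sel)),
                "mean_fpkm": float(sel.mean()) if len(sel) else math.nan,
            }
        )
    return pd.DataFrame(rows)


def sirna_stratified_contrast(
    distances: pd.DataFrame,
    labels: pd.DataFrame,
    expression: pd.DataFrame,
    timepoint: str,
    bin_bp: int = 1000,
    max_bp: int = 5000,
    test: str = "t",
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-bin siRNA+ vs siRNA- comparison of gene FPKM.

    ``labels`` maps te_id -> sirna_label; genes inherit the label of their
    nearest TE.  Each populated bin gets a two-sample location test
    (Student's t by default, ``test='ranksum'`` for Mann-Whitney) and the
    ratio of stratum means.  Bins where a stratum has n < 2 are skipped
    with a flag.
    """
    if test not in ("t", "ranksum"):
        raise ValueError("test must be 't' or 'ranksum'")
    merged = distances.merge(labels, on="te_id", how="left")
    merged = merged.merge(
        expression[[timepoint]], left_on="gene_id", right_index=True, how="inner"
    )
    values = merged[timepoint].to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    idx = np.array(
        [_bin_index(d, bin_bp, max_bp) for d in merged["distance"]], dtype=int
    )
    plus = (merged["sirna_label"] == "siRNA+").to_numpy()
    minus = (merged["sirna_label"] == "siRNA-").to_numpy()
    rows = []
    n_bins = max_bp // bin_bp + 1
    for b in range(n_bins):
        sel = idx == b
        a = values[sel & plus]
        c = values[sel & minus]
        row = {
            "bin_lo": b * bin_bp,
            "bin_hi": (b + 1) * bin_bp if b < n_bins - 1 else math.inf,
            "n_plus": int(len(a)),
            "n_minus": int(len(c)),
            "mean_plus": float(a.mean()) if len(a) else math.nan,
            "mean_minus": float(c.mean()) if len(c) else math.nan,
        }
        if len(a) < 2 or len(c) < 2:
            row.update({"ratio": math.nan, "statistic": math.nan, "p_value": math.nan, "tested": False})
        else:
            ratio = row["mean_plus"] / row["mean_minus"] if row["mean_minus"] else math.nan
            if test == "t":
                res = stats.ttest_ind(a, c, equal_var=False)
            else:
                res = stats.mannwhitneyu(a, c, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            if math.isnan(p) and np.array_equal(np.sort(a), np.sort(c)):
                stat, p = 0.0, 1.0  # identical strata: no evidence of difference
            row.update({"ratio": ratio, "statistic": stat, "p_value": p, "tested": True})
        rows.append(row)
    return pd.DataFrame(rows)


def timepoint_contrast(
    expression: pd.DataFrame,
    t_a: str,
    t_b: str,
    paired: bool = True,
) -> dict:
    """Two-sample (paired by default) t-test between two timepoints."""
    for t in (t_a, t_b):
        if t not in expression.columns:
            raise PolyteError(f"timepoint {t!r} not in expression table")
    table = expression[[t_a, t_b]].dropna()
    if len(table) < len(expression):
        logger.info(
            "timepoint_contrast: intersecting gene sets (%d of %d genes kept)",
            len(table),
            len(expression),
        )
    if len(table) < 2:
        raise PolyteError("timepoint contrast requires >= 2 shared genes")
    a = table[t_a].to_numpy(dtype=float)
    b = table[t_b].to_numpy(dtype=float)
    diff = b - a
    if paired:
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(b, a)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.ttest_ind(b, a, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
    mean_diff = float(diff.mean())
    return {
        "t_a": t_a,
        "t_b": t_b,
        "n": int(len(table)),
        "mean_diff": mean_diff,
        "direction": "increase" if mean_diff > 0 else ("decrease" if mean_diff < 0 else "none"),
        "statistic": stat,
        "p_value": p,
        "paired": paired,
    }
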
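"""Population-level TE insertion-frequency analysis.

Frequencies are complete-case carrier frequencies (NA genotypes excluded
from numerator and denominator).  The purifying-selection signal is tested
per genic category against the intergenic reference with a one-sided
Fisher's exact test on the low-frequency (f <= 0.1) contingency, corrected
across categories by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import PolyteError, PopulationAssignment

__all__ = [
    "TEFrequencyRecord",
    "insertion_frequencies",
    "classify_sharing",
    "low_frequency_bias_test",
    "sfs_and_composition",
    "distance_sharing_correlation",
    "shared_te_count_matrix",
    "benjamini_hochberg",
]

logger = logging.getLogger(__name__)


@dataclass
class TEFrequencyRecord:
    locus_id: str
    freq_overall: float
    freq_by_pop: dict[str, float]
    sharing_class: str = ""


def _carrier_freq(values: np.ndarray) -> float:
    """Complete-case carrier frequency; NaN if every genotype is missing."""
    observed = values >= 0
    if not observed.any():
        return math.nan
    return float(values[observed].sum() / observed.sum())


def insertion_frequencies(
    matrix: pd.DataFrame,
    populations: PopulationAssignment,
) -> pd.DataFrame:
    """Per-locus carrier frequency overall and per population.

    ``matrix`` is accession x locus with values {0, 1} and -1 (or NaN) for
    missing.  All-NA loci are flagged with NaN frequency.
    """
    values = matrix.to_numpy(dtype=float)
    values = np.where(np.isnan(values), -1, values).astype(np.int8)
    unknown = [a for a in matrix.index if a not in populations.assignment]
    if unknown:
        raise PolyteError(f"accessions without population assignment: {unknown[:5]}")
    pop_rows = {
        pop: np.array([populations.assignment[a] == pop for a in matrix.index])
        for pop in populations.populations
    }
    rows = []
    for j, locus in enumerate(matrix.columns):
        col = values[:, j]
        overall = _carrier_freq(col)
        row = {"locus_id": locus, "freq_overall": overall}
        for pop, sel in pop_rows.items():
            row[f"freq_{pop}"] = _carrier_freq(col[sel])
        rows.append(row)
    df = pd.DataFrame(rows)
    n_undef = int(df["freq_overall"].isna().sum())
    if n_undef:
        logger.warning("insertion_frequencies: %d loci have all-missing genotypes", n_undef)
    return df


def classify_sharing(
    freqs: pd.DataFrame,
    populations: PopulationAssignment,
) -> pd.DataFrame:
    """Sharing class per locus: population-specific iff present in exactly
    one population, all-shared iff present in all, else partial."""
    populations.require_pairs()
    pops = populations.populations
    cols = [f"freq_{pop}" for pop in pops]
    missing = [c for c in cols if c not in freqs.columns]
    if missing:
        raise PolyteError(f"missing per-population frequency columns: {missing}")
    out = freqs.copy()
    classes = []
    for _, row in freqs.iterrows():
        present = [pop for pop, col in zip(pops, cols) if row[col] > 0]
        if len(present) == 0:
            classes.append("absent")
        elif len(present) == 1:
            classes.append(f"pop-specific:{present[0]}")
        elif len(present) == len(pops):
            classes.append("all-shared")
        else:
            classes.append("partial")
    out["sharing_class"] = classes
    return out


def fisher_exact_greater(table: np.ndarray) -> tuple[float, float]:
    """One-sided (enrichment) Fisher's exact test on a 2x2 table.

    Returns (odds_ratio, p).  The odds ratio is the plain cross-product
    ratio (inf when the denominator is 0 with a non-zero numerator)."""
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    return odds, p


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    prev = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        value = min(prev, p[i] * n / (rank + 1))
        adjusted[i] = value
        prev = value
    return adjusted.tolist()


def bonferroni(pvalues: list[float]) -> list[float]:
    return [min(1.0, p * len(pvalues)) for p in pvalues]


def low_frequency_bias_test(
    freqs: pd.DataFrame,
    categories: pd.DataFrame,
    threshold: float = 0.1,
    reference: str = "intergenic",
    correction: str = "bh",
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-category low-frequency enrichment vs. the reference category.

    For each non-reference genic category, builds the 2x2 table
    [[cat_low, cat_high], [ref_low, ref_high]] where low means
    ``frequency <= threshold``, runs a one-sided Fisher's exact test for
    enrichment of low-frequency loci, and corrects across categories.
    """
    if correction not in ("bh", "bonferroni"):
        raise ValueError("correction must be 'bh' or 'bonferroni'")
    merged = freqs.merge(categories[["locus_id", "genic_category"]], on="locus_id")
    merged = merged[np.isfinite(merged["freq_overall"])]
    ref = merged[merged["genic_category"] == reference]
    if len(ref) == 0:
        raise PolyteError(f"reference category {reference!r} is empty")
    ref_low = int((ref["freq_overall"] <= threshold).sum())
    ref_high = len(ref) - ref_low
    rows = []
    for cat in sorted(merged["genic_category"].unique()):
        if cat == reference:
            continue
        sub = merged[merged["genic_category"] == cat]
        if len(sub) == 0:
            continue
        low = int((sub["freq_overall"] <= threshold).sum())
        high = len(sub) - low
        table = np.array([[low, high], [ref_low, ref_high]])
        if alternative == "greater":
            odds, p = fisher_exact_greater(table)
        else:
            odds_p = stats.fisher_exact(table, alternative=alternative)
            odds = fisher_exact_greater(table)[0]
            p = float(odds_p[1])
        rows.append(
            {
                "category": cat,
                "n_low": low,
                "n_high": high,
                "ref_low": ref_low,
                "ref_high": ref_high,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        adjust = benjamini_hochberg if correction == "bh" else bonferroni
        df["p_adjusted"] = adjust(df["p_value"].tolist())
    return df


def sfs_and_composition(
    freqs: pd.DataFrame,
    loci: pd.DataFrame,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frequency histogram plus superfamily composition per sharing class.

    The histogram uses ``n_bins`` equal bins over (0, 1]; composition
    fractions sum to 1 within each sharing group.
    """
    defined = freqs[np.isfinite(freqs["freq_overall"])]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    f = defined["freq_overall"].to_numpy()
    # bins are (lo, hi]: a locus at exactly a bin edge belongs to the lower bin
    idx = np.clip(np.ceil(f * n_bins).astype(int) - 1, 0, n_bins - 1)
    hist = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "count": [int((idx == b).sum()) for b in range(n_bins)],
        }
    )
    merged = defined.merge(loci[["locus_id", "superfamily"]], on="locus_id")
    groups: dict[str, pd.DataFrame] = {"all": merged}
    if "sharing_class" in merged.columns:
        groups["shared"] = merged[merged["sharing_class"] == "all-shared"]
        for cls in sorted(merged["sharing_class"].unique()):
            if cls.startswith("pop-specific:"):
                groups[f"specific-{cls.split(':', 1)[1]}"] = merged[
                    merged["sharing_class"] == cls
                ]
    comp_rows = []
    for group, sub in groups.items():
        total = len(sub)
        if total == 0:
            continue
        for superfamily, count in sub["superfamily"].value_counts().items():
            comp_rows.append(
                {
                    "group": group,
                    "superfamily": superfamily,
                    "count": int(count),
                    "fraction": count / total,
                }
            )
    return hist, pd.DataFrame(comp_rows)


def shared_te_count_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Accession-pair counts of loci carried by both accessions.

    Missing genotypes contribute nothing to any pair involving them.
    """
    values = matrix.to_numpy(dtype=float)
    carrier = np.where(np.isnan(values), 0, values) == 1
    shared = carrier.astype(np.int64) @ carrier.astype(np.int64).T
    return pd.DataFrame(shared, index=matrix.index, columns=matrix.index)


def distance_sharing_correlation(
    genetic_distance: pd.DataFrame,
    shared_counts: pd.DataFrame,
) -> dict:
    """Pearson correlation over upper-triangle accession pairs."""
    if list(genetic_distance.index) != list(shared_counts.index) or list(
        genetic_distance.columns
    ) != list(shared_counts.columns):
        raise PolyteError("matrices must share accession order")
    n = len(genetic_distance)
    iu = np.triu_indices(n, k=1)
    x = genetic_distance.to_numpy(dtype=float)[iu]
    y = shared_counts.to_numpy(dtype=float)[iu]
    if len(x) < 2:
        raise PolyteError("correlation requires >= 2 accession pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        logger.warning("distance_sharing_correlation: constant vector, r undefined")
        return {"r": math.nan, "p_value": math.nan, "n_pairs": int(len(x))}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p_value": float(p), "n_pairs": int(len(x))}
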
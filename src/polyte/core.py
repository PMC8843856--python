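"""Core domain types shared across the pipeline.

All internal coordinates are 0-based half-open.  VCF and GFF3 records are
converted at the I/O boundary; BED coordinates pass through unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

STRANDS = ("+", "-", ".")

#: Closed superfamily vocabulary used for TE annotations.
SUPERFAMILIES = ("Gypsy", "Copia", "other-LTR", "Helitron", "other-DNA", "other")

#: Genic categories in classification precedence order (coding-most first).
GENIC_CATEGORIES = (
    "CDS",
    "5UTR",
    "3UTR",
    "intron",
    "promoter2kb",
    "downstream2kb",
    "intergenic",
)


class PolyteError(Exception):
    """Base class for pipeline errors."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between intervals; 0 when they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


@dataclass
class PopulationAssignment:
    """Accession -> population labels.

    Accession ids must be unique; at least two populations are required for
    any pairwise statistic (enforced by the callers that need pairs).
    """

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise ValueError("empty population assignment")

    @property
    def accessions(self) -> list[str]:
        return list(self.assignment)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop, None)
        return list(seen)

    def members(self, population: str) -> list[str]:
        return [a for a, p in self.assignment.items() if p == population]

    def require_pairs(self) -> None:
        if len(self.populations) < 2:
            raise PolyteError(">=2 populations required for pairwise statistics")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PopulationAssignment":
        assignment: dict[str, str] = {}
        for accession, pop in pairs:
            if accession in assignment:
                raise ValueError(f"duplicate accession id {accession!r}")
            assignment[accession] = pop
        return cls(assignment)


@dataclass
class ConfigProfile:
    """Numeric parameters of the pipeline with their defaults.

    Window and flank sizes are in bp.  Defaults follow the analysis
    protocol: 5,000-bp scan step, 500-bp ROD windows over 10-kb flanks,
    20-kb flanks for the neutrality-test confirmation, top-5% empirical
    outliers, 0.1 low-frequency threshold, >=10 reads and 150-bp merging
    for siRNA loci, and a 0.05 MAF floor for SNP statistics.
    """

    window_bp: int = 5000
    step_bp: int = 5000
    sweep_window_bp: int = 5000
    rod_window_bp: int = 500
    flank_rod_bp: int = 10_000
    flank_tajd_bp: int = 20_000
    central_zone_bp: int = 2000
    outlier_quantile: float = 0.05
    low_freq_threshold: float = 0.1
    sirna_min_reads: int = 10
    sirna_merge_bp: int = 150
    maf_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "window_bp",
            "step_bp",
            "sweep_window_bp",
            "rod_window_bp",
            "flank_rod_bp",
            "flank_tajd_bp",
            "central_zone_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.outlier_quantile < 1):
            raise ValueError("outlier_quantile must be in (0, 1)")
        if not (0 < self.low_freq_threshold < 1):
            raise ValueError("low_freq_threshold must be in (0, 1)")
        if self.sirna_min_reads < 1:
            raise ValueError("sirna_min_reads must be >= 1")
        if self.sirna_merge_bp < 0:
            raise ValueError("sirna_merge_bp must be >= 0")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")

    def replace(self, **kwargs) -> "ConfigProfile":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str | int | float]) -> "ConfigProfile":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in mapping.items():
            if key not in fields:
                raise ValueError(f"unknown config key {key!r}")
            caster = float if key in ("outlier_quantile", "low_freq_threshold", "maf_min") else int
            kwargs[key] = caster(value)
        return cls(**kwargs)


@dataclass
class GenotypePanel:
    """Per-chromosome biallelic SNP genotypes as alternate-allele counts.

    ``counts`` is accessions x sites with values in {0, 1, 2}; -1 marks a
    missing genotype.  Positions are 0-based.
    """

    chrom: str
    positions: np.ndarray
    counts: np.ndarray
    samples: list[str]
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int8)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (accessions x sites)")
        if self.counts.shape != (len(self.samples), len(self.positions)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        if np.any(np.diff(self.positions) < 0):
            order = np.argsort(self.positions, kind="stable")
            self.positions = self.positions[order]
            self.counts = self.counts[:, order]
            if self.ref:
                self.ref = [self.ref[i] for i in order]
            if self.alt:
                self.alt = [self.alt[i] for i in order]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def subset_samples(self, samples: Iterable[str]) -> "GenotypePanel":
        wanted = list(samples)
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise PolyteError(f"samples absent from panel: {missing}")
        rows = [index[s] for s in wanted]
        return GenotypePanel(
            chrom=self.chrom,
            positions=self.positions.copy(),
            counts=self.counts[rows],
            samples=wanted,
            ref=list(self.ref),
            alt=list(self.alt),
        )

    def site_counts(self) -> "SiteCounts":
        """Collapse genotypes to per-site derived/total allele counts."""
        observed = self.counts >= 0
        derived = np.where(observed, self.counts, 0).sum(axis=0)
        total = 2 * observed.sum(axis=0)
        return SiteCounts(self.positions.copy(), derived.astype(np.int64), total.astype(np.int64))


@dataclass
class SiteCounts:
    """Per-site derived-allele counts ``c`` out of ``m`` observed alleles.

    The minimal sufficient representation for frequency-based diversity
    statistics (pi, Watterson's theta, Tajima's D, Hudson Fst).
    """

    positions: np.ndarray
    derived: np.ndarray
    total: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.derived = np.asarray(self.derived, dtype=np.int64)
        self.total = np.asarray(self.total, dtype=np.int64)
        if not (len(self.positions) == len(self.derived) == len(self.total)):
            raise ValueError("positions/derived/total length mismatch")
        if np.any(self.derived > self.total) or np.any(self.derived < 0):
            raise ValueError("derived counts must lie in [0, total]")

    def __len__(self) -> int:
        return len(self.positions)

    def in_range(self, start: int, end: int) -> "SiteCounts":
        mask = (self.positions >= start) & (self.positions < end)
        return SiteCounts(self.positions[mask], self.derived[mask], self.total[mask])

    def segregating_mask(self) -> np.ndarray:
        return (self.derived > 0) & (self.derived < self.total)

    def maf_mask(self, maf_min: float) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(self.total > 0, self.derived / np.maximum(self.total, 1), 0.0)
        maf = np.minimum(freq, 1.0 - freq)
        return maf >= maf_min
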
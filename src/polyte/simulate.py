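"""Synthetic-data generation for every pipeline input.

Neutral windows come from a single-population coalescent (exponential
coalescence times, Poisson mutations on branches, infinite sites, uniform
positions).  Multi-population panels use a shared ancestral haplotype pool
whose per-site allele frequencies drift per population under a
Balding-Nichols model calibrated to a target baseline differentiation.
A selective sweep is emulated by thinning expected diversity around the
planted TE with an exponential-decay factor ``1 - f_red * exp(-d/decay)``;
thinned sites are converted to singletons (a fraction) or monomorphic so
the planted ROD target is exact in expectation while the local frequency
spectrum skews toward rare variants.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GenomicInterval, PolyteError, PopulationAssignment
from .popgen import HaplotypeBlock

__all__ = [
    "SimParams",
    "PlantedTruth",
    "SweepDataset",
    "simulate_neutral_window",
    "simulate_sweep_dataset",
    "simulate_te_genotype_matrix",
    "simulate_landscape",
    "write_fixture_bundle",
]

#: Fraction of suppressed sweep-region sites converted to singletons rather
#: than monomorphic; generates the rare-variant excess of a sweep while the
#: per-site expected diversity stays exactly ``factor * h``.
SINGLETON_FRACTION = 0.8


@dataclass
class SimParams:
    n_pops: int = 3
    n_haps_per_pop: int = 20
    theta_per_bp: float = 0.012
    window_bp: int = 21_000
    n_regions: int = 100
    sweep_region_index: int | None = None
    sweep_f_red: float = 0.9
    sweep_decay_bp: int = 2000
    fst_baseline: float = 0.1
    te_len_bp: int = 100
    region_stride_bp: int = 30_000
    pop_labels: tuple[str, ...] = ("NE", "NW", "S")
    sweep_target_pop: str = "NE"
    te_carrier_freq_target: float = 0.9
    te_carrier_freq_other: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sweep_f_red <= 1.0):
            raise ValueError("sweep_f_red must lie in [0, 1]")
        if self.theta_per_bp <= 0:
            raise ValueError("theta_per_bp must be > 0")
        if self.n_haps_per_pop < 2:
            raise ValueError("n_haps_per_pop must be >= 2")
        if not (0.0 <= self.fst_baseline < 1.0):
            raise ValueError("fst_baseline must lie in [0, 1)")
        if len(self.pop_labels) < self.n_pops:
            raise ValueError("not enough pop_labels for n_pops")
        if self.sweep_region_index is not None and not (
            0 <= self.sweep_region_index < self.n_regions
        ):
            raise ValueError("sweep_region_index out of range")


@dataclass
class PlantedTruth:
    adaptive_te_ids: list[str] = field(default_factory=list)
    sweep_target_pop: str | None = None
    sweep_f_red: float = 0.0
    sweep_decay_bp: int = 0
    te_frequency_by_category: dict[str, list[float]] = field(default_factory=dict)
    expression_beta: float = 0.0
    sirna_plus_multiplier: float = 1.0
    te_carrier_freq: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def simulate_neutral_window(
    n_haps: int,
    theta: float,
    window_bp: int,
    seed: int | np.random.Generator = 0,
    start: int = 0,
    chrom: str = "chr1",
) -> HaplotypeBlock:
    """Infinite-sites haplotypes for one window via Hudson's coalescent.

    ``theta`` is the per-window population mutation rate: each branch of
    length t (coalescent units) receives Poisson(theta/2 * t) mutations, so
    E[S] = theta * a1(n).
    """
    if n_haps < 2:
        raise PolyteError("coalescent simulation requires n_haps >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Active lineages as leaf-membership boolean rows.
    lineages = [np.eye(n_haps, dtype=bool)[i] for i in range(n_haps)]
    columns: list[np.ndarray] = []
    k = n_haps
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        # Each of the k branches carries mutations at rate theta/2 over t.
        n_mut = rng.poisson(theta / 2.0 * t, size=k)
        for branch, count in zip(lineages, n_mut):
            for _ in range(count):
                columns.append(branch.copy())
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1
    S = len(columns)
    matrix = (
        np.stack(columns, axis=1).astype(np.uint8)
        if S
        else np.zeros((n_haps, 0), dtype=np.uint8)
    )
    positions = start + np.sort(rng.integers(0, window_bp, size=S))
    return HaplotypeBlock(
        positions=positions,
        matrix=matrix,
        window=GenomicInterval(chrom, start, start + window_bp),
    )


def _drift_frequencies(p: np.ndarray, fst: float, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols per-population frequency drift around ancestral p."""
    if fst <= 0:
        return p.copy()
    scale = (1.0 - fst) / fst
    a = np.maximum(p * scale, 1e-9)
    b = np.maximum((1.0 - p) * scale, 1e-9)
    return rng.beta(a, b)


@dataclass
class SweepRegion:
    region_id: str
    te_id: str
    interval: GenomicInterval
    te_interval: GenomicInterval
    #: pruned per-population haplotype blocks (segregating sites only)
    blocks: dict[str, HaplotypeBlock]
    #: shared site positions and raw (unpruned) per-population matrices,
    #: kept so cross-population statistics see a common site set
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def site_counts_by_pop(self) -> dict:
        from .core import SiteCounts

        out = {}
        for pop, matrix in self.matrices.items():
            out[pop] = SiteCounts(
                self.positions.copy(),
                matrix.sum(axis=0).astype(np.int64),
                np.full(len(self.positions), matrix.shape[0], dtype=np.int64),
            )
        return out


@dataclass
class SweepDataset:
    params: SimParams
    regions: list[SweepRegion]
    populations: PopulationAssignment
    te_carriers: dict[str, dict[str, int]]
    truth: PlantedTruth

    @property
    def te_intervals(self) -> dict[str, GenomicInterval]:
        return {r.te_id: r.te_interval for r in self.regions}


def _sweep_site_alleles(
    q: float,
    factor: float,
    n_haps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Alleles for one target-population site under expected-pi thinning.

    Chooses among keep / singleton / monomorphic outcomes with
    probabilities solved so that E[pi_site] = factor * 2 q (1 - q).
    """
    h0 = 2.0 * q * (1.0 - q)
    h1 = 2.0 / n_haps  # expected pi of a single-carrier site
    if factor >= 1.0 or h0 == 0.0:
        return (rng.random(n_haps) < q).astype(np.uint8)
    if h0 <= h1:
        k, s = factor, 0.0
    else:
        s = SINGLETON_FRACTION * (1.0 - factor)
        k = factor - s * h1 / h0
        if k < 0.0:
            k = 0.0
            s = factor * h0 / h1
    u = rng.random()
    if u < k:
        return (rng.random(n_haps) < q).astype(np.uint8)
    if u < k + s:
        alleles = np.zeros(n_haps, dtype=np.uint8)
        alleles[rng.integers(n_haps)] = 1
        return alleles
    fixed = 1 if rng.random() < q else 0
    return np.full(n_haps, fixed, dtype=np.uint8)


def simulate_sweep_dataset(params: SimParams, seed: int | None = None) -> SweepDataset:
    """Multi-region, multi-population haplotype panels with an optional sweep.

    Each region gets one pooled ancestral coalescent window; per-population
    haplotypes are resampled per site from drifted frequencies.  In the
    sweep region, the target population's expected diversity at distance d
    from the TE is scaled by ``1 - f_red * exp(-d / decay)``, and the TE
    insertion allele is carried at high frequency in the target population
    only.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    labels = list(params.pop_labels[: params.n_pops])
    if params.sweep_region_index is not None and params.sweep_target_pop not in labels:
        raise ValueError("sweep_target_pop not among pop_labels")
    n = params.n_haps_per_pop
    n_acc = n // 2
    if n_acc < 1:
        raise ValueError("need >= 2 haplotypes per population")
    assignment = PopulationAssignment.from_pairs(
        (f"{pop}_{i:03d}", pop) for pop in labels for i in range(n_acc)
    )
    regions: list[SweepRegion] = []
    te_carriers: dict[str, dict[str, int]] = {}
    truth = PlantedTruth(
        sweep_target_pop=params.sweep_target_pop
        if params.sweep_region_index is not None
        else None,
        sweep_f_red=params.sweep_f_red,
        sweep_decay_bp=params.sweep_decay_bp,
    )
    L = params.window_bp
    theta = params.theta_per_bp * L
    n_pool = n * len(labels)
    for r in range(params.n_regions):
        start = r * params.region_stride_bp
        region_iv = GenomicInterval("chr1", start, start + L)
        te_mid = start + L // 2
        te_iv = GenomicInterval(
            "chr1", te_mid - params.te_len_bp // 2, te_mid + (params.te_len_bp + 1) // 2
        )
        te_id = f"TE{r:04d}"
        pool = simulate_neutral_window(n_pool, theta, L, rng, start=start)
        p_anc = pool.matrix.mean(axis=0)
        positions = pool.positions
        # distance from each site to the TE interval (0 inside)
        d = np.maximum(
            0, np.maximum(te_iv.start - positions, positions - (te_iv.end - 1))
        ).astype(float)
        is_sweep = params.sweep_region_index == r
        blocks: dict[str, HaplotypeBlock] = {}
        matrices: dict[str, np.ndarray] = {}
        for pop in labels:
            q = _drift_frequencies(p_anc, params.fst_baseline, rng)
            if is_sweep and pop == params.sweep_target_pop and params.sweep_f_red > 0:
                factor = 1.0 - params.sweep_f_red * np.exp(-d / params.sweep_decay_bp)
                matrix = np.empty((n, len(positions)), dtype=np.uint8)
                for j in range(len(positions)):
                    matrix[:, j] = _sweep_site_alleles(q[j], float(factor[j]), n, rng)
            else:
                matrix = (rng.random((n, len(positions))) < q).astype(np.uint8)
            matrices[pop] = matrix
            blocks[pop] = HaplotypeBlock(
                positions=positions.copy(), matrix=matrix, window=region_iv
            )
        carriers: dict[str, int] = {}
        for pop in labels:
            if is_sweep:
                freq = (
                    params.te_carrier_freq_target
                    if pop == params.sweep_target_pop
                    else params.te_carrier_freq_other
                )
            else:
                freq = float(rng.beta(0.3, 0.3))
            for acc in assignment.members(pop):
                carriers[acc] = int(rng.random() < freq)
            if is_sweep:
                truth.te_carrier_freq.setdefault(te_id, {})[pop] = freq
        te_carriers[te_id] = carriers
        regions.append(
            SweepRegion(
                f"region{r:04d}", te_id, region_iv, te_iv, blocks,
                positions=positions.copy(), matrices=matrices,
            )
        )
        if is_sweep:
            truth.adaptive_te_ids.append(te_id)
    return SweepDataset(params, regions, assignment, te_carriers, truth)


def sweep_dataset_to_panel(dataset: SweepDataset):
    """Pair haplotypes into diploid accessions and pool regions into one
    chr1 genotype panel (alternate-allele counts in {0, 1, 2})."""
    from .core import GenotypePanel

    labels = list(dataset.params.pop_labels[: dataset.params.n_pops])
    samples = dataset.populations.accessions
    pos_parts = []
    count_parts = []
    for region in dataset.regions:
        pos_parts.append(region.positions)
        cols = []
        for pop in labels:
            matrix = region.matrices[pop]
            n_acc = matrix.shape[0] // 2
            cols.append(matrix[: 2 * n_acc : 2] + matrix[1 : 2 * n_acc : 2])
        count_parts.append(np.concatenate(cols, axis=0))
    positions = np.concatenate(pos_parts)
    counts = np.concatenate(count_parts, axis=1)
    return GenotypePanel(
        chrom="chr1", positions=positions, counts=counts, samples=samples
    )


def simulate_te_genotype_matrix(
    n_loci: int,
    pops: dict[str, int],
    category_mix: dict[str, float] | None = None,
    bias_params: dict[str, float] | None = None,
    superfamily_mix: dict[str, float] | None = None,
    pop_specific_fraction: float = 0.0,
    baseline_beta: tuple[float, float] = (0.3, 0.3),
    low_freq_range: tuple[float, float] = (0.01, 0.08),
    seed: int = 0,
):
    """TE presence/absence matrix with planted genic-category frequency bias.

    Per-locus carrier frequency is drawn from a U-shaped Beta baseline;
    for categories named in ``bias_params`` the locus is drawn instead from
    a low-frequency component (uniform on ``low_freq_range``) with the stated
    probability.  Returns ``(loci_df, matrix_df, truth)`` where loci_df has
    locus metadata and matrix_df is accession x locus in {0, 1}.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if category_mix is None:
        category_mix = {
            "CDS": 0.05,
            "5UTR": 0.05,
            "3UTR": 0.05,
            "intron": 0.15,
            "promoter2kb": 0.1,
            "downstream2kb": 0.1,
            "intergenic": 0.5,
        }
    missing = {"CDS", "intron", "promoter2kb", "downstream2kb", "intergenic"} - set(
        category_mix
    )
    has_utr = ("UTR" in category_mix) or {"5UTR", "3UTR"} <= set(category_mix)
    if missing or not has_utr:
        raise ValueError(f"category_mix must cover all genic categories (missing {missing or 'UTR'})")
    if abs(sum(category_mix.values()) - 1.0) > 1e-9:
        raise ValueError("category_mix weights must sum to 1")
    if superfamily_mix is None:
        superfamily_mix = {
            "Gypsy": 0.114,
            "Copia": 0.118,
            "other-LTR": 0.15,
            "Helitron": 0.2,
            "other-DNA": 0.26,
            "other": 0.158,
        }
    if abs(sum(superfamily_mix.values()) - 1.0) > 1e-9:
        raise ValueError("superfamily_mix weights must sum to 1")
    bias_params = dict(bias_params or {})
    pop_labels = list(pops)
    categories = rng.choice(
        list(category_mix), size=n_loci, p=list(category_mix.values())
    )
    superfamilies = rng.choice(
        list(superfamily_mix), size=n_loci, p=list(superfamily_mix.values())
    )
    freqs = np.empty(n_loci)
    for i, cat in enumerate(categories):
        low_prob = bias_params.get(cat, 0.0)
        if rng.random() < low_prob:
            freqs[i] = rng.uniform(*low_freq_range)
        else:
            freqs[i] = rng.beta(*baseline_beta)
    specific_pop = np.full(n_loci, "", dtype=object)
    n_specific = int(round(pop_specific_fraction * n_loci))
    if n_specific:
        chosen = rng.choice(n_loci, size=n_specific, replace=False)
        specific_pop[chosen] = rng.choice(pop_labels, size=n_specific)
    accessions = [f"{pop}_{i:03d}" for pop in pop_labels for i in range(pops[pop])]
    acc_pop = np.array([a.rsplit("_", 1)[0] for a in accessions])
    matrix = np.zeros((len(accessions), n_loci), dtype=np.int8)
    for j in range(n_loci):
        for pop in pop_labels:
            rows = acc_pop == pop
            if specific_pop[j] and pop != specific_pop[j]:
                continue
            draw = rng.random(int(rows.sum())) < freqs[j]
            matrix[rows, j] = draw.astype(np.int8)
        if specific_pop[j] and matrix[:, j].sum() == 0:
            # guarantee the planted pop-specific locus is observed
            rows = np.flatnonzero(acc_pop == specific_pop[j])
            matrix[rng.choice(rows), j] = 1
    loci = pd.DataFrame(
        {
            "locus_id": [f"TE{j:05d}" for j in range(n_loci)],
            "chrom": "chr1",
            "start": np.arange(n_loci) * 1000,
            "end": np.arange(n_loci) * 1000 + 100,
            "superfamily": superfamilies,
            "genic_category": categories,
            "planted_freq": freqs,
            "planted_specific_pop": specific_pop,
        }
    )
    matrix_df = pd.DataFrame(matrix, index=accessions, columns=loci["locus_id"])
    truth = PlantedTruth()
    for cat in category_mix:
        truth.te_frequency_by_category[cat] = [
            float(f) for f, c in zip(freqs, categories) if c == cat
        ]
    return loci, matrix_df, truth


@dataclass
class Landscape:
    genes: "object"  # list[landscape.GeneModel]; late import avoids a cycle
    tes: "object"
    sirna_reads: list[GenomicInterval]
    expression: "object"  # pandas DataFrame genes x timepoints
    truth: PlantedTruth


def simulate_landscape(
    n_genes: int = 200,
    n_tes: int = 200,
    sirna_fraction: float = 0.5,
    expression_params: dict | None = None,
    timepoints: tuple[str, ...] = ("0h", "36h"),
    gene_len_bp: int = 2000,
    spacing_bp: int = 14_000,
    max_te_distance_bp: int = 6000,
    sirna_reads_per_te: int = 12,
    seed: int = 0,
) -> Landscape:
    """Gene/TE/siRNA annotations plus an FPKM table with planted effects.

    Expression for gene g is ``(baseline + beta * min(d_g, 1000)) * m_g *
    lognormal(0, noise_sd)`` where d_g is the distance to the nearest TE
    and m_g is ``sirna_plus_multiplier`` when that TE is siRNA+ (else 1).
    """
    import pandas as pd

    from .landscape import GeneModel, TEAnnotation

    params = {
        "baseline": 10.0,
        "beta": 0.0,
        "sirna_plus_multiplier": 1.0,
        "noise_sd": 0.3,
    }
    params.update(expression_params or {})
    rng = np.random.default_rng(seed)
    if spacing_bp < gene_len_bp + 2 * max_te_distance_bp // 2:
        raise PolyteError("infeasible placement density: increase spacing_bp")
    genes: list[GeneModel] = []
    tes: list[TEAnnotation] = []
    sirna_reads: list[GenomicInterval] = []
    te_distance: dict[str, float] = {}
    te_sirna: dict[str, bool] = {}
    rows = []
    for i in range(n_genes):
        gstart = 10_000 + i * spacing_bp
        gend = gstart + gene_len_bp
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{i:05d}"
        exon_mid = gene_len_bp // 2
        exons = [
            GenomicInterval("chr1", gstart, gstart + exon_mid - 100, strand),
            GenomicInterval("chr1", gstart + exon_mid + 100, gend, strand),
        ]
        cds = [
            GenomicInterval("chr1", gstart + 200, gstart + exon_mid - 100, strand),
            GenomicInterval("chr1", gstart + exon_mid + 100, gend - 200, strand),
        ]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval("chr1", gstart, gend, strand),
                exons=exons,
                cds=cds,
            )
        )
        if i < n_tes:
            d = int(rng.integers(0, max_te_distance_bp))
            te_len = 150
            if d == 0:
                te_start = gstart + exon_mid - 50  # inside the intron
            else:
                te_start = gstart - d - te_len  # upstream, edge gap exactly d
            te_id = f"te{i:05d}"
            te_iv = GenomicInterval("chr1", te_start, te_start + te_len)
            has_sirna = bool(rng.random() < sirna_fraction)
            tes.append(TEAnnotation(te_id=te_id, interval=te_iv, superfamily="Helitron"))
            te_distance[gene_id] = d
            te_sirna[gene_id] = has_sirna
            if has_sirna:
                # jitter < read length keeps the stack one connected component
                base = int(rng.integers(0, te_len - 24 - 8))
                for _ in range(sirna_reads_per_te):
                    off = base + int(rng.integers(0, 8))
                    sirna_reads.append(
                        GenomicInterval("chr1", te_start + off, te_start + off + 24)
                    )
            mean = params["baseline"] + params["beta"] * min(d, 1000)
            if has_sirna:
                mean *= params["sirna_plus_multiplier"]
        else:
            mean = params["baseline"]
        fpkm = mean * rng.lognormal(0.0, params["noise_sd"], size=len(timepoints))
        rows.append([gene_id, *fpkm])
    expression = pd.DataFrame(
        [r[1:] for r in rows],
        index=[r[0] for r in rows],
        columns=list(timepoints),
    )
    expression.index.name = "gene_id"
    truth = PlantedTruth(
        expression_beta=params["beta"],
        sirna_plus_multiplier=params["sirna_plus_multiplier"],
    )
    return Landscape(genes, tes, sirna_reads, expression, truth)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(outputs: dict[str, Path | str], out_dir: Path | str) -> dict:
    """Record a checksum manifest for an already-written set of artifacts."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": {}}
    for name, path in sorted(outputs.items()):
        path = Path(path)
        if not path.exists():
            raise PolyteError(f"artifact {name!r} missing at {path}")
        manifest["files"][name] = {
            "path": str(path.relative_to(out_dir)) if path.is_relative_to(out_dir) else str(path),
            "sha256": _sha256(path),
        }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def verify_fixture_bundle(out_dir: Path | str) -> list[str]:
    """Return the names of artifacts whose checksum no longer matches."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    bad = []
    for name, entry in manifest["files"].items():
        path = Path(entry["path"])
        if not path.is_absolute():
            path = out_dir / path
        if not path.exists() or _sha256(path) != entry["sha256"]:
            bad.append(name)
    return bad
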
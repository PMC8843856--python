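"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere.  VCF (1-based) and
GFF3 (1-based inclusive) are converted at this boundary; BED passes
through unchanged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import GenomicInterval, GenotypePanel, PolyteError, PopulationAssignment
from .landscape import GeneModel, TEAnnotation

__all__ = [
    "read_vcf_genotypes",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_te_annotations",
    "read_te_matrix",
    "write_te_matrix",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_populations",
    "write_populations",
    "read_expression",
    "write_expression",
    "read_config_file",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# VCF

def read_vcf_genotypes(
    path: str | Path,
    populations: PopulationAssignment | None = None,
) -> dict[str, GenotypePanel]:
    """Read biallelic SNP genotypes from a VCF into per-chromosome panels.

    Positions are converted to 0-based; multi-allelic and non-SNP records
    are skipped with a logged count.  When ``populations`` is given, every
    assigned accession must be present in the VCF header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if populations is not None:
        absent = [a for a in populations.accessions if a not in samples]
        if absent:
            raise PolyteError(
                f"samples in population file absent from VCF header: {absent}"
            )
    per_chrom: dict[str, dict[str, list]] = {}
    n_skipped = 0
    for rec in vcf:
        alts = rec.alts or ()
        if len(alts) != 1 or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        store = per_chrom.setdefault(
            rec.chrom, {"pos": [], "ref": [], "alt": [], "counts": []}
        )
        store["pos"].append(rec.pos - 1)
        store["ref"].append(rec.ref)
        store["alt"].append(alts[0])
        col = np.full(len(samples), -1, dtype=np.int8)
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            col[i] = sum(1 for a in gt if a != 0)
        store["counts"].append(col)
    if n_skipped:
        logger.info("read_vcf_genotypes: skipped %d non-biallelic-SNP records", n_skipped)
    panels = {}
    for chrom, store in per_chrom.items():
        panels[chrom] = GenotypePanel(
            chrom=chrom,
            positions=np.array(store["pos"], dtype=np.int64),
            counts=np.stack(store["counts"], axis=1) if store["counts"] else np.zeros((len(samples), 0), dtype=np.int8),
            samples=samples,
            ref=store["ref"],
            alt=store["alt"],
        )
    return panels


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(panels: dict[str, GenotypePanel] | GenotypePanel, path: str | Path) -> None:
    """Write panels as an uncompressed VCF 4.2 with unphased GT calls."""
    if isinstance(panels, GenotypePanel):
        panels = {panels.chrom: panels}
    chroms = sorted(panels)
    samples = panels[chroms[0]].samples
    lines = [_VCF_HEADER]
    for chrom in chroms:
        end = int(panels[chrom].positions.max()) + 1 if panels[chrom].n_sites else 1
        lines.append(f"##contig=<ID={chrom},length={end}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n"
    )
    gt_map = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    for chrom in chroms:
        panel = panels[chrom]
        if panel.samples != samples:
            raise PolyteError("all panels must share the sample list")
        ref = panel.ref or ["A"] * panel.n_sites
        alt = panel.alt or ["T"] * panel.n_sites
        for j in range(panel.n_sites):
            gts = "\t".join(gt_map[int(g)] for g in panel.counts[:, j])
            lines.append(
                f"{chrom}\t{panel.positions[j] + 1}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[tuple[GenomicInterval, str, str]]:
    """Read BED3/BED6 records as (interval, name, score) tuples."""
    out = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise PolyteError(f"{path}:{line_no}: BED record with <3 fields")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"feature{line_no}"
        score = fields[4] if len(fields) > 4 else "."
        strand = fields[5] if len(fields) > 5 else "."
        out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


def write_bed(records, path: str | Path) -> None:
    """Write (interval, name, score) tuples (or bare intervals) as BED6."""
    lines = []
    for record in records:
        if isinstance(record, GenomicInterval):
            iv, name, score = record, ".", "."
        else:
            iv, name, score = record
        lines.append(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
    Path(path).write_text("".join(lines))


def read_te_annotations(path: str | Path) -> list[TEAnnotation]:
    """BED6 of TE loci: name = te_id, score column carries the superfamily
    when it is not numeric/'.', otherwise 'other'."""
    from .core import SUPERFAMILIES

    out = []
    for iv, name, score in read_bed(path):
        superfamily = score if score in SUPERFAMILIES else "other"
        out.append(TEAnnotation(te_id=name, interval=iv, superfamily=superfamily))
    return out


# ---------------------------------------------------------------------------
# TE genotype matrix (BED + TSV)

def read_te_matrix(
    bed_path: str | Path, tsv_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join TE locus BED with a locus x accession presence TSV.

    The TSV has a ``locus_id`` first column and one column per accession
    holding {0, 1, NA}.  Returns (loci, matrix) where matrix is accession x
    locus with NA kept as NaN.  A TSV locus missing from the BED is a hard
    error; BED-only loci are dropped with a log entry.
    """
    bed = read_bed(bed_path)
    loci = pd.DataFrame(
        {
            "locus_id": [name for _, name, _ in bed],
            "chrom": [iv.chrom for iv, _, _ in bed],
            "start": [iv.start for iv, _, _ in bed],
            "end": [iv.end for iv, _, _ in bed],
            "strand": [iv.strand for iv, _, _ in bed],
            "superfamily": [score if score != "." else "other" for _, _, score in bed],
        }
    )
    if loci["locus_id"].duplicated().any():
        raise PolyteError("duplicate locus ids in BED")
    table = pd.read_csv(tsv_path, sep="\t", dtype={"locus_id": str})
    if "locus_id" not in table.columns:
        raise PolyteError("TE matrix TSV must have a locus_id column")
    if len(table) == 0:
        raise PolyteError("no genotype rows in TE matrix TSV")
    unknown = set(table["locus_id"]) - set(loci["locus_id"])
    if unknown:
        raise PolyteError(f"locus ids in TSV absent from BED: {sorted(unknown)[:5]}")
    table = table.set_index("locus_id")
    matrix = table.T  # accession x locus
    matrix = matrix.apply(pd.to_numeric, errors="coerce")
    present = [l for l in loci["locus_id"] if l in matrix.columns]
    dropped = len(loci) - len(present)
    if dropped:
        logger.info("read_te_matrix: %d BED loci have no genotype rows", dropped)
    loci = loci[loci["locus_id"].isin(present)].reset_index(drop=True)
    matrix = matrix[loci["locus_id"].tolist()]
    return loci, matrix


def write_te_matrix(
    loci: pd.DataFrame, matrix: pd.DataFrame, bed_path: str | Path, tsv_path: str | Path
) -> None:
    records = [
        (
            GenomicInterval(r.chrom, int(r.start), int(r.end), getattr(r, "strand", ".")),
            r.locus_id,
            getattr(r, "superfamily", "."),
        )
        for r in loci.itertuples()
    ]
    write_bed(records, bed_path)
    out = matrix.T
    out.index.name = "locus_id"
    with_na = out.astype("object").where(out.notna(), "NA")
    with_na.to_csv(tsv_path, sep="\t")


# ---------------------------------------------------------------------------
# GFF3 gene models

def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features into gene models.

    Coordinates become 0-based half-open.  Exons and CDS of all transcripts
    of a gene are pooled; UTRs are derived downstream from exon minus CDS
    when not explicit.  Children with unresolvable parents are skipped with
    a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        interval = GenomicInterval(
            gene.seqid, gene.start - 1, gene.end, gene.strand if gene.strand in "+-" else "."
        )
        exons: list[GenomicInterval] = []
        cds: list[GenomicInterval] = []
        for child in db.children(gene.id):
            kind = child.featuretype.lower()
            iv = GenomicInterval(
                child.seqid, child.start - 1, child.end, child.strand if child.strand in "+-" else "."
            )
            if kind == "exon":
                exons.append(iv)
            elif kind == "cds":
                cds.append(iv)
        genes.append(
            GeneModel(gene_id=gene.id, interval=interval, exons=exons, cds=cds)
        )
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


def write_gff3_genes(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (gene -> mRNA -> exon/CDS)."""
    lines = ["##gff-version 3\n"]
    for gene in genes:
        iv = gene.interval
        lines.append(
            f"{iv.chrom}\tpolyte\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={gene.gene_id}\n"
        )
        mrna_id = f"{gene.gene_id}.1"
        lines.append(
            f"{iv.chrom}\tpolyte\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\tID={mrna_id};Parent={gene.gene_id}\n"
        )
        for i, exon in enumerate(sorted(gene.exons, key=lambda e: e.start), 1):
            lines.append(
                f"{iv.chrom}\tpolyte\texon\t{exon.start + 1}\t{exon.end}\t.\t{iv.strand}\t.\t"
                f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
            )
        for i, c in enumerate(sorted(gene.cds, key=lambda e: e.start), 1):
            lines.append(
                f"{iv.chrom}\tpolyte\tCDS\t{c.start + 1}\t{c.end}\t.\t{iv.strand}\t0\t"
                f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
            )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Simple TSVs

def read_populations(path: str | Path) -> PopulationAssignment:
    """Two-column TSV (accession_id, population) with a header row."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(table.columns)
    if len(cols) < 2:
        raise PolyteError("population TSV needs accession and population columns")
    return PopulationAssignment.from_pairs(
        (row[cols[0]], row[cols[1]]) for _, row in table.iterrows()
    )


def write_populations(populations: PopulationAssignment, path: str | Path) -> None:
    lines = ["accession_id\tpopulation\n"]
    lines += [f"{a}\t{p}\n" for a, p in populations.assignment.items()]
    Path(path).write_text("".join(lines))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x timepoint FPKM TSV with a gene_id first column."""
    table = pd.read_csv(path, sep="\t")
    if table.columns[0] != "gene_id":
        table = table.rename(columns={table.columns[0]: "gene_id"})
    if table["gene_id"].duplicated().any():
        raise PolyteError("duplicate gene ids in expression table")
    table = table.set_index("gene_id")
    if (table.to_numpy(dtype=float) < 0).any():
        raise PolyteError("FPKM values must be >= 0")
    return table


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    out = expression.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_config_file(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` config lines; '#' starts a comment."""
    out: dict[str, str] = {}
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise PolyteError(f"{path}:{line_no}: expected key = value")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out
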
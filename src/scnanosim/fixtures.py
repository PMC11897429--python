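"""Self-contained synthetic inputs: toy genome/annotation/transcriptome,
barcode whitelists, count matrices and constructed PAF alignments.

Everything a simulation run needs can be generated here from a seed, so the
package (and its tests) never depend on downloaded references.  The toy
genome carries multi-exon genes whose isoforms share exons, which exercises
the length prior, splicing and intron retention; synthetic PAF files realise
exactly known truncation and identity values, which makes the estimators
testable against construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .counts import CountMatrix, CountModelParams, simulate_counts
from .paf import PafRecord

__all__ = [
    "ToyReference",
    "make_toy_reference",
    "write_toy_reference",
    "make_synthetic_paf",
    "make_whitelist",
    "make_toy_matrix",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


@dataclass
class ToyReference:
    """In-memory toy reference; use :func:`write_toy_reference` for files."""

    genome: dict[str, str]
    transcripts: dict[str, str]  # transcript id -> spliced sequence
    gtf_lines: list[str]
    gene_to_transcripts: dict[str, list[str]]
    exons: dict[str, tuple[str, str, list[tuple[int, int]]]]


def make_toy_reference(
    n_genes: int = 5,
    isoforms_per_gene: int = 2,
    exons_per_gene: int = 4,
    exon_length_range: tuple[int, int] = (60, 160),
    intron_length_range: tuple[int, int] = (40, 120),
    seed: int | np.random.Generator = 0,
) -> ToyReference:
    """Random multi-exon genes on one chromosome, alternating strands.

    Isoform 1 of each gene uses all exons; further isoforms each skip one
    distinct internal exon, so isoforms share sequence but differ in length.
    Transcript sequences are spliced from the genome, so extracting exons
    per the GTF reproduces them exactly.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if isoforms_per_gene < 1:
        raise ValueError("isoforms_per_gene must be >= 1")
    if exons_per_gene < max(isoforms_per_gene, 2) and isoforms_per_gene > 1:
        raise ValueError("need enough internal exons to skip one per extra isoform")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed

    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    gtf: list[str] = []
    transcripts: dict[str, str] = {}
    gene_map: dict[str, list[str]] = {}
    exon_map: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}

    for g in range(n_genes):
        gene_id = f"gene_{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        gap = int(rng.integers(50, 150))
        pieces.append(_random_seq(gap, rng))
        cursor += gap
        exons: list[tuple[int, int]] = []
        for e in range(exons_per_gene):
            if e > 0:
                ilen = int(rng.integers(*intron_length_range))
                pieces.append(_random_seq(ilen, rng))
                cursor += ilen
            elen = int(rng.integers(*exon_length_range))
            pieces.append(_random_seq(elen, rng))
            exons.append((cursor, cursor + elen))
            cursor += elen
        gene_start, gene_end = exons[0][0], exons[-1][1]
        gtf.append(_gtf_line(chrom, "gene", gene_start, gene_end, strand,
                             gene_id=gene_id))
        skippable = list(range(1, exons_per_gene - 1)) or [0]
        tids: list[str] = []
        for k in range(isoforms_per_gene):
            tid = f"tx_{g + 1}_{k + 1}"
            if k == 0:
                use = exons
            else:
                drop = skippable[(k - 1) % len(skippable)]
                use = [ex for i, ex in enumerate(exons) if i != drop]
            gtf.append(_gtf_line(chrom, "transcript", use[0][0], use[-1][1],
                                 strand, gene_id=gene_id, transcript_id=tid))
            for s, e in use:
                gtf.append(_gtf_line(chrom, "exon", s, e, strand,
                                     gene_id=gene_id, transcript_id=tid))
            exon_map[tid] = (chrom, strand, list(use))
            tids.append(tid)
        gene_map[gene_id] = tids

    genome = {chrom: "".join(pieces)}
    for tid, (c, strand, use) in exon_map.items():
        spliced = "".join(genome[c][s:e] for s, e in use)
        if strand == "-":
            spliced = spliced.translate(_COMPLEMENT)[::-1]
        transcripts[tid] = spliced
    return ToyReference(
        genome=genome,
        transcripts=transcripts,
        gtf_lines=gtf,
        gene_to_transcripts=gene_map,
        exons=exon_map,
    )


def _gtf_line(chrom: str, feature: str, start0: int, end: int, strand: str,
              gene_id: str, transcript_id: str | None = None) -> str:
    attrs = f'gene_id "{gene_id}";'
    if transcript_id is not None:
        attrs += f' transcript_id "{transcript_id}";'
    # GTF coordinates are 1-based closed
    return "\t".join(
        [chrom, "scnanosim", feature, str(start0 + 1), str(end), ".", strand, ".", attrs]
    )


def write_toy_reference(ref: ToyReference, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "transcripts": out_dir / "transcripts.fa",
        "gtf": out_dir / "annotation.gtf",
    }
    with open(paths["genome"], "w") as fh:
        for name, seq in ref.genome.items():
            fh.write(f">{name}\n{seq}\n")
    with open(paths["transcripts"], "w") as fh:
        for tid, seq in ref.transcripts.items():
            fh.write(f">{tid}\n{seq}\n")
    with open(paths["gtf"], "w") as fh:
        fh.write("\n".join(ref.gtf_lines) + "\n")
    return paths


def make_synthetic_paf(
    out_path: str | Path,
    n_records: int = 100,
    truncation: tuple[float, float] = (0.25, 0.75),
    identity: float = 0.9,
    target_length: int = 1000,
    seed: int | np.random.Generator = 0,
) -> Path:
    """Construct PAF records realising exact truncation and identity values.

    Every record aligns to relative target coordinates ``truncation`` and
    carries a substitution-only CIGAR whose match count gives precisely the
    requested gap-included identity (the aligned span is adjusted so
    ``identity * span`` is integral).
    """
    if not 0.0 <= truncation[0] < truncation[1] <= 1.0:
        raise ValueError("truncation must satisfy 0 <= start < end <= 1")
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    out_path = Path(out_path)
    tstart = int(round(truncation[0] * target_length))
    tend = int(round(truncation[1] * target_length))
    span = tend - tstart
    matches = int(round(identity * span))
    if matches / span != identity:
        raise ValueError(
            f"identity {identity} is not exactly realisable over a span of "
            f"{span} columns; adjust target_length or truncation"
        )
    with open(out_path, "w") as fh:
        for i in range(n_records):
            rec = PafRecord(
                query_name=f"read_{i}",
                query_length=span,
                query_start=0,
                query_end=span,
                strand="+",
                target_name="tx_synthetic",
                target_length=target_length,
                target_start=tstart,
                target_end=tend,
                residue_matches=matches,
                block_length=span,
                mapping_quality=60,
                tags={"tp": "P", "cg": f"{span}M"},
            )
            fh.write(rec.to_line() + "\n")
    return out_path


def make_whitelist(
    n_barcodes: int,
    cb_length: int = 16,
    seed: int | np.random.Generator = 0,
    out_path: str | Path | None = None,
) -> list[str]:
    """Distinct random barcodes; optionally written one per line."""
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n_barcodes:
        bc = _random_seq(cb_length, rng)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    if out_path is not None:
        Path(out_path).write_text("\n".join(barcodes) + "\n")
    return barcodes


def make_toy_matrix(
    feature_ids: list[str],
    n_cells: int = 20,
    mean: float = 2.0,
    dispersion: float = 0.3,
    libsize_log_sd: float = 0.2,
    seed: int | np.random.Generator = 0,
) -> CountMatrix:
    """Small Gamma-Poisson matrix over the given features."""
    nf = len(feature_ids)
    params = CountModelParams(
        feature_mean=np.full(nf, mean),
        feature_dispersion=np.full(nf, dispersion),
        libsize_log_mean=float(np.log(max(mean * nf, 1.0))),
        libsize_log_sd=libsize_log_sd,
        feature_ids=list(feature_ids),
    )
    return simulate_counts(params, n_cells=n_cells, seed=seed)
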
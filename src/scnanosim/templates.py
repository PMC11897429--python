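"""Perfect-read generation.

Every UMI count in the matrix becomes one full-length cDNA molecule with the
10x Genomics + Nanopore library structure

    adapter + cell barcode + UMI + oligo(dT) + cDNA + TSO

For gene-level matrices a transcript of the gene is chosen with a softmax
prior favouring short cDNAs, ``P(t) ∝ exp(-L_t / tau)``.  Optionally a
molecule retains its introns (unspliced cDNA built from the genome), is
truncated according to an empirical truncation distribution estimated from
long-read alignments, and finally the whole molecule is emitted on either
strand with equal probability.  The resulting sequences carry no sequencing
errors at all, hence "perfect reads"; all provenance lives in a side table.
"""

from __future__ import annotations

import gzip
import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .counts import CountMatrix
from .paf import PafRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptomeIndex",
    "ReadStructure",
    "MoleculeRecord",
    "TruncationModel",
    "load_transcriptome",
    "pick_transcript",
    "unspliced_sequence",
    "estimate_truncation_model",
    "apply_truncation",
    "generate_umi",
    "assemble_molecule",
    "orient",
    "reverse_complement",
    "assign_barcodes",
    "generate_perfect_reads",
    "write_molecules_fasta",
    "write_ground_truth",
    "read_ground_truth",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.array(list("ACGT"))
_VERSION_RE = re.compile(r"\.\d+$")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _strip_version(identifier: str) -> str:
    return _VERSION_RE.sub("", identifier)


# ---------------------------------------------------------------------------
# reference handling


@dataclass
class TranscriptomeIndex:
    """Transcript sequences plus optional gene/exon/genome context.

    ``exon_structure`` maps transcript id -> (chromosome, strand, exons)
    with exons as sorted 0-based half-open genomic intervals.
    """

    transcript_seq: dict[str, str]
    gene_to_transcripts: dict[str, list[str]]
    transcript_to_gene: dict[str, str] = field(default_factory=dict)
    exon_structure: dict[str, tuple[str, str, list[tuple[int, int]]]] = field(
        default_factory=dict
    )
    genome_seq: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, tids in self.gene_to_transcripts.items():
            for tid in tids:
                if tid not in self.transcript_seq:
                    raise ValueError(
                        f"transcript '{tid}' of gene '{gene}' has no sequence"
                    )
        if not self.transcript_to_gene:
            self.transcript_to_gene = {
                t: g for g, ts in self.gene_to_transcripts.items() for t in ts
            }

    @property
    def n_transcripts(self) -> int:
        return len(self.transcript_seq)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_fasta(path: str | Path) -> dict[str, str]:
    with _open_maybe_gzip(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return seqs


def _parse_gtf_exons(gtf_path: str | Path):
    """Yield (gene_id, transcript_id, chrom, strand, start0, end) per exon."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    for exon in db.features_of_type("exon", order_by=("seqid", "start")):
        gene_id = exon.attributes.get("gene_id", [None])[0]
        tid = exon.attributes.get("transcript_id", [None])[0]
        if tid is None:
            continue
        # GTF is 1-based closed; convert to 0-based half-open.
        yield gene_id or tid, tid, exon.seqid, exon.strand, exon.start - 1, exon.end


def load_transcriptome(
    transcript_fasta: str | Path,
    annotation_gtf: str | Path | None = None,
    genome_fasta: str | Path | None = None,
) -> TranscriptomeIndex:
    """Build a :class:`TranscriptomeIndex` from a transcript FASTA.

    With a GTF the gene->transcript map and exon structures are taken from
    the annotation (transcript ids matched after stripping ``.N`` version
    suffixes); transcripts present in the GTF but absent from the FASTA are
    skipped with a warning.  Without a GTF every transcript is its own gene.
    A genome FASTA additionally enables intron-retained (unspliced) cDNAs.
    """
    transcript_seq = _read_fasta(transcript_fasta)
    if not transcript_seq:
        raise ValueError(f"no sequences in transcript FASTA {transcript_fasta}")
    by_stripped = {_strip_version(t): t for t in transcript_seq}

    gene_to_transcripts: dict[str, list[str]] = {}
    exon_structure: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}
    if annotation_gtf is not None:
        exons_by_tid: dict[str, list[tuple[str, str, int, int]]] = {}
        tid_gene: dict[str, str] = {}
        for gene_id, tid, chrom, strand, start, end in _parse_gtf_exons(annotation_gtf):
            exons_by_tid.setdefault(tid, []).append((chrom, strand, start, end))
            tid_gene[tid] = gene_id
        for tid, exons in exons_by_tid.items():
            fasta_tid = by_stripped.get(_strip_version(tid))
            if fasta_tid is None:
                warnings.warn(
                    f"transcript '{tid}' in GTF has no FASTA sequence; skipped"
                )
                continue
            chrom, strand = exons[0][0], exons[0][1]
            intervals = sorted((s, e) for _, _, s, e in exons)
            spliced_len = sum(e - s for s, e in intervals)
            if spliced_len != len(transcript_seq[fasta_tid]):
                warnings.warn(
                    f"exon length sum ({spliced_len}) of '{tid}' does not match "
                    f"its sequence length ({len(transcript_seq[fasta_tid])}); "
                    "exon structure dropped for this transcript"
                )
            else:
                exon_structure[fasta_tid] = (chrom, strand, intervals)
            gene = tid_gene[tid]
            gene_to_transcripts.setdefault(gene, []).append(fasta_tid)
    else:
        gene_to_transcripts = {t: [t] for t in transcript_seq}

    genome_seq = _read_fasta(genome_fasta) if genome_fasta is not None else {}
    return TranscriptomeIndex(
        transcript_seq=transcript_seq,
        gene_to_transcripts=gene_to_transcripts,
        exon_structure=exon_structure,
        genome_seq=genome_seq,
    )


def pick_transcript(
    gene_id: str,
    index: TranscriptomeIndex,
    tau: float = 2000.0,
    rng: np.random.Generator | None = None,
) -> str:
    """Choose one isoform of a gene, short transcripts preferred.

    Transcript ``t`` of length ``L_t`` is picked with probability
    proportional to ``exp(-L_t / tau)``; ``tau`` (nt) controls how sharply
    short isoforms dominate.
    """
    if gene_id not in index.gene_to_transcripts:
        raise KeyError(f"unknown gene '{gene_id}'")
    rng = rng or np.random.default_rng()
    tids = index.gene_to_transcripts[gene_id]
    if len(tids) == 1:
        return tids[0]
    lengths = np.array([len(index.transcript_seq[t]) for t in tids], dtype=float)
    w = np.exp(-(lengths - lengths.min()) / tau)  # shift for stability
    return tids[rng.choice(len(tids), p=w / w.sum())]


def unspliced_sequence(transcript_id: str, index: TranscriptomeIndex) -> str:
    """Intron-retained cDNA: genomic span of the transcript, stranded."""
    if transcript_id not in index.exon_structure or not index.genome_seq:
        raise ValueError(
            "intron retention requires a GTF annotation and a genome FASTA"
        )
    chrom, strand, exons = index.exon_structure[transcript_id]
    if chrom not in index.genome_seq:
        raise ValueError(f"chromosome '{chrom}' missing from genome FASTA")
    span = index.genome_seq[chrom][exons[0][0] : exons[-1][1]]
    return reverse_complement(span) if strand == "-" else span


# ---------------------------------------------------------------------------
# truncation


@dataclass
class TruncationModel:
    """Joint empirical distribution of relative (5' start, 3' end) retained
    cDNA endpoints, binned on [0, 1] x [0, 1].

    Sampling draws a bin by its probability, then a uniform point inside
    the bin; a zero-width bin yields its boundary value exactly (the
    full-length model is the degenerate case start = 0, end = 1).
    """

    start_edges: np.ndarray  # len n_start_bins + 1
    end_edges: np.ndarray  # len n_end_bins + 1
    probs: np.ndarray  # shape (n_start_bins, n_end_bins), sums to 1

    def __post_init__(self) -> None:
        self.start_edges = np.asarray(self.start_edges, dtype=float)
        self.end_edges = np.asarray(self.end_edges, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0) or not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("truncation probabilities must be >= 0 and sum to 1")

    @classmethod
    def full_length(cls) -> "TruncationModel":
        return cls(
            start_edges=np.array([0.0, 0.0]),
            end_edges=np.array([1.0, 1.0]),
            probs=np.array([[1.0]]),
        )

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        flat = rng.choice(self.probs.size, p=self.probs.ravel())
        i, j = np.unravel_index(flat, self.probs.shape)
        s_lo, s_hi = self.start_edges[i], self.start_edges[i + 1]
        e_lo, e_hi = self.end_edges[j], self.end_edges[j + 1]
        rel_start = s_lo if s_hi == s_lo else rng.uniform(s_lo, s_hi)
        rel_end = e_lo if e_hi == e_lo else rng.uniform(e_lo, e_hi)
        return float(rel_start), float(rel_end)


def estimate_truncation_model(
    alignments: Iterable[PafRecord], n_bins: int = 50
) -> TruncationModel:
    """Estimate the truncation distribution from transcriptome alignments.

    Each primary alignment contributes one (target_start/target_length,
    target_end/target_length) point; points are binned into an
    ``n_bins`` x ``n_bins`` joint histogram and normalised.
    """
    starts, ends = [], []
    for rec in alignments:
        if not rec.is_primary or rec.target_length <= 0:
            continue
        starts.append(rec.target_start / rec.target_length)
        ends.append(rec.target_end / rec.target_length)
    if not starts:
        raise ValueError("no usable primary alignments for truncation estimation")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _, _ = np.histogram2d(starts, ends, bins=[edges, edges])
    return TruncationModel(
        start_edges=edges, end_edges=edges, probs=hist / hist.sum()
    )


def apply_truncation(
    cdna: str, model: TruncationModel, rng: np.random.Generator
) -> tuple[str, int, int]:
    """Truncate a cDNA according to the model; retains at least 1 nt."""
    if not cdna:
        raise ValueError("empty cDNA")
    length = len(cdna)
    rel_start, rel_end = model.sample(rng)
    start = int(np.floor(rel_start * length))
    end = int(np.ceil(rel_end * length))
    start = min(max(start, 0), length - 1)
    end = min(max(end, start + 1), length)
    return cdna[start:end], start, end


# ---------------------------------------------------------------------------
# molecule assembly

# 10x Chromium 3' v3 geometry; the adapter is the partial read-1 primer as it
# appears at the 5' end of Nanopore reads of such libraries, the TSO sequence
# closes the construct.  Both are configuration defaults, not protocol law.
DEFAULT_ADAPTER = "CTACACGACGCTCTTCCGATCT"
DEFAULT_TSO = "ATGTACTCTGCGTTGATACCACTGCTT"


@dataclass
class ReadStructure:
    """Layout of the library construct around the cDNA insert."""

    adapter: str = DEFAULT_ADAPTER
    tso: str = DEFAULT_TSO
    cb_length: int = 16
    umi_length: int = 12
    polyt_length: int = 20

    def __post_init__(self) -> None:
        for name, seq in (("adapter", self.adapter), ("tso", self.tso)):
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty A/C/G/T string")
        if min(self.cb_length, self.umi_length, self.polyt_length) < 1:
            raise ValueError("cb_length, umi_length and polyt_length must be >= 1")


@dataclass(slots=True)
class MoleculeRecord:
    """One simulated cDNA library molecule plus its ground truth."""

    read_id: str
    cell_barcode: str
    umi: str
    gene_id: str
    transcript_id: str
    strand: str
    trunc_start: int
    trunc_end: int
    sequence: str
    unspliced: bool = False


def generate_umi(umi_length: int, rng: np.random.Generator) -> str:
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    return "".join(_BASES[rng.integers(0, 4, size=umi_length)])


def assemble_molecule(
    cell_barcode: str, umi: str, cdna_fragment: str, structure: ReadStructure
) -> str:
    """Concatenate adapter + CB + UMI + oligo(dT) + cDNA + TSO."""
    if len(cell_barcode) != structure.cb_length:
        raise ValueError(
            f"barcode length {len(cell_barcode)} != cb_length {structure.cb_length}"
        )
    if len(umi) != structure.umi_length:
        raise ValueError(
            f"UMI length {len(umi)} != umi_length {structure.umi_length}"
        )
    return (
        structure.adapter
        + cell_barcode
        + umi
        + "T" * structure.polyt_length
        + cdna_fragment
        + structure.tso
    )


def orient(sequence: str, rng: np.random.Generator) -> tuple[str, str]:
    """Return the sequence on a random strand (+ unchanged, - revcomp)."""
    if rng.random() < 0.5:
        return reverse_complement(sequence), "-"
    return sequence, "+"


def assign_barcodes(
    cell_ids: Sequence[str],
    whitelist: Sequence[str] | None,
    cb_length: int,
    rng: np.random.Generator,
) -> dict[str, str]:
    """Map matrix cell ids to cell barcodes.

    Cell ids that already are valid barcodes (A/C/G/T of the right length)
    are used verbatim; otherwise barcodes are drawn without replacement from
    the whitelist, or generated as random distinct ``cb_length``-mers when
    no whitelist is given.
    """
    ids = list(cell_ids)
    if all(len(c) == cb_length and not set(c) - set("ACGT") for c in ids):
        return {c: c for c in ids}
    if whitelist is not None:
        pool = list(dict.fromkeys(whitelist))
        if len(pool) < len(ids):
            raise ValueError(
                f"whitelist has {len(pool)} barcodes for {len(ids)} cells"
            )
        chosen = rng.choice(len(pool), size=len(ids), replace=False)
        return {c: pool[k] for c, k in zip(ids, chosen)}
    seen: set[str] = set()
    mapping: dict[str, str] = {}
    for c in ids:
        while True:
            bc = "".join(_BASES[rng.integers(0, 4, size=cb_length)])
            if bc not in seen:
                seen.add(bc)
                mapping[c] = bc
                break
    return mapping


def generate_perfect_reads(
    matrix: CountMatrix,
    index: TranscriptomeIndex,
    structure: ReadStructure | None = None,
    truncation: TruncationModel | None = None,
    whitelist: Sequence[str] | None = None,
    intron_retention_prob: float = 0.0,
    tau: float = 2000.0,
    seed: int | np.random.Generator = 0,
) -> list[MoleculeRecord]:
    """Emit one perfect read per UMI count.

    Exactly ``matrix[f, c]`` molecules are produced for every (feature,
    cell) pair, each with a freshly drawn UMI.  Features are resolved first
    as genes (isoform picked per the length prior), then as transcripts.
    """
    structure = structure or ReadStructure()
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    if not 0.0 <= intron_retention_prob <= 1.0:
        raise ValueError("intron_retention_prob must be in [0, 1]")

    by_stripped = {_strip_version(t): t for t in index.transcript_seq}
    unresolved = [
        f
        for f in matrix.feature_ids
        if f not in index.gene_to_transcripts and _strip_version(f) not in by_stripped
    ]
    if unresolved:
        raise KeyError(
            "features not found in transcriptome (as gene or transcript): "
            + ", ".join(unresolved[:10])
            + ("..." if len(unresolved) > 10 else "")
        )
    barcode_of = assign_barcodes(
        matrix.cell_barcodes, whitelist, structure.cb_length, rng
    )

    records: list[MoleculeRecord] = []
    serial = 0
    for fi, feature in enumerate(matrix.feature_ids):
        is_gene = feature in index.gene_to_transcripts
        for ci, cell in enumerate(matrix.cell_barcodes):
            for _ in range(int(matrix.counts[fi, ci])):
                tid = (
                    pick_transcript(feature, index, tau=tau, rng=rng)
                    if is_gene
                    else by_stripped[_strip_version(feature)]
                )
                unspliced = (
                    intron_retention_prob > 0
                    and tid in index.exon_structure
                    and bool(index.genome_seq)
                    and rng.random() < intron_retention_prob
                )
                cdna = unspliced_sequence(tid, index) if unspliced else index.transcript_seq[tid]
                if truncation is not None:
                    fragment, t_start, t_end = apply_truncation(cdna, truncation, rng)
                else:
                    fragment, t_start, t_end = cdna, 0, len(cdna)
                umi = generate_umi(structure.umi_length, rng)
                assembled = assemble_molecule(barcode_of[cell], umi, fragment, structure)
                oriented, strand = orient(assembled, rng)
                records.append(
                    MoleculeRecord(
                        read_id=f"mol_{serial:08d}",
                        cell_barcode=barcode_of[cell],
                        umi=umi,
                        gene_id=feature if is_gene else index.transcript_to_gene.get(tid, tid),
                        transcript_id=tid,
                        strand=strand,
                        trunc_start=t_start,
                        trunc_end=t_end,
                        sequence=oriented,
                        unspliced=unspliced,
                    )
                )
                serial += 1
    logger.info("generated %d perfect reads", len(records))
    return records


# ---------------------------------------------------------------------------
# artifact I/O

GROUND_TRUTH_COLUMNS = [
    "read_id",
    "cell_barcode",
    "umi",
    "gene_id",
    "transcript_id",
    "strand",
    "trunc_start",
    "trunc_end",
    "unspliced",
]


def write_molecules_fasta(records: Iterable[MoleculeRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.read_id}\n{rec.sequence}\n")
    return path


def write_ground_truth(records: Iterable[MoleculeRecord], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(GROUND_TRUTH_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.read_id}\t{r.cell_barcode}\t{r.umi}\t{r.gene_id}\t"
                f"{r.transcript_id}\t{r.strand}\t{r.trunc_start}\t{r.trunc_end}\t"
                f"{int(r.unspliced)}\n"
            )
    return path


def read_ground_truth(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
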
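"""Sequencing-error simulation driven by a beta read-identity model.

Nanopore read accuracy varies read-to-read; the marginal distribution of
per-read alignment identity is well described by a beta distribution.  The
model is fitted to identities computed from long-read alignments (PAF), with
the three standard identity definitions:

* ``gap_included``   — matches / all alignment columns (gaps count),
* ``gap_excluded``   — matches / non-gap columns,
* ``gap_compressed`` — matches / (non-gap columns + number of gap runs).

At simulation time each template read draws a target identity from the
fitted Beta(alpha, beta); ``round(L * (1 - identity))`` error events are
placed uniformly along the read, each event a substitution, insertion or
deletion according to the error profile.  Per-base Phred qualities reflect
the read's realised error rate with integer jitter, a deliberately simple
stand-in for basecaller quality strings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from scipy import stats

from .paf import PafRecord

logger = logging.getLogger(__name__)

__all__ = [
    "IdentityModel",
    "ErrorProfile",
    "alignment_identity",
    "fit_identity_beta",
    "sample_read_identity",
    "inject_errors",
    "simulate_fastq",
]

IDENTITY_MODES = ("gap_included", "gap_excluded", "gap_compressed")
_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}
_CLAMP = 1e-6


@dataclass
class IdentityModel:
    """Beta(alpha, beta) distribution over per-read alignment identity."""

    alpha: float
    beta: float
    identity_mode: str = "gap_included"

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.identity_mode not in IDENTITY_MODES:
            raise ValueError(f"identity_mode must be one of {IDENTITY_MODES}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass
class ErrorProfile:
    """Mixture of error-event types and the quality-score cap."""

    p_sub: float = 1.0 / 3.0
    p_ins: float = 1.0 / 3.0
    p_del: float = 1.0 / 3.0
    max_quality: int = 40

    def __post_init__(self) -> None:
        total = self.p_sub + self.p_ins + self.p_del
        if min(self.p_sub, self.p_ins, self.p_del) < 0 or not np.isclose(total, 1.0):
            raise ValueError("p_sub + p_ins + p_del must be 1 with each >= 0")


def alignment_identity(record: PafRecord, mode: str = "gap_included") -> float:
    """Per-alignment sequence identity under one of three definitions.

    ``gap_included`` uses the PAF block length as the column count; the two
    gap-aware definitions require a ``cg`` CIGAR tag.
    """
    if mode not in IDENTITY_MODES:
        raise ValueError(f"unknown identity mode '{mode}'")
    if record.block_length <= 0:
        raise ValueError(f"zero-length alignment for query '{record.query_name}'")
    if mode == "gap_included":
        return record.residue_matches / record.block_length
    cigar = record.cigar
    if cigar is None:
        raise ValueError(
            f"identity mode '{mode}' needs a cg CIGAR tag "
            f"(query '{record.query_name}')"
        )
    aligned_cols = sum(n for n, op in cigar if op in "M=X")
    gap_runs = sum(1 for _, op in cigar if op in "ID")
    if aligned_cols == 0:
        raise ValueError("CIGAR contains no aligned columns")
    if mode == "gap_excluded":
        return record.residue_matches / aligned_cols
    return record.residue_matches / (aligned_cols + gap_runs)


def fit_identity_beta(
    identities: Iterable[float], identity_mode: str = "gap_included"
) -> IdentityModel:
    """Fit Beta(alpha, beta) to observed identities.

    Values are clamped to [1e-6, 1 - 1e-6] (the beta likelihood is undefined
    at the boundaries), initialised by method of moments and refined by
    maximum likelihood.  Needs at least 10 usable values with non-zero
    variance.
    """
    x = np.clip(np.asarray(list(identities), dtype=float), _CLAMP, 1.0 - _CLAMP)
    if x.size < 10:
        raise ValueError(f"need >= 10 identity values, got {x.size}")
    m, v = float(x.mean()), float(x.var(ddof=1))
    if v < 1e-12:
        raise ValueError(
            "identities have zero variance; use a fixed identity instead of a beta fit"
        )
    common = m * (1.0 - m) / v - 1.0
    a0, b0 = max(m * common, _CLAMP), max((1.0 - m) * common, _CLAMP)
    try:
        a, b, _, _ = stats.beta.fit(x, a0, b0, floc=0.0, fscale=1.0)
    except Exception:  # MLE failure: keep the moment estimate
        a, b = a0, b0
    model = IdentityModel(alpha=float(a), beta=float(b), identity_mode=identity_mode)
    if abs(model.mean - m) > 1e-3:
        logger.warning(
            "beta MLE mean %.4f deviates from sample mean %.4f; "
            "falling back to moment estimates",
            model.mean,
            m,
        )
        model = IdentityModel(alpha=a0, beta=b0, identity_mode=identity_mode)
    return model


def sample_read_identity(model: IdentityModel, rng: np.random.Generator) -> float:
    """One beta draw, kept strictly inside (0, 1)."""
    return float(np.clip(rng.beta(model.alpha, model.beta), _CLAMP, 1.0 - _CLAMP))


def _quality_string(length: int, error_rate: float, max_quality: int,
                    rng: np.random.Generator) -> str:
    base_q = -10.0 * np.log10(max(error_rate, 1e-4))
    q = np.rint(base_q + rng.integers(-3, 4, size=length)).astype(int)
    q = np.clip(q, 2, max_quality)
    return "".join(chr(33 + int(v)) for v in q)


def inject_errors(
    sequence: str,
    target_identity: float,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Inject ``round(L * (1 - target_identity))`` error events into a read.

    Event positions are uniform without replacement; event types follow the
    profile.  Substitutions change the base, insertions add a random base
    before the position, deletions drop the base.  Returns the read and a
    Phred quality string of matching length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not 0.0 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0, 1]")
    length = len(sequence)
    n_events = int(round(length * (1.0 - target_identity)))
    if n_events == 0:
        return sequence, chr(33 + profile.max_quality) * length

    positions = np.sort(rng.choice(length, size=min(n_events, length), replace=False))
    kinds = rng.choice(3, size=positions.size, p=[profile.p_sub, profile.p_ins, profile.p_del])
    out: list[str] = []
    prev = 0
    for pos, kind in zip(positions.tolist(), kinds.tolist()):
        out.append(sequence[prev:pos])
        base = sequence[pos]
        if kind == 0:  # substitution
            out.append(_OTHER[base][rng.integers(0, 3)] if base in _OTHER else base)
        elif kind == 1:  # insertion before this base
            out.append(_BASES[rng.integers(0, 4)])
            out.append(base)
        # kind == 2: deletion, emit nothing
        prev = pos + 1
    out.append(sequence[prev:])
    read = "".join(out)
    realized_rate = positions.size / max(length, 1)
    qual = _quality_string(len(read), realized_rate, profile.max_quality, rng)
    return read, qual


def simulate_fastq(
    templates_fasta: str | Path,
    model: IdentityModel,
    profile: ErrorProfile,
    rng: np.random.Generator,
    out_fastq: str | Path,
) -> int:
    """Turn template reads into error-bearing FASTQ, one record per template.

    Read ids are preserved so every FASTQ record links back to its ground
    truth.  Returns the number of records written.
    """
    n = 0
    with open(templates_fasta) as fin, open(out_fastq, "w") as fout:
        for title, seq in SimpleFastaParser(fin):
            read_id = title.split()[0]
            identity = sample_read_identity(model, rng)
            read, qual = inject_errors(seq.upper(), identity, profile, rng)
            fout.write(f"@{read_id}\n{read}\n+\n{qual}\n")
            n += 1
    if n == 0:
        warnings.warn(f"no templates in {templates_fasta}; wrote empty FASTQ")
    logger.info("wrote %d error-bearing reads to %s", n, out_fastq)
    return n
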
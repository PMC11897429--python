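"""End-to-end orchestration: counts -> perfect reads -> PCR -> errors -> QC.

A :class:`SimulationConfig` mirrors the CLI flags section by section; every
stage seed is spawned deterministically from the single global seed, so a
config plus a seed fully determines every output byte.  A manifest records
parameters, per-stage seeds and SHA-256 checksums of all artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .counts import (
    CountMatrix,
    estimate_count_params,
    read_count_matrix,
    simulate_counts,
    write_count_matrix,
)
from .errors import ErrorProfile, IdentityModel, alignment_identity, fit_identity_beta, simulate_fastq
from .paf import read_paf
from .pcr import PCRParams, pcr_amplify, subsample_pool
from .qc import compute_qc, render_report
from .templates import (
    ReadStructure,
    estimate_truncation_model,
    generate_perfect_reads,
    load_transcriptome,
    write_ground_truth,
    write_molecules_fasta,
)

logger = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class SimulationConfig:
    # inputs
    matrix: str | None = None
    transcriptome: str | None = None
    gtf: str | None = None
    genome: str | None = None
    whitelist: str | None = None
    paf: str | None = None
    # counts stage: resimulate a matrix from the input matrix when n_cells set
    counts_n_cells: int | None = None
    # templates stage
    tau: float = 2000.0
    intron_retention_prob: float = 0.0
    truncation_bins: int = 50
    cb_length: int = 16
    umi_length: int = 12
    # pcr stage (cycles = 0 disables)
    pcr_cycles: int = 0
    pcr_p_dup: float = 0.9
    pcr_p_error: float = 3.5e-5
    pcr_sample_size: int | None = None
    # errors stage
    identity_alpha: float = 38.0
    identity_beta: float = 2.0
    identity_mode: str = "gap_included"
    p_sub: float = 1.0 / 3.0
    p_ins: float = 1.0 / 3.0
    p_del: float = 1.0 / 3.0
    # global
    outdir: str = "scnanosim_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):  # per-stage sections
                for k, v in val.items():
                    flat[f"{key}_{k}" if f"{key}_{k}" in _FIELDS else k] = v
            else:
                flat[key] = val
        unknown = set(flat) - _FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)


_FIELDS = {f.name for f in dataclasses.fields(SimulationConfig)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: SimulationConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    stage_rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(("counts", "templates", "pcr", "errors", "qc"), seeds)
    }
    artifacts: dict[str, Path] = {}

    # -- counts ------------------------------------------------------------
    try:
        if config.matrix is None:
            raise ValueError("a count matrix CSV is required (config key 'matrix')")
        matrix = read_count_matrix(config.matrix)
        if config.counts_n_cells is not None:
            params = estimate_count_params(matrix)
            matrix = simulate_counts(
                params, n_cells=config.counts_n_cells, seed=stage_rngs["counts"]
            )
        artifacts["matrix"] = write_count_matrix(matrix, outdir / "matrix.csv")
    except Exception as exc:
        raise PipelineError(f"counts stage failed: {exc}") from exc

    # -- templates ---------------------------------------------------------
    try:
        if config.transcriptome is None:
            raise ValueError("a transcriptome FASTA is required")
        index = load_transcriptome(config.transcriptome, config.gtf, config.genome)
        truncation = None
        if config.paf is not None:
            truncation = estimate_truncation_model(
                read_paf(config.paf), n_bins=config.truncation_bins
            )
        whitelist = None
        if config.whitelist is not None:
            whitelist = [
                line.strip()
                for line in Path(config.whitelist).read_text().splitlines()
                if line.strip()
            ]
        structure = ReadStructure(
            cb_length=config.cb_length, umi_length=config.umi_length
        )
        molecules = generate_perfect_reads(
            matrix,
            index,
            structure,
            truncation=truncation,
            whitelist=whitelist,
            intron_retention_prob=config.intron_retention_prob,
            tau=config.tau,
            seed=stage_rngs["templates"],
        )
        artifacts["perfect_fasta"] = write_molecules_fasta(
            molecules, outdir / "perfect_reads.fasta"
        )
        artifacts["ground_truth"] = write_ground_truth(
            molecules, outdir / "ground_truth.tsv"
        )
        barcodes = sorted({m.cell_barcode for m in molecules})
        wl_path = outdir / "whitelist.txt"
        wl_path.write_text("\n".join(barcodes) + ("\n" if barcodes else ""))
        artifacts["whitelist"] = wl_path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"templates stage failed: {exc}") from exc

    # -- pcr (optional) ----------------------------------------------------
    template_fasta = artifacts["perfect_fasta"]
    if config.pcr_cycles > 0:
        try:
            params = PCRParams(
                cycles=config.pcr_cycles,
                p_dup=config.pcr_p_dup,
                p_error=config.pcr_p_error,
                sample_size=config.pcr_sample_size,
            )
            pool = pcr_amplify(molecules, params, stage_rngs["pcr"])
            if params.sample_size is not None:
                pool = subsample_pool(
                    pool, min(params.sample_size, len(pool)), stage_rngs["pcr"]
                )
            amp_fasta = outdir / "amplified_reads.fasta"
            amp_tsv = outdir / "amplified_ground_truth.tsv"
            truth = {m.read_id: m for m in molecules}
            with open(amp_fasta, "w") as fa, open(amp_tsv, "w") as tsv:
                tsv.write(
                    "read_id\torigin_read_id\tn_mutations\tcell_barcode\tumi\t"
                    "gene_id\ttranscript_id\n"
                )
                for m in pool:
                    read_id = f"{m.origin_read_id}_amp{m.copy_serial}"
                    fa.write(f">{read_id}\n{m.sequence}\n")
                    t = truth[m.origin_read_id]
                    tsv.write(
                        f"{read_id}\t{m.origin_read_id}\t{m.n_mutations}\t"
                        f"{t.cell_barcode}\t{t.umi}\t{t.gene_id}\t{t.transcript_id}\n"
                    )
            artifacts["amplified_fasta"] = amp_fasta
            artifacts["amplified_ground_truth"] = amp_tsv
            template_fasta = amp_fasta
        except Exception as exc:
            raise PipelineError(f"pcr stage failed: {exc}") from exc

    # -- errors ------------------------------------------------------------
    try:
        if config.paf is not None:
            identities = [
                alignment_identity(rec, config.identity_mode)
                for rec in read_paf(config.paf)
                if rec.is_primary
            ]
            try:
                model = fit_identity_beta(identities, config.identity_mode)
            except ValueError as exc:
                logger.warning(
                    "identity fit from PAF failed (%s); using configured alpha/beta",
                    exc,
                )
                model = IdentityModel(
                    config.identity_alpha, config.identity_beta, config.identity_mode
                )
        else:
            model = IdentityModel(
                config.identity_alpha, config.identity_beta, config.identity_mode
            )
        profile = ErrorProfile(p_sub=config.p_sub, p_ins=config.p_ins, p_del=config.p_del)
        fastq = outdir / "simulated_reads.fastq"
        n_reads = simulate_fastq(template_fasta, model, profile, stage_rngs["errors"], fastq)
        artifacts["fastq"] = fastq
    except Exception as exc:
        raise PipelineError(f"errors stage failed: {exc}") from exc

    # -- qc ----------------------------------------------------------------
    try:
        metrics = compute_qc(fastq)
        artifacts["report"] = render_report(metrics, outdir / "report.html")
        artifacts["metrics"] = outdir / "report.json"
    except Exception as exc:
        raise PipelineError(f"qc stage failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            name: list(map(int, s.generate_state(2)))
            for name, s in zip(("counts", "templates", "pcr", "errors", "qc"), seeds)
        },
        "config": dataclasses.asdict(config),
        "n_reads": n_reads,
        "checksums": {k: _sha256(p) for k, p in artifacts.items()},
        "artifacts": {k: str(p) for k, p in artifacts.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d reads in %s", n_reads, fastq)
    return manifest
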
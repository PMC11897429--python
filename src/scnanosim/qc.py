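"""Quality-control summary of a simulated FASTQ: counts, lengths, qualities,
GC content, rendered as a standalone HTML report plus a JSON sidecar."""

from __future__ import annotations

import base64
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["QCMetrics", "compute_qc", "render_report", "load_metrics"]

_QUALITY_BINS = np.arange(0, 61, 1)  # per-read mean Phred, integer bins


@dataclass
class QCMetrics:
    n_reads: int
    length_quantiles: dict[str, float]
    mean_quality_hist: dict[str, list[float]]  # {"edges": ..., "counts": ...}
    length_hist: dict[str, list[float]]
    gc_fraction: float

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        q = [self.length_quantiles[k] for k in ("min", "q25", "median", "q75", "max")]
        if any(b < a for a, b in zip(q, q[1:])):
            raise ValueError("length quantiles must be non-decreasing")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")


def compute_qc(fastq: str | Path) -> QCMetrics:
    """One streaming pass over a FASTQ file."""
    lengths: list[int] = []
    mean_quals: list[float] = []
    gc = 0
    total = 0
    with open(fastq) as fh:
        for _, seq, qual in FastqGeneralIterator(fh):
            lengths.append(len(seq))
            phred = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33
            mean_quals.append(float(phred.mean()) if len(phred) else 0.0)
            s = seq.upper()
            gc += s.count("G") + s.count("C")
            total += len(s)
    if not lengths:
        raise ValueError(f"no reads in {fastq}")
    arr = np.array(lengths, dtype=float)
    qhist, _ = np.histogram(mean_quals, bins=_QUALITY_BINS)
    n_len_bins = min(50, max(5, int(np.sqrt(len(arr)))))
    lhist, ledges = np.histogram(arr, bins=n_len_bins)
    return QCMetrics(
        n_reads=len(lengths),
        length_quantiles={
            "min": float(arr.min()),
            "q25": float(np.quantile(arr, 0.25)),
            "median": float(np.quantile(arr, 0.5)),
            "q75": float(np.quantile(arr, 0.75)),
            "max": float(arr.max()),
        },
        mean_quality_hist={
            "edges": _QUALITY_BINS.tolist(),
            "counts": qhist.tolist(),
        },
        length_hist={"edges": ledges.tolist(), "counts": lhist.tolist()},
        gc_fraction=gc / total if total else 0.0,
    )


def _hist_png(edges, counts, xlabel: str) -> str:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3), dpi=90)
    edges = np.asarray(edges, dtype=float)
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="#4878a8", edgecolor="none")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("reads")
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", metadata={"Software": None})
    plt.close(fig)
    return base64.b64encode(buf.getvalue()).decode()


def render_report(metrics: QCMetrics, out_html: str | Path) -> Path:
    """Write a standalone HTML report and a sibling ``.json`` metrics file.

    The report embeds its plots as base64 PNG and contains no timestamps,
    so identical metrics render byte-identical files.
    """
    out_html = Path(out_html)
    json_path = out_html.with_suffix(".json")
    with open(json_path, "w") as fh:
        json.dump(asdict(metrics), fh, indent=1, sort_keys=True)

    lq = metrics.length_quantiles
    rows = "".join(
        f"<tr><td>{k}</td><td>{v}</td></tr>"
        for k, v in [
            ("reads", metrics.n_reads),
            ("min length (nt)", lq["min"]),
            ("Q25 length (nt)", lq["q25"]),
            ("median length (nt)", lq["median"]),
            ("Q75 length (nt)", lq["q75"]),
            ("max length (nt)", lq["max"]),
            ("GC fraction", round(metrics.gc_fraction, 4)),
        ]
    )
    len_png = _hist_png(
        metrics.length_hist["edges"], metrics.length_hist["counts"], "read length (nt)"
    )
    qual_png = _hist_png(
        metrics.mean_quality_hist["edges"],
        metrics.mean_quality_hist["counts"],
        "mean read Phred quality",
    )
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>scnanosim QC report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; color: #222; }}
table {{ border-collapse: collapse; }}
td {{ border: 1px solid #bbb; padding: 4px 10px; }}
h1 {{ font-size: 1.4em; }} h2 {{ font-size: 1.1em; }}
</style></head><body>
<h1>Simulated-read QC report</h1>
<h2>Summary</h2>
<table>{rows}</table>
<h2>Read length distribution</h2>
<img src="data:image/png;base64,{len_png}" alt="length histogram"/>
<h2>Mean read quality distribution</h2>
<img src="data:image/png;base64,{qual_png}" alt="quality histogram"/>
</body></html>
"""
    out_html.write_text(html)
    return out_html


def load_metrics(json_path: str | Path) -> QCMetrics:
    with open(json_path) as fh:
        return QCMetrics(**json.load(fh))
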
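"""Minimal PAF (pairwise mapping format) records.

PAF is the 12-column tab-separated format emitted by minimap2 and friends,
with optional SAM-style typed tags from column 13 on.  Only the fields the
truncation and identity estimators need are modelled.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = ["PafRecord", "parse_paf", "read_paf"]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class PafRecord:
    query_name: str
    query_length: int
    query_start: int
    query_end: int
    strand: str
    target_name: str
    target_length: int
    target_start: int
    target_end: int
    residue_matches: int
    block_length: int
    mapping_quality: int
    tags: dict[str, str] = field(default_factory=dict)

    @property
    def is_primary(self) -> bool:
        # tp:A:P marks primary alignments; records without the tag are kept.
        return self.tags.get("tp", "P") == "P"

    @property
    def cigar(self) -> list[tuple[int, str]] | None:
        cg = self.tags.get("cg")
        if cg is None:
            return None
        ops = _CIGAR_RE.findall(cg)
        if "".join(f"{n}{op}" for n, op in ops) != cg:
            raise ValueError(f"malformed CIGAR string: {cg!r}")
        return [(int(n), op) for n, op in ops]

    def to_line(self) -> str:
        fields = [
            self.query_name,
            str(self.query_length),
            str(self.query_start),
            str(self.query_end),
            self.strand,
            self.target_name,
            str(self.target_length),
            str(self.target_start),
            str(self.target_end),
            str(self.residue_matches),
            str(self.block_length),
            str(self.mapping_quality),
        ]
        for key, val in self.tags.items():
            typ = "A" if key == "tp" else ("Z" if key == "cg" else "i")
            if key not in ("tp", "cg") and not val.lstrip("-").isdigit():
                typ = "Z"
            fields.append(f"{key}:{typ}:{val}")
        return "\t".join(fields)


def parse_paf(line: str) -> PafRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 12:
        raise ValueError(f"PAF line has {len(cols)} columns, expected >= 12")
    tags: dict[str, str] = {}
    for raw in cols[12:]:
        parts = raw.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return PafRecord(
        query_name=cols[0],
        query_length=int(cols[1]),
        query_start=int(cols[2]),
        query_end=int(cols[3]),
        strand=cols[4],
        target_name=cols[5],
        target_length=int(cols[6]),
        target_start=int(cols[7]),
        target_end=int(cols[8]),
        residue_matches=int(cols[9]),
        block_length=int(cols[10]),
        mapping_quality=int(cols[11]),
        tags=tags,
    )


def read_paf(path: str | Path) -> Iterator[PafRecord]:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                yield parse_paf(line)
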
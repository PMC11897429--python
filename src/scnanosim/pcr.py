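"""PCR amplification bias as a branching process.

Each cycle every molecule in the pool spawns one copy with probability
``p_dup`` (default 0.9), so the expected pool grows by ``(1 + p_dup)`` per
cycle.  Copies are made from the current, possibly already mutated template:
substitutions introduced early propagate to all descendants, which is what
creates UMI-duplicate families sharing errors.  Each copied base mutates
with probability ``p_error`` (default 3.5e-5); the per-copy mutation count
is drawn binomially and positions sampled, which is distributionally the
per-base Bernoulli model but fast at realistic rates.  Substitution-only:
copies keep their template's length.  A final uniform subsample mimics
loading only part of the product on the flowcell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .templates import MoleculeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PCRParams",
    "AmplifiedMolecule",
    "mutate_copy",
    "pcr_amplify",
    "subsample_pool",
    "amplification_stats",
]

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}

# refuse runs whose expected pool would not fit in memory
MAX_EXPECTED_POOL = 2e8


@dataclass
class PCRParams:
    cycles: int = 10
    p_dup: float = 0.9
    p_error: float = 3.5e-5
    sample_size: int | None = None

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if not 0.0 <= self.p_dup <= 1.0:
            raise ValueError("p_dup must be in [0, 1]")
        if not 0.0 <= self.p_error <= 1.0:
            raise ValueError("p_error must be in [0, 1]")
        if self.sample_size is not None and self.sample_size < 1:
            raise ValueError("sample_size must be positive")


@dataclass(slots=True)
class AmplifiedMolecule:
    """One molecule of the post-PCR pool.

    ``n_mutations`` counts substitutions relative to the original ancestor
    (cumulative along the lineage); ``n_new_mutations`` only those
    introduced when this copy was synthesised.  ``cycle`` is 0 for input
    molecules.
    """

    origin_read_id: str
    copy_serial: int
    sequence: str
    n_mutations: int = 0
    n_new_mutations: int = 0
    cycle: int = 0
    parent_serial: int = -1


def _mutate_positions(sequence: str, k: int, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute k uniformly chosen positions; N bases are left untouched."""
    length = len(sequence)
    positions = rng.choice(length, size=min(k, length), replace=False)
    chars = list(sequence)
    changed = 0
    for pos in positions:
        base = chars[pos]
        if base not in _OTHER:  # N and friends never mutate
            continue
        chars[pos] = _OTHER[base][rng.integers(0, 3)]
        changed += 1
    return "".join(chars), changed


def mutate_copy(
    sequence: str, p_error: float, rng: np.random.Generator
) -> tuple[str, int]:
    """Copy a sequence with Binomial(L, p_error) substitutions."""
    if p_error <= 0.0:
        return sequence, 0
    k = int(rng.binomial(len(sequence), p_error))
    if k == 0:
        return sequence, 0
    return _mutate_positions(sequence, k, rng)


def pcr_amplify(
    molecules: Sequence[MoleculeRecord],
    params: PCRParams,
    rng: np.random.Generator,
) -> list[AmplifiedMolecule]:
    """Amplify molecules through ``params.cycles`` PCR cycles.

    Expected final pool size is ``N * (1 + p_dup) ** cycles``; an overflow
    guard rejects configurations whose expectation exceeds
    ``MAX_EXPECTED_POOL`` molecules.
    """
    n0 = len(molecules)
    expected = n0 * (1.0 + params.p_dup) ** params.cycles
    if expected > MAX_EXPECTED_POOL:
        raise ValueError(
            f"expected pool size {expected:.3g} exceeds {MAX_EXPECTED_POOL:.0e}; "
            "reduce cycles or the number of input molecules"
        )
    pool: list[AmplifiedMolecule] = [
        AmplifiedMolecule(
            origin_read_id=m.read_id, copy_serial=i, sequence=m.sequence
        )
        for i, m in enumerate(molecules)
    ]
    serial = n0
    for cycle in range(1, params.cycles + 1):
        n = len(pool)
        if params.p_dup >= 1.0:
            dup_idx = np.arange(n)
        else:
            dup_idx = np.flatnonzero(rng.random(n) < params.p_dup)
        if dup_idx.size == 0:
            continue
        if params.p_error > 0.0:
            lengths = np.fromiter(
                (len(pool[i].sequence) for i in dup_idx), dtype=np.int64, count=dup_idx.size
            )
            n_muts = rng.binomial(lengths, params.p_error)
        else:
            n_muts = np.zeros(dup_idx.size, dtype=np.int64)
        for i, k in zip(dup_idx.tolist(), n_muts.tolist()):
            template = pool[i]
            if k:
                seq, changed = _mutate_positions(template.sequence, k, rng)
            else:
                seq, changed = template.sequence, 0  # shares the string
            pool.append(
                AmplifiedMolecule(
                    origin_read_id=template.origin_read_id,
                    copy_serial=serial,
                    sequence=seq,
                    n_mutations=template.n_mutations + changed,
                    n_new_mutations=changed,
                    cycle=cycle,
                    parent_serial=template.copy_serial,
                )
            )
            serial += 1
        logger.debug("cycle %d: pool size %d", cycle, len(pool))
    return pool


def subsample_pool(
    pool: Sequence[AmplifiedMolecule], n: int, rng: np.random.Generator
) -> list[AmplifiedMolecule]:
    """Uniform sample of n molecules without replacement, order randomised."""
    if n > len(pool):
        raise ValueError(f"cannot sample {n} from a pool of {len(pool)}")
    idx = rng.permutation(len(pool))[:n]
    return [pool[i] for i in idx]


def amplification_stats(pool: Sequence[AmplifiedMolecule]) -> dict[str, int]:
    """Totals over all copies made during amplification (inputs excluded)."""
    duplicated_bases = 0
    mutation_events = 0
    n_copies = 0
    for m in pool:
        if m.cycle > 0:
            n_copies += 1
            duplicated_bases += len(m.sequence)
            mutation_events += m.n_new_mutations
    return {
        "n_copies": n_copies,
        "duplicated_bases": duplicated_bases,
        "mutation_events": mutation_events,
    }
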
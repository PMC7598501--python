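"""Small shared helpers: seeding, rounding, interval arithmetic."""

from __future__ import annotations

import hashlib
import math

import numpy as np

_MOD31 = 2**31


def derive_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed.

    Deterministic scheme (documented so stages can be re-run in isolation):
    SHA-256 of ``"{global_seed}:{stage}"`` reduced modulo 2^31.
    """
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % _MOD31


def rng_for(global_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, stage))


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (Python's round() is banker's rounding)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def expected_read_count(
    genome_length: int, coverage: float, read_length: int, paired: bool
) -> int:
    """Number of reads needed for a target coverage.

    Ceiling of coverage * genome_length / read_length, rounded up to the next
    even integer when the library is paired (pairs must be whole). For a
    204 Mb genome at 0.2x with 151 nt reads this yields 270,200.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    n = math.ceil(coverage * genome_length / read_length)
    if paired and n % 2:
        n += 1
    return n


def span_length_1based(start: int, end: int) -> int:
    """Length of a 1-based inclusive genomic span, e.g. 11651877-11652254 -> 378."""
    if end < start:
        raise ValueError("end < start")
    return end - start + 1


def orf_residues(orf_length_bp: int) -> int:
    """Residues encoded by an ORF including its stop codon: 378 bp -> 125 aa."""
    if orf_length_bp % 3:
        raise ValueError("ORF length must be a multiple of 3")
    return orf_length_bp // 3 - 1


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
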
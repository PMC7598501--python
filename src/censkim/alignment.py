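"""Pairwise ungapped overlap alignment of uniform-length reads.

Reads from tandem repeat arrays overlap each other at arbitrary monomer
phases, so similarity is scored over the best *dovetail* overlap: for a
relative shift s, read a positions [max(0,s), min(La, Lb+s)) are compared
to read b, in either orientation, and identity is matches / overlap
length.  The divergence model of the synthetic repeatome is
substitution-only, which makes ungapped scoring exact for its reads.

Candidate (pair, orientation, shift) triples come from shared k-mer seeds.
The seed length is chosen by a pigeonhole bound from the identity and
overlap thresholds, so every overlap that can qualify contains at least
one exact k-mer and seeding is lossless: the seeded edge set equals the
exhaustive all-shift comparison (verified against a brute-force oracle in
the tests).

BLAST-style bit scores for read-to-reference mapping use ungapped
Karlin-Altschul statistics with megablast scoring (match +1, mismatch -2,
lambda 1.28, K 0.46).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .reads import reverse_complement

# megablast ungapped scoring and Karlin-Altschul parameters
MATCH_REWARD = 1
MISMATCH_PENALTY = 2
KA_LAMBDA = 1.28
KA_K = 0.46

_ENC = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENC[b] = i
    _ENC[b + 32] = i


def encode(seq: str) -> np.ndarray:
    """2-bit-ish encoding; ambiguous bases get a sentinel that never matches."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()
    arr[arr == 255] = np.arange(4, 4 + int((arr == 255).sum())) % 251 + 4
    return arr


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2.0)


def raw_score_for_bits(bits: float) -> float:
    return (bits * math.log(2.0) + math.log(KA_K)) / KA_LAMBDA


def overlap_at_shift(a: np.ndarray, b: np.ndarray, shift: int) -> tuple[int, int]:
    """(matches, overlap_length) of a against b at a relative shift."""
    lo = max(0, shift)
    hi = min(len(a), len(b) + shift)
    if hi <= lo:
        return 0, 0
    m = int(np.count_nonzero(a[lo:hi] == b[lo - shift : hi - shift]))
    return m, hi - lo


def seed_length(min_identity: float, min_overlap: int, read_length: int) -> int:
    """Longest k guaranteeing a shared exact k-mer in any qualifying overlap.

    An overlap of length m at identity >= min_identity has at most
    floor((1-id)*m) mismatches, which by pigeonhole leaves an exact run of
    at least ceil((m - e) / (e + 1)) bases; k is the minimum of that bound
    over admissible overlap lengths, clamped to [4, 16].
    """
    best = None
    for m in range(min_overlap, read_length + 1):
        e = math.floor((1.0 - min_identity) * m)
        g = math.ceil((m - e) / (e + 1))
        best = g if best is None else min(best, g)
    return max(4, min(16, best if best is not None else 16))


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-4 codes of all k-mers; -1 where a window has ambiguity."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    valid = arr < 4
    vals = np.where(valid, arr, 0).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(vals, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    codes = windows @ powers
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    return np.where(ok, codes, -1)


class KmerIndex:
    """k-mer -> (sequence index, position) lookup over a set of sequences."""

    def __init__(self, encoded: list[np.ndarray], k: int):
        self.k = k
        self.encoded = encoded
        self._table: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for idx, arr in enumerate(encoded):
            for pos, code in enumerate(_kmer_codes(arr, k)):
                if code >= 0:
                    self._table[int(code)].append((idx, pos))

    def candidate_shifts(self, query: np.ndarray) -> dict[int, set[int]]:
        """Map target index -> set of shifts proposed by shared k-mers
        (shift s: query position i aligns target position i - s)."""
        out: dict[int, set[int]] = defaultdict(set)
        for i, code in enumerate(_kmer_codes(query, self.k)):
            if code < 0:
                continue
            for idx, j in self._table.get(int(code), ()):
                out[idx].add(i - j)
        return out


@dataclass(frozen=True)
class OverlapHit:
    target: int
    identity: float
    overlap: int
    shift: int
    orientation: str  # "forward" | "reverse"
    raw_score: int


def _score(matches: int, length: int) -> int:
    return MATCH_REWARD * matches - MISMATCH_PENALTY * (length - matches)


def best_hits(
    query_fwd: np.ndarray,
    query_rev: np.ndarray,
    index: KmerIndex,
    min_overlap: int,
    exclude: int | None = None,
    max_candidates: int | None = None,
) -> dict[int, OverlapHit]:
    """Best overlap per target for one query, both orientations.

    ``max_candidates`` optionally restricts evaluation to the targets
    sharing the most seeds (a BLAST-like speed heuristic; None = exact).
    """
    hits: dict[int, OverlapHit] = {}
    for orient, q in (("forward", query_fwd), ("reverse", query_rev)):
        cands = index.candidate_shifts(q)
        if exclude is not None:
            cands.pop(exclude, None)
        items = cands.items()
        if max_candidates is not None and len(cands) > max_candidates:
            items = sorted(items, key=lambda kv: -len(kv[1]))[:max_candidates]
        for tgt, shifts in items:
            tarr = index.encoded[tgt]
            for s in shifts:
                matches, length = overlap_at_shift(q, tarr, s)
                if length < min_overlap:
                    continue
                hit = OverlapHit(
                    tgt, matches / length, length, s, orient, _score(matches, length)
                )
                prev = hits.get(tgt)
                if (
                    prev is None
                    or hit.raw_score > prev.raw_score
                    or (hit.raw_score == prev.raw_score and hit.identity > prev.identity)
                ):
                    hits[tgt] = hit
    return hits


def encode_pair(seq: str) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse-complement) encodings of a read."""
    return encode(seq), encode(reverse_complement(seq))


def identity_to_reference(read: str, reference: str) -> float:
    """Identity of a read semi-globally aligned inside a longer reference
    (best of both orientations), via edlib infix alignment: identity is
    1 - edit distance / read length, i.e. gaps count as errors."""
    import edlib

    best = 0.0
    for seq in (read, reverse_complement(read)):
        res = edlib.align(seq, reference, mode="HW", task="distance")
        d = res["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(read))
    return best


def tile_reference(consensus: str, read_length: int) -> str:
    """Tile a tandem monomer consensus so any read phase is contained."""
    reps = max(2, math.ceil(read_length / len(consensus)) + 1)
    return consensus * reps
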
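"""Read preprocessing: quality filtering, trimming, pair interlacing and
coverage-targeted random subsampling.

The chain mirrors standard short-read preparation for graph-based repeat
clustering: keep reads with at least ``pass_fraction`` of bases at or above
the Phred cutoff (defaults 0.95 and 10), truncate everything to a uniform
length (default 151 nt, dropping shorter reads), interlace mate pairs, and
randomly subsample to a target genome coverage in the 0.01-0.50x range that
read-clustering pipelines recommend.
"""

from __future__ import annotations

import warnings

import numpy as np

from .reads import Read, ReadSet, with_bases
from .util import expected_read_count


class InsufficientReadsError(ValueError):
    pass


def quality_filter(rs: ReadSet, cutoff: int = 10, pass_fraction: float = 0.95) -> ReadSet:
    """Keep reads whose fraction of bases with quality >= cutoff reaches
    ``pass_fraction``; both comparisons are inclusive, order is preserved."""
    if not 0.0 <= pass_fraction <= 1.0:
        raise ValueError("pass_fraction must be in [0, 1]")
    kept = []
    for r in rs:
        if len(r) == 0:
            continue
        n_ok = sum(1 for q in r.qualities if q >= cutoff)
        if n_ok / len(r) >= pass_fraction:
            kept.append(r)
    return ReadSet(kept)


def trim_to_length(rs: ReadSet, target: int = 151) -> ReadSet:
    """Truncate reads from the 3' end to ``target`` bases; drop shorter
    reads so that all output reads have uniform length."""
    if target < 1:
        raise ValueError("target length must be >= 1")
    out = []
    for r in rs:
        if len(r) < target:
            continue
        out.append(with_bases(r, r.bases[:target]) if len(r) > target else r)
    return ReadSet(out)


def trim_adapters(rs: ReadSet, prefix: int = 0, suffix: int = 0) -> ReadSet:
    """Optional fixed-length end trimming (adapter removal stand-in);
    synthetic reads carry no adapters, so both defaults are 0."""
    if prefix == 0 and suffix == 0:
        return rs
    out = []
    for r in rs:
        end = len(r) - suffix
        if end <= prefix:
            continue
        out.append(
            Read(r.id, r.bases[prefix:end], r.qualities[prefix:end], r.mate_id, r.source)
        )
    return ReadSet(out)


def interlace_pairs(rs: ReadSet) -> ReadSet:
    """Order mates as (a1, a2, b1, b2, ...); pairs with a missing mate are
    dropped entirely (clustering operates on whole interlaced pairs)."""
    if len(rs) == 0:
        return ReadSet([])
    if not rs.is_paired:
        raise ValueError("interlace_pairs requires a paired read set")
    index = rs.by_id()
    seen: set[str] = set()
    out = []
    for r in rs:
        if r.id in seen:
            continue
        if r.mate_id is None:
            continue  # orphan by construction
        mate = index.get(r.mate_id)
        if mate is None:
            seen.add(r.id)
            continue  # mate filtered out upstream: drop the pair
        out.extend([r, mate])
        seen.update((r.id, mate.id))
    return ReadSet(out)


def subsample_to_coverage(
    rs: ReadSet,
    genome_length: int,
    target_coverage: float,
    read_length: int,
    seed: int,
) -> ReadSet:
    """Uniform random subsample (without replacement) sized for a target
    coverage; pairs are kept or dropped together."""
    if target_coverage <= 0:
        raise ValueError("target_coverage must be > 0")
    if len(rs) == 0:
        raise ValueError("cannot subsample an empty read set")
    if not 0.01 <= target_coverage <= 0.50:
        warnings.warn(
            f"target coverage {target_coverage}x is outside the 0.01-0.50x "
            "range recommended for graph-based repeat clustering"
        )
    paired = rs.is_paired
    n = expected_read_count(genome_length, target_coverage, read_length, paired)
    if n >= len(rs):
        if n > len(rs):
            raise InsufficientReadsError(
                f"need {n} reads for {target_coverage}x but only {len(rs)} available"
            )
        return ReadSet(list(rs.reads))
    rng = np.random.default_rng(seed)
    if paired:
        index = rs.by_id()
        units: list[tuple[Read, ...]] = []
        seen: set[str] = set()
        for r in rs:
            if r.id in seen:
                continue
            mate = index.get(r.mate_id) if r.mate_id else None
            if mate is not None:
                units.append((r, mate))
                seen.update((r.id, mate.id))
            else:
                units.append((r,))
                seen.add(r.id)
        n_units = n // 2
        if n_units > len(units):
            raise InsufficientReadsError("not enough pairs to reach target coverage")
        picks = rng.choice(len(units), size=n_units, replace=False)
        out: list[Read] = []
        for k in sorted(picks):
            out.extend(units[k])
        return ReadSet(out)
    picks = rng.choice(len(rs), size=n, replace=False)
    return ReadSet([rs[int(k)] for k in sorted(picks)])
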
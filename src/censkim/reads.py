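"""Read containers.

A :class:`ReadSet` is the unit every pipeline stage consumes and produces:
an ordered collection of reads with Phred qualities, optional mate linkage
(paired-end libraries) and, for simulated reads, a ground-truth source
interval used by recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SourceInterval:
    """Where a simulated read truly came from (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str  # "+" or "-"
    family: str | None = None  # repeat family at the start position, if any
    subfamily: int | None = None


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    qualities: tuple[int, ...]
    mate_id: str | None = None
    source: SourceInterval | None = None

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(
                f"read {self.id}: bases ({len(self.bases)}) and qualities "
                f"({len(self.qualities)}) differ in length"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadSet:
    """Ordered collection of reads with unique identifiers."""

    reads: list[Read] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(set(ids)) != len(ids):
            raise ValueError("read identifiers must be unique")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i: int) -> Read:
        return self.reads[i]

    def ids(self) -> list[str]:
        return [r.id for r in self.reads]

    def by_id(self) -> dict[str, Read]:
        return {r.id: r for r in self.reads}

    @property
    def is_paired(self) -> bool:
        return any(r.mate_id is not None for r in self.reads)

    def validate_pairing(self) -> None:
        """Check mate linkage is symmetric for all present pairs."""
        index = self.by_id()
        for r in self.reads:
            if r.mate_id is None:
                continue
            mate = index.get(r.mate_id)
            if mate is not None and mate.mate_id != r.id:
                raise ValueError(f"asymmetric mate linkage: {r.id} <-> {r.mate_id}")

    def subset(self, keep_ids: Iterable[str]) -> "ReadSet":
        keep = set(keep_ids)
        return ReadSet([r for r in self.reads if r.id in keep])


def make_read(
    rid: str,
    bases: str,
    quality: int = 30,
    mate_id: str | None = None,
    source: SourceInterval | None = None,
) -> Read:
    """Convenience constructor with a constant Phred quality."""
    return Read(rid, bases, tuple([quality] * len(bases)), mate_id, source)


def with_bases(read: Read, bases: str) -> Read:
    """Copy of a read with new bases and qualities truncated to match."""
    return replace(read, bases=bases, qualities=read.qualities[: len(bases)])
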
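"""Synthetic repeatome generator.

Builds annotated genomes, sequencing read sets and 1-D fluorescence
intensity profiles with the statistical structure of a beetle-like
monocentric repeatome: a highly abundant major satellite (360-bp monomers,
five subfamilies mutually divergent up to 30%, ~17% of the genome) filling
most of the centromeric intervals with spill-over into the pericentromere,
minor satellites, 5S rDNA-like tandem units (192 bp = 119 bp gene + 73 bp
spacer), dispersed retroelement-like copies and short interstitial
(TCAGG)n arrays, the rest being i.i.d. random background.

Every planted repeat copy is annotated (family, subfamily) and every
simulated read records its true source interval, so downstream stages can
be tested against ground truth. All generators are bit-reproducible from
(spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cytometry import IntensityProfile
from .reads import Read, ReadSet, SourceInterval, reverse_complement
from .util import expected_read_count

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ------------------------------------------------------------------ specs

@dataclass(frozen=True)
class RepeatFamilySpec:
    """One repeat family of the synthetic genome.

    ``max_subfamily_divergence`` bounds the pairwise fraction of substituted
    positions between subfamily consensuses; ``intra_divergence`` is the
    per-copy substitution rate around the subfamily consensus (tandem arrays
    are never perfectly homogeneous).  ``array_length_bp`` bounds individual
    tandem array lengths, e.g. (100, 400) for short interstitial telomeric
    arrays.
    """

    name: str
    monomer_length: int
    genome_fraction: float
    n_subfamilies: int = 1
    max_subfamily_divergence: float = 0.0
    organization: str = "tandem"  # or "dispersed"
    centromeric: bool = False
    intra_divergence: float = 0.02
    array_length_bp: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.monomer_length < 1:
            raise ValueError(f"{self.name}: monomer_length must be >= 1")
        if self.n_subfamilies < 1:
            raise ValueError(f"{self.name}: n_subfamilies must be >= 1")
        if not 0.0 <= self.genome_fraction <= 1.0:
            raise ValueError(f"{self.name}: genome_fraction must be in [0, 1]")
        if not 0.0 <= self.max_subfamily_divergence <= 1.0:
            raise ValueError(f"{self.name}: divergence must be in [0, 1]")
        if self.organization not in ("tandem", "dispersed"):
            raise ValueError(f"{self.name}: unknown organization")


@dataclass(frozen=True)
class GenomeSpec:
    genome_length: int
    families: tuple[RepeatFamilySpec, ...] = ()
    n_chromosomes: int = 1
    centromere_fraction: float = 0.435
    seed: int = 0
    # fraction of a centromeric family's array bases spilling into the
    # flanking pericentromere (satellite arrays outspread beyond the
    # CenH3-occupied domains)
    pericentromere_spill: float = 0.20

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if not 0.0 < self.centromere_fraction < 1.0:
            raise ValueError("centromere_fraction must be in (0, 1)")
        total = sum(f.genome_fraction for f in self.families)
        if total > 1.0:
            raise ValueError(f"family fractions sum to {total:.3f} > 1 (infeasible)")


@dataclass(frozen=True)
class Annotation:
    chrom: str
    start: int
    end: int  # half-open
    family: str
    subfamily: int


@dataclass
class AnnotatedGenome:
    """Synthetic sequence plus ground-truth interval annotations."""

    sequences: dict[str, str]
    annotations: list[Annotation]
    centromeres: list[tuple[str, int, int]]
    arrays: list[Annotation] = field(default_factory=list)  # array-level grouping

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def family_base_fraction(self, family: str) -> float:
        total = sum(a.end - a.start for a in self.annotations if a.family == family)
        return total / self.genome_length

    def validate(self) -> None:
        """Check the ground-truth invariants: intervals inside chromosomes,
        no overlapping annotations per chromosome."""
        for a in self.annotations:
            if not (0 <= a.start < a.end <= len(self.sequences[a.chrom])):
                raise AssertionError(f"annotation out of bounds: {a}")
        by_chrom: dict[str, list[Annotation]] = {}
        for a in self.annotations:
            by_chrom.setdefault(a.chrom, []).append(a)
        for anns in by_chrom.values():
            anns.sort(key=lambda a: a.start)
            for prev, cur in zip(anns, anns[1:]):
                if cur.start < prev.end:
                    raise AssertionError(f"overlapping annotations: {prev} / {cur}")


@dataclass(frozen=True)
class OccupancyModel:
    """Chromatin pull-down model for ChIP read simulation.

    Reads originate with probability proportional to a per-position weight:
    ``family_weights[f]`` inside *occupied* centromeric arrays of family
    ``f``, ``background_weight`` everywhere else.  Only a fraction
    ``occupied_fraction`` of each centromeric family's arrays carries the
    centromeric histone mark (CenH3 nucleosomes interact with only part of
    the underlying repeat arrays).
    """

    family_weights: dict[str, float] = field(default_factory=dict)
    background_weight: float = 1.0
    occupied_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.occupied_fraction <= 1.0:
            raise ValueError("occupied_fraction must be in (0, 1]")
        if any(w < 0 for w in self.family_weights.values()) or self.background_weight < 0:
            raise ValueError("weights must be >= 0")
        if self.background_weight == 0 and not any(
            w > 0 for w in self.family_weights.values()
        ):
            raise ValueError("degenerate model: all weights zero")


@dataclass(frozen=True)
class IntensityProfileSpec:
    n_positions: int
    centromere_fraction: float = 0.435
    n_domains: int = 4
    channel_overlap: float = 0.75
    noise_sd: float = 0.0
    seed: int = 0
    mode: str = "chromosome"  # or "fiber"

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("n_domains must be >= 1")
        if self.n_positions < 10 * self.n_domains:
            raise ValueError("n_positions must be >= 10 * n_domains")
        if not 0.0 < self.centromere_fraction < 1.0:
            raise ValueError("centromere_fraction must be in (0, 1)")
        if not 0.0 <= self.channel_overlap <= 1.0:
            raise ValueError("channel_overlap must be in [0, 1]")


# ------------------------------------------------------- family library

def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Substitute each given position with a different base."""
    out = seq.copy()
    for p in positions:
        choices = _BASES[_BASES != out[p]]
        out[p] = rng.choice(choices)
    return out


def build_family_library(spec: RepeatFamilySpec, seed: int) -> list[str]:
    """Subfamily consensus sequences for one repeat family.

    A random ancestor monomer is substituted, independently per subfamily,
    at ``floor(i/(n-1) * max_divergence/2 * L)`` uniformly chosen positions
    for subfamily i (0-based).  The triangle inequality bounds every
    pairwise divergence by ``max_divergence`` (coincident substitutions
    only lower it), while the graded distances make subfamilies *mutually
    divergent up to* the target rather than all equidistant — as in real
    satellite families, where some subfamily pairs are much closer than
    the most diverged pair.
    """
    rng = np.random.default_rng(seed)
    ancestor = _random_sequence(rng, spec.monomer_length)
    n = spec.n_subfamilies
    consensuses = []
    for i in range(n):
        frac = i / (n - 1) if n > 1 else 0.0
        n_mut = math.floor(frac * spec.max_subfamily_divergence / 2.0 * spec.monomer_length)
        pos = rng.choice(spec.monomer_length, size=n_mut, replace=False)
        consensuses.append(_mutate(rng, ancestor, pos))
    return [c.tobytes().decode() for c in consensuses]


def pairwise_divergence(a: str, b: str) -> float:
    """Fraction of mismatching positions between equal-length sequences."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return float((arr_a != arr_b).mean())


# ----------------------------------------------------------- genome build

class _FreeList:
    """Non-overlapping free intervals of one chromosome, for array placement."""

    def __init__(self, length: int):
        self.intervals: list[tuple[int, int]] = [(0, length)]

    def place(self, size: int, lo: int, hi: int, rng: np.random.Generator) -> int | None:
        """Reserve ``size`` bases somewhere inside [lo, hi); return start."""
        candidates = []
        for idx, (s, e) in enumerate(self.intervals):
            s2, e2 = max(s, lo), min(e, hi)
            if e2 - s2 >= size:
                candidates.append((idx, s2, e2))
        if not candidates:
            return None
        weights = np.array([e2 - s2 - size + 1 for _, s2, e2 in candidates], dtype=float)
        pick = rng.choice(len(candidates), p=weights / weights.sum())
        idx, s2, e2 = candidates[pick]
        start = int(s2 + rng.integers(0, e2 - s2 - size + 1))
        s, e = self.intervals[idx]
        repl = [iv for iv in ((s, start), (start + size, e)) if iv[1] > iv[0]]
        self.intervals[idx : idx + 1] = repl
        return start


def _array_plan(
    total_bases: int,
    monomer: int,
    length_range: tuple[int, int] | None,
    rng: np.random.Generator,
) -> list[int]:
    """Split a family's base budget into per-array monomer counts."""
    n_monomers = max(1, round(total_bases / monomer))
    if length_range is None:
        lo_bp, hi_bp = max(monomer, 2000), max(monomer * 2, 20000)
    else:
        lo_bp, hi_bp = length_range
    lo = max(1, lo_bp // monomer)
    hi = max(lo, hi_bp // monomer)
    counts: list[int] = []
    remaining = n_monomers
    while remaining > 0:
        c = int(rng.integers(lo, hi + 1))
        counts.append(min(c, remaining))
        remaining -= counts[-1]
    return counts


def build_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Assemble a synthetic annotated genome from a spec.

    Tandem families are head-to-tail monomer arrays; centromeric families
    put ~(1 - spill) of their arrays inside the centromere interval and the
    rest immediately flanking it; dispersed families are isolated copies
    outside centromeres; all remaining sequence is i.i.d. random background.
    """
    rng = np.random.default_rng(spec.seed)
    base_len = spec.genome_length // spec.n_chromosomes
    chrom_lengths = [base_len] * spec.n_chromosomes
    chrom_lengths[-1] += spec.genome_length - base_len * spec.n_chromosomes
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]

    seqs = {n: _random_sequence(rng, L) for n, L in zip(chrom_names, chrom_lengths)}
    free = {n: _FreeList(L) for n, L in zip(chrom_names, chrom_lengths)}

    centromeres = []
    cen_bounds = {}
    for name, L in zip(chrom_names, chrom_lengths):
        cen_len = round(spec.centromere_fraction * L)
        start = (L - cen_len) // 2
        centromeres.append((name, start, start + cen_len))
        cen_bounds[name] = (start, start + cen_len)

    libraries = {
        f.name: [
            np.frombuffer(c.encode(), dtype=np.uint8)
            for c in build_family_library(f, int(rng.integers(2**31)))
        ]
        for f in spec.families
    }

    annotations: list[Annotation] = []
    arrays: list[Annotation] = []
    total_len = float(spec.genome_length)

    def plant_array(fam: RepeatFamilySpec, chrom: str, n_monomers: int, lo: int, hi: int) -> bool:
        size = n_monomers * fam.monomer_length
        start = free[chrom].place(size, lo, hi, rng)
        if start is None:
            return False
        sub = int(rng.integers(0, fam.n_subfamilies))
        consensus = libraries[fam.name][sub]
        pos = start
        for _ in range(n_monomers):
            copy = consensus
            n_mut = rng.binomial(fam.monomer_length, fam.intra_divergence)
            if n_mut:
                mp = rng.choice(fam.monomer_length, size=n_mut, replace=False)
                copy = _mutate(rng, consensus, mp)
            seqs[chrom][pos : pos + fam.monomer_length] = copy
            annotations.append(
                Annotation(chrom, pos, pos + fam.monomer_length, fam.name, sub)
            )
            pos += fam.monomer_length
        arrays.append(Annotation(chrom, start, start + size, fam.name, sub))
        return True

    # centromeric tandem families first (they compete for limited space)
    order = sorted(
        spec.families,
        key=lambda f: (not f.centromeric, f.organization != "tandem", -f.genome_fraction),
    )
    for fam in order:
        fam_bases = fam.genome_fraction * total_len
        if fam_bases < 1:
            continue
        if fam.organization == "dispersed":
            n_copies = max(1, round(fam_bases / fam.monomer_length))
            for _ in range(n_copies):
                chrom = chrom_names[int(rng.integers(spec.n_chromosomes))]
                cs, ce = cen_bounds[chrom]
                L = len(seqs[chrom])
                lo, hi = (0, L)
                if not fam.centromeric:
                    # place outside the centromere, either arm
                    lo, hi = (0, cs) if rng.random() < cs / max(1, cs + L - ce) else (ce, L)
                plant_array(fam, chrom, 1, lo, hi)
            continue
        # tandem: distribute arrays across chromosomes proportionally to length
        counts = _array_plan(int(fam_bases), fam.monomer_length, fam.array_length_bp, rng)
        for n_monomers in counts:
            chrom = chrom_names[int(rng.integers(spec.n_chromosomes))]
            L = len(seqs[chrom])
            cs, ce = cen_bounds[chrom]
            if fam.centromeric:
                if rng.random() < spec.pericentromere_spill:
                    flank = max(1, (ce - cs) // 4)
                    placed = plant_array(fam, chrom, n_monomers, max(0, cs - flank), cs) or \
                        plant_array(fam, chrom, n_monomers, ce, min(L, ce + flank))
                else:
                    placed = plant_array(fam, chrom, n_monomers, cs, ce)
                if not placed:  # fall back to anywhere on the chromosome
                    plant_array(fam, chrom, n_monomers, 0, L)
            else:
                lo, hi = (0, cs) if rng.random() < cs / max(1, cs + L - ce) else (ce, L)
                if not plant_array(fam, chrom, n_monomers, lo, hi):
                    plant_array(fam, chrom, n_monomers, 0, L)

    genome = AnnotatedGenome(
        sequences={n: s.tobytes().decode() for n, s in seqs.items()},
        annotations=annotations,
        centromeres=centromeres,
        arrays=arrays,
    )
    genome.validate()
    return genome


# ------------------------------------------------------------ read draws

class _TruthLookup:
    """Midpoint-based family lookup into the annotation set."""

    def __init__(self, genome: AnnotatedGenome):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[Annotation]]] = {}
        per_chrom: dict[str, list[Annotation]] = {}
        for a in genome.annotations:
            per_chrom.setdefault(a.chrom, []).append(a)
        for chrom, anns in per_chrom.items():
            anns.sort(key=lambda a: a.start)
            starts = np.array([a.start for a in anns])
            ends = np.array([a.end for a in anns])
            self._by_chrom[chrom] = (starts, ends, anns)

    def family_at(self, chrom: str, pos: int) -> tuple[str | None, int | None]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None, None
        starts, ends, anns = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return anns[i].family, anns[i].subfamily
        return None, None


def _extract_read(seq: str, start: int, length: int, minus: bool) -> str:
    sub = seq[start : start + length]
    return reverse_complement(sub) if minus else sub


def _apply_errors(rng, bases: str, rate: float) -> str:
    if rate <= 0:
        return bases
    arr = np.frombuffer(bases.encode(), dtype=np.uint8).copy()
    n = rng.binomial(len(arr), rate)
    if n:
        pos = rng.choice(len(arr), size=n, replace=False)
        arr = _mutate(rng, arr, pos)
    return arr.tobytes().decode()


def simulate_wgs_reads(
    genome: AnnotatedGenome,
    coverage: float,
    read_length: int,
    paired: bool,
    seed: int,
    quality: int = 30,
    error_rate: float = 0.0,
    insert_size: int = 350,
) -> ReadSet:
    """Uniform whole-genome shotgun reads at a target coverage.

    Read count is ceil(coverage * genome_length / read_length), rounded up
    to the next even number when paired.  Each read records its true source
    interval for oracle tests.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    chroms = list(genome.sequences)
    lengths = np.array([len(genome.sequences[c]) for c in chroms])
    if read_length > lengths.min():
        raise ValueError("read_length exceeds shortest chromosome")
    n = expected_read_count(genome.genome_length, coverage, read_length, paired)
    if n == 0:
        return ReadSet([])
    rng = np.random.default_rng(seed)
    truth = _TruthLookup(genome)
    reads: list[Read] = []

    def one_read(rid: str, chrom: str, start: int, minus: bool, mate: str | None) -> Read:
        seq = genome.sequences[chrom]
        bases = _apply_errors(rng, _extract_read(seq, start, read_length, minus), error_rate)
        fam, sub = truth.family_at(chrom, start + read_length // 2)
        src = SourceInterval(chrom, start, start + read_length, "-" if minus else "+", fam, sub)
        return Read(rid, bases, tuple([quality] * read_length), mate, src)

    if paired:
        frag = max(insert_size, read_length)
        frag_caps = np.maximum(lengths - frag + 1, 1)
        probs = frag_caps / frag_caps.sum()
        for i in range(n // 2):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            f = min(frag, lengths[ci])
            start = int(rng.integers(0, lengths[ci] - f + 1))
            flip = bool(rng.random() < 0.5)
            r1 = one_read(f"wgs{i}/1", chrom, start, flip, f"wgs{i}/2")
            r2 = one_read(f"wgs{i}/2", chrom, start + f - read_length, not flip, f"wgs{i}/1")
            reads.extend([r1, r2])
    else:
        caps = lengths - read_length + 1
        probs = caps / caps.sum()
        for i in range(n):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom = chroms[ci]
            start = int(rng.integers(0, caps[ci]))
            reads.append(one_read(f"wgs{i}", chrom, start, bool(rng.random() < 0.5), None))
    return ReadSet(reads)


def expected_family_enrichment(
    genome: AnnotatedGenome, model: OccupancyModel, family: str
) -> float:
    """Closed-form expected ChIP:input read-origin ratio for a family.

    Input origin probability is the family's base fraction; ChIP origin
    probability weights occupied centromeric bases by the family weight.
    Uses the expectation over array occupancy (occupied_fraction).
    """
    total = genome.genome_length
    fam_bases = sum(a.end - a.start for a in genome.annotations if a.family == family)
    cen = {(c, s, e) for c, s, e in genome.centromeres}

    def in_cen(a: Annotation) -> bool:
        return any(c == a.chrom and a.start >= s and a.end <= e for c, s, e in cen)

    cen_bases = sum(
        a.end - a.start for a in genome.arrays if a.family == family and in_cen(a)
    )
    w = model.family_weights.get(family, model.background_weight)
    bg = model.background_weight
    occ = model.occupied_fraction
    # expected weighted mass of this family and of the whole genome
    fam_mass = cen_bases * (occ * w + (1 - occ) * bg) + (fam_bases - cen_bases) * bg
    other = {f for f in model.family_weights if f != family}
    total_mass = fam_mass + (total - fam_bases) * bg
    for f in other:
        f_bases = sum(a.end - a.start for a in genome.annotations if a.family == f)
        f_cen = sum(
            a.end - a.start for a in genome.arrays if a.family == f and in_cen(a)
        )
        wf = model.family_weights[f]
        total_mass += f_cen * occ * (wf - bg)
    chip_p = fam_mass / total_mass
    input_p = fam_bases / total
    return chip_p / input_p


def simulate_chip_input(
    genome: AnnotatedGenome,
    model: OccupancyModel,
    n_reads: int,
    read_length: int,
    seed: int,
    quality: int = 30,
    error_rate: float = 0.0,
) -> tuple[ReadSet, ReadSet]:
    """Simulate a ChIP library and its matched input control.

    Input read starts are uniform over the genome; ChIP read starts are
    drawn with probability proportional to the occupancy weight at the
    start position.  Both libraries have exactly ``n_reads`` reads and keep
    per-read ground truth.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if n_reads == 0:
        return ReadSet([]), ReadSet([])
    rng = np.random.default_rng(seed)
    truth = _TruthLookup(genome)
    chroms = list(genome.sequences)
    lengths = {c: len(genome.sequences[c]) for c in chroms}
    cen = {c: (s, e) for c, s, e in genome.centromeres}

    # decide per-array occupancy for centromeric arrays of weighted families
    weighted: list[tuple[str, int, int, float]] = []  # (chrom, start, end, weight)
    for a in genome.arrays:
        w = model.family_weights.get(a.family)
        if w is None:
            continue
        cs, ce = cen.get(a.chrom, (0, 0))
        if a.start >= cs and a.end <= ce and rng.random() < model.occupied_fraction:
            weighted.append((a.chrom, a.start, a.end, w))

    def draw(rid_prefix: str, use_weights: bool) -> ReadSet:
        # segment the genome into (chrom, start, end, weight) pieces
        segs: list[tuple[str, int, int, float]] = []
        if use_weights:
            per_chrom: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chroms}
            for c, s, e, w in weighted:
                per_chrom[c].append((s, e, w))
            for c in chroms:
                pieces = sorted(per_chrom[c])
                pos = 0
                for s, e, w in pieces:
                    if s > pos:
                        segs.append((c, pos, s, model.background_weight))
                    segs.append((c, s, e, w))
                    pos = e
                if pos < lengths[c]:
                    segs.append((c, pos, lengths[c], model.background_weight))
        else:
            segs = [(c, 0, lengths[c], 1.0) for c in chroms]
        mass = np.array([(e - s) * w for _, s, e, w in segs], dtype=float)
        if mass.sum() == 0:
            raise ValueError("degenerate model: zero total sampling weight")
        probs = mass / mass.sum()
        picks = rng.choice(len(segs), size=n_reads, p=probs)
        reads = []
        for i, k in enumerate(picks):
            chrom, s, e, _ = segs[k]
            start = int(rng.integers(s, e))
            start = min(start, lengths[chrom] - read_length)
            minus = bool(rng.random() < 0.5)
            bases = _apply_errors(
                rng, _extract_read(genome.sequences[chrom], start, read_length, minus),
                error_rate,
            )
            fam, sub = truth.family_at(chrom, start + read_length // 2)
            src = SourceInterval(
                chrom, start, start + read_length, "-" if minus else "+", fam, sub
            )
            reads.append(
                Read(f"{rid_prefix}{i}", bases, tuple([quality] * read_length), None, src)
            )
        return ReadSet(reads)

    chip = draw("chip", use_weights=True)
    inp = draw("input", use_weights=False)
    return chip, inp


# -------------------------------------------------------------- profiles

def simulate_profile(spec: IntensityProfileSpec) -> IntensityProfile:
    """Synthetic 1-D fluorescence profile.

    Chromosome mode: a DNA-stain channel positive along the whole axis and a
    centromere-protein channel positive in ``n_domains`` disjoint blocks
    whose outermost-edge span equals ``centromere_fraction`` of the axis
    (bead-like metapolycentric signal; a single block gives the dot-like
    pattern).  Fiber mode: two channels whose co-positive fraction over the
    signal-bearing span equals ``channel_overlap``.  Gaussian noise with sd
    ``noise_sd`` is added and intensities are clipped at zero.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_positions
    positions = np.arange(n, dtype=float)
    amp = 100.0

    if spec.mode == "chromosome":
        span = round(spec.centromere_fraction * n)
        span = max(span, 2 * spec.n_domains - 1)
        s0 = (n - span) // 2
        k = spec.n_domains
        cen = np.zeros(n)
        if k == 1:
            cen[s0 : s0 + span] = amp
        else:
            w = span // (2 * k - 1)
            if w < 1:
                raise ValueError("n_positions too small for n_domains")
            for i in range(k):
                start = s0 + i * 2 * w
                width = w if i < k - 1 else span - (k - 1) * 2 * w
                cen[start : start + width] = amp
        channels = {"dna": np.full(n, amp), "cen": cen}
    elif spec.mode == "fiber":
        c = spec.channel_overlap
        a_end = round(n * (1 + c) / 2.0)
        b_start = n - a_end
        ch_a = np.zeros(n)
        ch_b = np.zeros(n)
        ch_a[:a_end] = amp
        ch_b[b_start:] = amp
        channels = {"a": ch_a, "b": ch_b}
    else:
        raise ValueError(f"unknown profile mode: {spec.mode}")

    if spec.noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0, spec.noise_sd, size=n), 0, None
            )
    return IntensityProfile(positions=positions, channels=channels)


def sample_reads_from_consensuses(
    consensuses: dict[str, str],
    mixture: dict[str, float],
    n_reads: int,
    read_length: int,
    seed: int,
    intra_divergence: float = 0.02,
) -> ReadSet:
    """Reads drawn from tandem arrays of the given consensuses at planted
    mixture proportions, with random monomer phase and per-read
    substitution noise.  Each read's true subfamily is recorded in its
    source interval (family = the consensus label)."""
    labels = sorted(mixture)
    probs = np.array([mixture[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        label = labels[int(rng.choice(len(labels), p=probs))]
        cons = consensuses[label]
        reps = math.ceil(read_length / len(cons)) + 1
        tiled = np.frombuffer((cons * reps).encode(), dtype=np.uint8)
        start = int(rng.integers(0, len(cons)))
        window = tiled[start : start + read_length].copy()
        n_mut = rng.binomial(read_length, intra_divergence)
        if n_mut:
            pos = rng.choice(read_length, size=n_mut, replace=False)
            window = _mutate(rng, window, pos)
        bases = window.tobytes().decode()
        if rng.random() < 0.5:
            bases = reverse_complement(bases)
        src = SourceInterval("consensus", start, start + read_length, "+", label, None)
        reads.append(Read(f"mix{i}", bases, tuple([30] * read_length), None, src))
    return ReadSet(reads)


# ------------------------------------------------- default study genome

def default_families() -> tuple[RepeatFamilySpec, ...]:
    """Repeat families emulating the *T. castaneum* repeatome structure."""
    return (
        RepeatFamilySpec(
            "major_sat", 360, 0.17, n_subfamilies=5, max_subfamily_divergence=0.30,
            organization="tandem", centromeric=True,
        ),
        RepeatFamilySpec(
            "minor_sat180", 180, 0.005, organization="tandem", centromeric=False,
        ),
        RepeatFamilySpec(
            "sat73", 73, 0.0005, organization="tandem", centromeric=True,
        ),
        RepeatFamilySpec(
            "rdna_5s", 192, 0.002, organization="tandem", centromeric=False,
        ),
        RepeatFamilySpec(
            "retroelement", 1500, 0.03, organization="dispersed", centromeric=False,
            intra_divergence=0.05,
        ),
        RepeatFamilySpec(
            "tcagg", 5, 0.0005, organization="tandem", centromeric=False,
            intra_divergence=0.0, array_length_bp=(100, 400),
        ),
    )


def default_genome_spec(genome_length: int = 2_040_000, seed: int = 0) -> GenomeSpec:
    return GenomeSpec(
        genome_length=genome_length,
        families=default_families(),
        n_chromosomes=1,
        centromere_fraction=0.435,
        seed=seed,
    )
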
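"""Graph-based clustering of unassembled reads into repeat clusters.

Low-pass shotgun reads are compared all-against-all (k-mer seeded, both
orientations); pairs whose best ungapped overlap reaches the identity and
overlap-fraction thresholds (defaults 0.90 over 0.55 of the read length,
the convention of graph-clustering repeat pipelines) become edges of a
similarity graph.  Clusters are the connected components with at least two
members, ranked CL1, CL2, ... by descending size; everything else is a
singleton.  A cluster's share of the analyzed reads estimates the genome
proportion of the underlying repeat family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import alignment as aln
from .reads import ReadSet

DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_OVERLAP_FRACTION = 0.55


@dataclass(frozen=True)
class SimilarityEdge:
    read_a: str
    read_b: str
    identity: float
    overlap_fraction: float
    orientation: str  # "forward" | "reverse"

    def key(self) -> frozenset:
        return frozenset((self.read_a, self.read_b))


@dataclass
class RepeatCluster:
    cluster_id: str  # "CL" + rank
    member_reads: set[str]
    genome_proportion: float
    representative_sequences: list[tuple[str, str]] = field(default_factory=list)
    annotation: str | None = None

    @property
    def size(self) -> int:
        return len(self.member_reads)


@dataclass(frozen=True)
class ClusteringSummary:
    total_reads: int
    clustered_reads: int
    singleton_reads: int
    n_clusters: int

    def __post_init__(self) -> None:
        if self.clustered_reads + self.singleton_reads != self.total_reads:
            raise ValueError("clustered + singleton reads must equal total reads")

    @property
    def clustered_fraction(self) -> float:
        return self.clustered_reads / self.total_reads if self.total_reads else 0.0


@dataclass(frozen=True)
class SubfamilyProfile:
    cluster_id: str
    proportions: dict[str, float]
    unassigned_fraction: float


def build_similarity_graph(
    rs: ReadSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap_fraction: float = DEFAULT_MIN_OVERLAP_FRACTION,
) -> list[SimilarityEdge]:
    """All read pairs whose best dovetail overlap (either orientation)
    reaches identity >= min_identity over >= min_overlap_fraction of the
    read length.  Symmetric, no self-edges.  Seeding is lossless for the
    given thresholds (see :mod:`censkim.alignment`)."""
    if len(rs) == 0:
        return []
    lengths = {len(r) for r in rs}
    if len(lengths) != 1:
        raise ValueError("build_similarity_graph requires uniform read length")
    read_length = lengths.pop()
    min_overlap = math.ceil(min_overlap_fraction * read_length)
    k = aln.seed_length(min_identity, min_overlap, read_length)

    encoded = [aln.encode(r.bases) for r in rs]
    index = aln.KmerIndex(encoded, k)
    ids = rs.ids()
    edges: list[SimilarityEdge] = []
    for i, read in enumerate(rs):
        fwd = encoded[i]
        rev = aln.encode_pair(read.bases)[1]
        hits = aln.best_hits(fwd, rev, index, min_overlap, exclude=i)
        for tgt, hit in hits.items():
            if tgt <= i:  # each unordered pair reported once
                continue
            if hit.identity >= min_identity:
                edges.append(
                    SimilarityEdge(
                        ids[i], ids[tgt], hit.identity,
                        hit.overlap / read_length, hit.orientation,
                    )
                )
    return edges


def cluster_reads(
    edges: list[SimilarityEdge], rs: ReadSet
) -> tuple[list[RepeatCluster], ClusteringSummary]:
    """Connected components (>= 2 members) of the similarity graph, ranked
    by descending size with ties broken by the lexicographically smallest
    member identifier; the cluster reference is the full member read set."""
    graph = nx.Graph()
    graph.add_nodes_from(rs.ids())
    for e in edges:
        graph.add_edge(e.read_a, e.read_b)
    components = [c for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), min(c)))
    by_id = rs.by_id()
    total = len(rs)
    clusters = [
        RepeatCluster(
            cluster_id=f"CL{rank}",
            member_reads=set(comp),
            genome_proportion=len(comp) / total,
            representative_sequences=[(rid, by_id[rid].bases) for rid in sorted(comp)],
        )
        for rank, comp in enumerate(components, start=1)
    ]
    clustered = sum(c.size for c in clusters)
    summary = ClusteringSummary(
        total_reads=total,
        clustered_reads=clustered,
        singleton_reads=total - clustered,
        n_clusters=len(clusters),
    )
    return clusters, summary


def genome_proportion(cluster: RepeatCluster, total_reads: int) -> float:
    """Cluster read share of all analyzed reads (~ genome proportion)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if cluster.size == 0:
        raise ValueError("cluster must have at least one member")
    if total_reads < cluster.size:
        raise ValueError("total_reads smaller than cluster size")
    return cluster.size / total_reads


def annotate_cluster(
    cluster: RepeatCluster,
    library: dict[str, str],
    min_identity: float = 0.80,
    tandem_read_length: int | None = None,
) -> str:
    """Label a cluster against a user-supplied reference library.

    Each member read is assigned to the library sequence with its best
    semi-global alignment at identity >= min_identity; the plurality label
    wins, or "unknown" when fewer than half of the members hit anything.
    With ``tandem_read_length`` set, references are tiled head-to-tail so
    reads crossing a monomer junction still align.
    """
    if not library:
        raise ValueError("reference library must not be empty")
    refs = {
        label: aln.tile_reference(seq, tandem_read_length) if tandem_read_length else seq
        for label, seq in library.items()
    }
    votes: dict[str, int] = {}
    n_hit = 0
    for _, bases in cluster.representative_sequences:
        best_label, best_ident = None, min_identity
        for label in sorted(refs):
            ident = aln.identity_to_reference(bases, refs[label])
            if ident > best_ident or (ident == best_ident and best_label is None and ident >= min_identity):
                best_label, best_ident = label, ident
        if best_label is not None:
            n_hit += 1
            votes[best_label] = votes.get(best_label, 0) + 1
    if n_hit < 0.5 * cluster.size or not votes:
        return "unknown"
    return min(votes, key=lambda lab: (-votes[lab], lab))


def subfamily_proportions(
    cluster: RepeatCluster,
    consensuses: dict[str, str],
    min_identity: float = 0.55,
    tile_for_reads: bool = True,
) -> SubfamilyProfile:
    """Decompose a satellite cluster into subfamily proportions.

    Each member read goes to the subfamily consensus with the highest
    alignment identity (ties to the lexicographically first label); reads
    below ``min_identity`` against every consensus count as unassigned.
    Proportions are member counts over the cluster size.
    """
    if not consensuses:
        raise ValueError("consensuses must not be empty")
    if cluster.size == 0:
        raise ValueError("cluster must not be empty")
    read_length = max(len(b) for _, b in cluster.representative_sequences)
    refs = {
        label: aln.tile_reference(seq, read_length) if tile_for_reads else seq
        for label, seq in consensuses.items()
    }
    labels = sorted(refs)
    counts = {label: 0 for label in labels}
    unassigned = 0
    for _, bases in cluster.representative_sequences:
        best_label, best_ident = None, -1.0
        for label in labels:  # lexicographic order makes ties deterministic
            ident = aln.identity_to_reference(bases, refs[label])
            if ident > best_ident:
                best_label, best_ident = label, ident
        if best_ident >= min_identity:
            counts[best_label] += 1
        else:
            unassigned += 1
    n = cluster.size
    return SubfamilyProfile(
        cluster_id=cluster.cluster_id,
        proportions={label: counts[label] / n for label in labels},
        unassigned_fraction=unassigned / n,
    )


def clusters_table(clusters: list[RepeatCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "genome_proportion": c.genome_proportion,
                "annotation": c.annotation or "",
            }
            for c in clusters
        ]
    )


def summary_table(summary: ClusteringSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "total_reads": summary.total_reads,
                "clustered_reads": summary.clustered_reads,
                "singleton_reads": summary.singleton_reads,
                "n_clusters": summary.n_clusters,
                "clustered_fraction": summary.clustered_fraction,
            }
        ]
    )
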
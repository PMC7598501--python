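import pytest

from censkim.clustering import build_similarity_graph, cluster_reads
from censkim.simulate import build_genome, default_genome_spec, simulate_wgs_reads


@pytest.fixture(scope="session")
def small_genome():
    """500-kb single-chromosome genome with the default beetle-like families."""
    return build_genome(default_genome_spec(500_000, seed=2))


@pytest.fixture(scope="session")
def small_wgs(small_genome):
    """Paired 0.2x WGS reads over the small genome (with ground truth)."""
    return simulate_wgs_reads(small_genome, 0.2, 151, paired=True, seed=3)


@pytest.fixture(scope="session")
def small_clustering(small_wgs):
    edges = build_similarity_graph(small_wgs)
    clusters, summary = cluster_reads(edges, small_wgs)
    return edges, clusters, summary
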
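"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seeded/pruned code paths: edges are
found by exhaustive all-pairs, all-shift, both-orientation comparison.
"""

import math

import numpy as np

from censkim.alignment import encode
from censkim.reads import ReadSet, reverse_complement


def brute_force_edges(rs: ReadSet, min_identity=0.90, min_overlap_fraction=0.55):
    arrays = [(r.id, encode(r.bases), encode(reverse_complement(r.bases))) for r in rs]
    L = len(rs[0].bases)
    minov = math.ceil(min_overlap_fraction * L)
    edges = set()
    for i in range(len(arrays)):
        a = arrays[i][1]
        for j in range(i + 1, len(arrays)):
            hit = False
            for b in (arrays[j][1], arrays[j][2]):
                for s in range(-(L - minov), L - minov + 1):
                    lo, hi = max(0, s), min(L, L + s)
                    m = int(np.count_nonzero(a[lo:hi] == b[lo - s : hi - s]))
                    if m / (hi - lo) >= min_identity:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                edges.add(frozenset((arrays[i][0], arrays[j][0])))
    return edges


def brute_force_components(rs: ReadSet, min_identity=0.90, min_overlap_fraction=0.55):
    """Connected components (>= 2 members) of the brute-force edge set,
    via plain union-find (independent of networkx)."""
    parent = {r.id: r.id for r in rs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for edge in brute_force_edges(rs, min_identity, min_overlap_fraction):
        a, b = sorted(edge)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for rid in parent:
        groups.setdefault(find(rid), set()).add(rid)
    return {frozenset(g) for g in groups.values() if len(g) >= 2}
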
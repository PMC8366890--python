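"""Lineage assignment, haplotype collapsing, and the haplotype network.

The two mitochondrial lineages are recovered as the two subtrees of the
root of a UPGMA clock tree — a deterministic stand-in for a Bayesian
clock phylogeny that is equivalent when the between-lineage divergence
dwarfs within-lineage diversity, as it does here (~5% vs ~0.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceMatrix
from .seqio import Alignment
from .trees import UltrametricTree, build_tree_from_heights


class LineageError(ValueError):
    pass


# ----------------------------------------------------------------------
# UPGMA


def upgma(dm: DistanceMatrix) -> UltrametricTree:
    """Average-linkage (UPGMA) clustering into an ultrametric tree.

    Node height is half the average distance between the merged
    clusters.  Ties are broken by the lexicographically smallest pair
    of cluster representatives (a cluster is represented by its
    smallest member id), so the output is reproducible regardless of
    input order.
    """
    n = len(dm.sample_ids)
    if n < 2:
        raise LineageError("UPGMA needs at least 2 samples")
    if not np.all(np.isfinite(dm.values)):
        raise LineageError("UPGMA requires finite distances (saturated matrix?)")

    d = dm.values.astype(float).copy()
    sizes = np.ones(n)
    reps = list(dm.sample_ids)          # representative (min member id) per cluster
    node_ref: list[object] = list(dm.sample_ids)  # leaf label or merge index
    active = list(range(n))
    merges: list[tuple[float, object, object]] = []

    while len(active) > 1:
        # locate the minimum-distance active pair, ties by rep-id pair
        best = None
        for ai in range(len(active)):
            i = active[ai]
            for aj in range(ai + 1, len(active)):
                j = active[aj]
                key_pair = tuple(sorted((reps[i], reps[j])))
                cand = (d[i, j], key_pair, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, i, j = best
        height = dist / 2.0
        merges.append((height, node_ref[i], node_ref[j]))
        # merge j into i
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            d[i, k] = d[k, i] = (ni * d[i, k] + nj * d[j, k]) / (ni + nj)
        sizes[i] = ni + nj
        reps[i] = min(reps[i], reps[j])
        node_ref[i] = len(merges) - 1
        active.remove(j)

    return build_tree_from_heights(merges, dm.sample_ids)


# ----------------------------------------------------------------------
# Lineage assignment


@dataclass(frozen=True)
class LineageAssignment:
    labels: dict[str, str]          # sample id -> {northern, southern}
    split_depth: float              # height of the partitioning (root) node
    anchor_policy: str

    @property
    def northern(self) -> frozenset[str]:
        return frozenset(s for s, l in self.labels.items() if l == "northern")

    @property
    def southern(self) -> frozenset[str]:
        return frozenset(s for s, l in self.labels.items() if l == "southern")


def assign_lineages(
    tree: UltrametricTree,
    anchors: tuple[set[str], set[str]] | None = None,
) -> LineageAssignment:
    """Partition samples into the two subtrees of the root.

    ``anchors``, when given, is a pair ``(northern_ids, southern_ids)``
    of reference samples that orient the labels; any one anchor fixes
    its group.  Without anchors, "northern" is the group containing the
    lexicographically smallest sample id (recorded in
    ``anchor_policy``).
    """
    if tree.n_leaves < 2:
        raise LineageError("need at least 2 leaves to assign lineages")
    group_a, group_b = tree.root_split()

    if anchors is not None:
        north_ref, south_ref = set(anchors[0]), set(anchors[1])
        known = north_ref | south_ref
        unknown = known - (group_a | group_b)
        if unknown:
            raise LineageError(f"anchor ids not in tree: {sorted(unknown)}")
        votes_a = len(north_ref & group_a) + len(south_ref & group_b)
        votes_b = len(north_ref & group_b) + len(south_ref & group_a)
        if votes_a and votes_b:
            raise LineageError("anchors span both root subtrees inconsistently")
        if not (votes_a or votes_b):
            raise LineageError("no anchors usable for orientation")
        northern = group_a if votes_a else group_b
        policy = "anchored"
    else:
        smallest = min(group_a | group_b)
        northern = group_a if smallest in group_a else group_b
        policy = "lexicographic-smallest-id"

    labels = {}
    for s in group_a | group_b:
        labels[s] = "northern" if s in northern else "southern"
    return LineageAssignment(labels, tree.root_height, policy)


# ----------------------------------------------------------------------
# Haplotypes


@dataclass(frozen=True)
class HaplotypeTable:
    """haplotype id -> (representative sequence, member ids, count)."""

    sequences: dict[str, str]
    members: dict[str, tuple[str, ...]]

    @property
    def counts(self) -> dict[str, int]:
        return {h: len(m) for h, m in self.members.items()}

    @property
    def n_haplotypes(self) -> int:
        return len(self.sequences)

    def haplotype_of(self) -> dict[str, str]:
        return {s: h for h, mem in self.members.items() for s in mem}


def collapse_haplotypes(alignment: Alignment) -> HaplotypeTable:
    """Group samples with strictly identical (case-normalized) rows.

    Ambiguity codes are compared literally — no wildcard matching — and
    haplotype ids ``H1, H2, ...`` follow first occurrence order.
    """
    seen: dict[str, str] = {}
    sequences: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for sid, seq in alignment.sequence_strings().items():
        if seq not in seen:
            hid = f"H{len(seen) + 1}"
            seen[seq] = hid
            sequences[hid] = seq
            members[hid] = []
        members[seen[seq]].append(sid)
    return HaplotypeTable(sequences, {h: tuple(m) for h, m in members.items()})


# ----------------------------------------------------------------------
# Haplotype network (minimum spanning tree over mutation steps)


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]  # (hap_i, hap_j, mismatch steps)

    @property
    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges)


def _mismatches(a: str, b: str) -> int:
    xa = np.frombuffer(a.encode(), dtype=np.uint8)
    xb = np.frombuffer(b.encode(), dtype=np.uint8)
    return int((xa != xb).sum())


def build_network(haps: HaplotypeTable) -> HaplotypeNetwork:
    """Minimum spanning tree over haplotypes under mismatch-count distance.

    Kruskal with deterministic tie-break on (weight, id pair); edge
    weights are integer mutation steps.
    """
    ids = sorted(haps.sequences, key=lambda h: int(h[1:]))
    if not ids:
        raise LineageError("empty haplotype table")
    if len(ids) == 1:
        return HaplotypeNetwork((ids[0],), ())

    edges = []
    for i, hi in enumerate(ids):
        for hj in ids[i + 1:]:
            w = _mismatches(haps.sequences[hi], haps.sequences[hj])
            edges.append((w, hi, hj))
    edges.sort(key=lambda e: (e[0], e[1], e[2]))

    parent = {h: h for h in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    chosen = []
    for w, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            chosen.append((a, b, w))
            if len(chosen) == len(ids) - 1:
                break
    return HaplotypeNetwork(tuple(ids), tuple(chosen))
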
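import numpy as np
import pytest

import psncomm as pc


@pytest.fixture
def ala_polymer():
    """Factory: all-alanine polymer (one side-chain atom per residue), so
    contact counts from planted chains are exactly min_atom_pairs."""

    def make(n_residues, seed=0, frames_per_window=50):
        return pc.make_reference_polymer(
            n_residues,
            seed=seed,
            sequence=["ALA"] * n_residues,
            frames_per_window=frames_per_window,
        )

    return make


@pytest.fixture
def replicate_frames(ala_polymer):
    """Factory: a static ensemble with n identical frames (no noise), the
    cleanest substrate for planting contact chains."""

    def make(n_residues, n_frames, frames_per_window=50):
        ref = ala_polymer(n_residues, frames_per_window=frames_per_window)
        coords = np.repeat(ref.coords, n_frames, axis=0)
        return pc.Ensemble(
            coords=coords, atoms=ref.atoms, frames_per_window=frames_per_window
        )

    return make


# -- independent oracles -------------------------------------------------------


def bfs_distances(n_nodes, edges):
    """Hand-rolled breadth-first-search hop distances (oracle)."""
    from collections import deque

    adj = {i: [] for i in range(n_nodes)}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    dist = np.full((n_nodes, n_nodes), np.inf)
    for s in range(n_nodes):
        dist[s, s] = 0
        queue = deque([s])
        while queue:
            cur = queue.popleft()
            for nb in adj[cur]:
                if not np.isfinite(dist[s, nb]):
                    dist[s, nb] = dist[s, cur] + 1
                    queue.append(nb)
    return dist


class UnionFind:
    """Hand-rolled union-find (oracle for cluster decomposition)."""

    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def components(self, n):
        comps = {}
        for x in range(n):
            comps.setdefault(self.find(x), set()).add(x)
        return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


@pytest.fixture
def bfs_oracle():
    return bfs_distances


@pytest.fixture
def union_find_oracle():
    def components(n_nodes, edges):
        uf = UnionFind(n_nodes)
        for u, v in edges:
            uf.union(u, v)
        return [c for c in uf.components(n_nodes) if len(c) > 1]

    return components
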
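"""Protein structure networks from residue interaction strengths.

The network is built per frame from the number of distinct side-chain
atom-pair contacts ``n_ij`` between residues i and j within a distance cutoff
(default 0.45 nm), normalized by residue-type-specific values::

    I_ij = 100 * n_ij / sqrt(N_i * N_j)

(the factor 100 puts I on the percent scale of the PSN literature, where the
largest-cluster transition is scanned over I_min in [0, 40]).  Residues are
nodes; an edge is drawn when I_ij exceeds, strictly, a cutoff I_min.  Nodes
with zero edges are orphans; nodes at or above a degree threshold are hubs;
clusters are the connected components of the graph.  The critical cutoff
I_crit is the I_min at the main transition (largest single-step drop) of the
largest-cluster size along an I_min scan.

A consensus network over a trajectory keeps only edges present (above I_min)
in at least a stated fraction of frames — by default half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .ensemble import AtomSelection, Ensemble
from .exceptions import (
    InvalidArgumentError,
    NormalizationError,
    NoTransitionError,
    SelectionError,
)

DEFAULT_CUTOFF = 0.45  # nm
DEFAULT_SEQ_EXCLUSION = 2  # |i - j| >= 2: exclude covalent neighbours
DEFAULT_HUB_DEGREE = 4
DEFAULT_PERSISTENCE = 0.5


def count_atom_pairs(
    ensemble: Ensemble,
    selection: AtomSelection,
    cutoff: float = DEFAULT_CUTOFF,
    seq_exclusion: int = DEFAULT_SEQ_EXCLUSION,
) -> np.ndarray:
    """Per-frame distinct atom-pair contact counts.

    Returns an integer array of shape ``(n_frames, n_res, n_res)`` whose
    (f, i, j) entry is the number of distinct atom pairs (a in i, b in j)
    with ||a - b|| <= cutoff in frame f, for |i - j| >= seq_exclusion;
    diagonal and excluded pairs are zero.  Each atom pair counts once, but an
    atom may participate in several pairs.
    """
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be > 0")
    if len(selection.flat) == 0:
        raise SelectionError("empty atom selection")
    n_res = selection.n_residues
    flat = selection.flat
    owner = selection.atom_residue
    counts = np.zeros((ensemble.n_frames, n_res, n_res), dtype=np.int64)
    for f in range(ensemble.n_frames):
        tree = cKDTree(ensemble.coords[f, flat])
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ri = owner[pairs[:, 0]]
        rj = owner[pairs[:, 1]]
        keep = np.abs(ri - rj) >= seq_exclusion
        ri, rj = ri[keep], rj[keep]
        np.add.at(counts[f], (ri, rj), 1)
        np.add.at(counts[f], (rj, ri), 1)
    return counts


@dataclass
class NormalizationTable:
    """Residue-type normalization values N used in the interaction strength.

    In the PSN literature these come from a large protein dataset (the
    maximum connectivity a residue type attains); here they may also be
    derived from the ensemble itself (:func:`self_normalization`).
    """

    values: dict
    provenance: str = "user"

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v <= 0:
                raise InvalidArgumentError(f"normalization for {name} must be > 0")

    def __getitem__(self, res_name: str) -> float:
        try:
            return float(self.values[res_name])
        except KeyError:
            raise NormalizationError(
                f"no normalization value for residue type {res_name!r}"
            ) from None

    @classmethod
    def uniform(cls, value: float, res_names) -> "NormalizationTable":
        return cls({name: float(value) for name in set(res_names)}, provenance="uniform")


def interaction_strength(
    n_ij: np.ndarray,
    residue_types,
    table: NormalizationTable,
    percent: bool = True,
) -> np.ndarray:
    """Interaction strengths I_ij = 100 * n_ij / sqrt(N_i * N_j).

    ``n_ij`` may be a single residue x residue matrix or a per-frame stack;
    the normalization broadcasts over leading axes.  ``percent=False`` drops
    the factor 100.
    """
    n_ij = np.asarray(n_ij, dtype=float)
    n_res = n_ij.shape[-1]
    if len(residue_types) != n_res:
        raise InvalidArgumentError("residue_types length must match matrix order")
    norms = np.array([table[t] for t in residue_types])
    denom = np.sqrt(norms[:, None] * norms[None, :])
    scale = 100.0 if percent else 1.0
    return scale * n_ij / denom


def self_normalization(
    ensemble: Ensemble,
    selection: AtomSelection,
    cutoff: float = DEFAULT_CUTOFF,
    seq_exclusion: int = DEFAULT_SEQ_EXCLUSION,
) -> NormalizationTable:
    """Normalization values derived from the ensemble itself.

    For each residue type, N is the maximum over residues of that type of
    the total contacts the residue makes (mean over frames), floored at 1 so
    values stay strictly positive even for isolated residues.
    """
    if ensemble.n_frames < 1:
        raise InvalidArgumentError("ensemble must have at least one frame")
    counts = count_atom_pairs(ensemble, selection, cutoff, seq_exclusion)
    mean_counts = counts.mean(axis=0)
    totals = mean_counts.sum(axis=1)
    values: dict = {}
    for res, name in enumerate(ensemble.residue_names):
        values[name] = max(values.get(name, 1.0), float(totals[res]), 1.0)
    return NormalizationTable(values, provenance="self")


@dataclass
class PSNGraph:
    """A protein structure network at a given I_min.

    ``clusters`` are the connected components restricted to non-orphan nodes,
    sorted by decreasing size; ``orphans`` are the zero-degree nodes.  The
    largest-cluster size of an edgeless graph is defined as 0, so that I_min
    scans terminate at zero.
    """

    graph: nx.Graph
    i_min: float = 0.0
    clusters: list = field(init=False)
    degrees: dict = field(init=False)
    orphans: list = field(init=False)

    def __post_init__(self) -> None:
        self.degrees = dict(self.graph.degree())
        self.orphans = sorted(n for n, d in self.degrees.items() if d == 0)
        comps = [set(c) for c in nx.connected_components(self.graph) if len(c) > 1]
        self.clusters = sorted(comps, key=lambda c: (-len(c), min(c)))

    @property
    def largest_cluster_size(self) -> int:
        return len(self.clusters[0]) if self.clusters else 0

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def has_edge(self, u, v) -> bool:
        return self.graph.has_edge(u, v)

    @classmethod
    def from_edges(cls, n_nodes: int, edges, i_min: float = 0.0, weights=None) -> "PSNGraph":
        g = nx.Graph()
        g.add_nodes_from(range(n_nodes))
        for k, (u, v) in enumerate(edges):
            w = 1.0 if weights is None else float(weights[k])
            g.add_edge(int(u), int(v), weight=w)
        return cls(graph=g, i_min=i_min)


def build_psn(I_ij: np.ndarray, i_min: float) -> PSNGraph:
    """Build the network with the strict edge rule I_ij > I_min.

    The matrix must be symmetric; sequence-neighbour exclusion is applied
    upstream in :func:`count_atom_pairs`, where covalent adjacency is known.
    """
    I_ij = np.asarray(I_ij, dtype=float)
    if I_ij.ndim != 2 or I_ij.shape[0] != I_ij.shape[1]:
        raise InvalidArgumentError("I_ij must be a square matrix")
    if not np.allclose(I_ij, I_ij.T):
        raise InvalidArgumentError("I_ij must be symmetric")
    n = I_ij.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(I_ij > i_min, k=1))
    for u, v in zip(ii, jj):
        g.add_edge(int(u), int(v), weight=float(I_ij[u, v]))
    return PSNGraph(graph=g, i_min=float(i_min))


@dataclass
class IminScanProfile:
    """Largest-cluster size as a function of I_min (the Fig-3-style profile)."""

    i_min_values: np.ndarray
    sizes: np.ndarray
    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        self.i_min_values = np.asarray(self.i_min_values, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=int)
        if np.any(np.diff(self.i_min_values) <= 0):
            raise InvalidArgumentError("i_min grid must be strictly increasing")


def imin_scan(
    I_ij: np.ndarray,
    start: float = 0.0,
    stop: float = 40.0,
    step: float = 0.2,
) -> IminScanProfile:
    """Scan I_min over a grid and record the largest-cluster size at each point."""
    if step <= 0:
        raise InvalidArgumentError("step must be > 0")
    n_points = int(np.floor((stop - start) / step + 1e-9)) + 1
    grid = start + step * np.arange(n_points)
    sizes = np.array([build_psn(I_ij, x).largest_cluster_size for x in grid])
    return IminScanProfile(grid, sizes, start=start, stop=stop, step=step)


@dataclass
class IcritResult:
    icrit: float
    drop: int
    index: int


def detect_icrit(profile: IminScanProfile, method: str = "max_drop") -> IcritResult:
    """Locate the main largest-cluster transition along an I_min scan.

    The transition is operationalized as the largest single-step drop in
    largest-cluster size; I_crit is the grid value just after that drop, with
    ties broken toward the smaller I_min.  ``method="smoothed"`` locates the
    maximum of a 3-point moving average of the step drops instead, which is
    more robust when the transition is spread over neighbouring grid points.
    """
    sizes = profile.sizes
    if len(sizes) < 3:
        raise InvalidArgumentError("profile needs at least 3 points")
    drops = sizes[:-1] - sizes[1:]
    if np.all(drops == 0):
        raise NoTransitionError("largest-cluster profile is flat: no transition")
    if method == "max_drop":
        k = int(np.argmax(drops))
        return IcritResult(
            icrit=float(profile.i_min_values[k + 1]), drop=int(drops[k]), index=k + 1
        )
    if method == "smoothed":
        kernel = np.ones(3) / 3.0
        smooth = np.convolve(drops, kernel, mode="same")
        k = int(np.argmax(smooth))
        return IcritResult(
            icrit=float(profile.i_min_values[k + 1]), drop=int(drops[k]), index=k + 1
        )
    raise InvalidArgumentError(f"unknown method {method!r}")


def hubs(graph: PSNGraph, min_degree: int = DEFAULT_HUB_DEGREE):
    """Highly connected nodes and the full per-residue degree profile.

    Returns ``(hub_list, degree_profile)`` where ``hub_list`` holds
    ``(residue, degree)`` pairs with degree >= min_degree sorted by degree
    descending then residue index, and ``degree_profile`` maps every node to
    its degree.
    """
    profile = dict(sorted(graph.degrees.items()))
    hub_list = sorted(
        ((n, d) for n, d in profile.items() if d >= min_degree),
        key=lambda t: (-t[1], t[0]),
    )
    return hub_list, profile


def consensus_psn(
    per_frame_I: np.ndarray,
    i_min: float,
    persistence_threshold: float = DEFAULT_PERSISTENCE,
):
    """Consensus network over frames: keep edges present in enough frames.

    An edge (i, j) is kept iff the fraction of frames with I_ij > i_min is at
    least ``persistence_threshold`` ("at least half" by default).  Returns
    ``(PSNGraph, persistence_matrix)``; edge weights on the graph are the
    per-edge persistence fractions, and the full candidate persistence matrix
    is returned for all pairs.
    """
    per_frame_I = np.asarray(per_frame_I, dtype=float)
    if per_frame_I.ndim != 3:
        raise InvalidArgumentError("per_frame_I must be (frames, n, n)")
    if per_frame_I.shape[0] < 2:
        raise InvalidArgumentError("consensus needs at least 2 frames")
    persistence = (per_frame_I > i_min).mean(axis=0)
    n = per_frame_I.shape[1]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(persistence >= persistence_threshold, k=1))
    for u, v in zip(ii, jj):
        g.add_edge(int(u), int(v), weight=float(persistence[u, v]))
    return PSNGraph(graph=g, i_min=float(i_min)), persistence


def window_consensus_graphs(
    per_frame_I: np.ndarray,
    i_min: float,
    frames_per_window: int,
    persistence_threshold: float = DEFAULT_PERSISTENCE,
) -> list:
    """One consensus network per non-overlapping window of frames.

    Trailing frames that do not fill a window are dropped, mirroring the
    windowing of the correlation stage.  These per-window networks are the
    denominator of path occurrence probabilities.
    """
    per_frame_I = np.asarray(per_frame_I, dtype=float)
    n_frames = per_frame_I.shape[0]
    if frames_per_window < 2:
        raise InvalidArgumentError("frames_per_window must be >= 2")
    n_windows = n_frames // frames_per_window
    if n_windows == 0:
        raise InvalidArgumentError("not enough frames for one window")
    graphs = []
    for w in range(n_windows):
        chunk = per_frame_I[w * frames_per_window : (w + 1) * frames_per_window]
        graph, _ = consensus_psn(chunk, i_min, persistence_threshold)
        graphs.append(graph)
    return graphs
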
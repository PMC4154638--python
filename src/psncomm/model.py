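"""Model/Results interface and end-to-end pipeline orchestration.

:class:`CommunicationModel` bundles a conformational ensemble with a target
residue set and an :class:`AnalysisConfig`; ``fit()`` runs the full analysis
cascade — contact counting, interaction strengths, I_min scan and I_crit,
consensus network, hubs, windowed generalized-correlation matrices,
correlation-filtered shortest paths, long-range classification and the
occurrence-weighted meta-graph — and returns a :class:`CommunicationResults`
carrying every intermediate product, a ``summary()`` table, plotting helpers
and ``save()``/``compare()``.

:func:`run_pipeline` drives the same computation from a config file and
writes a run directory of artifacts with a machine-readable manifest;
:func:`compare_runs` reproduces the free-vs-bound comparison logic from two
such directories.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as _io
from . import lmi as _lmi
from . import paths as _paths
from . import psn as _psn
from .ensemble import Ensemble, read_ensemble, select_atoms
from .exceptions import InvalidArgumentError, PsncommError

_STAGES = (
    "selection",
    "contacts",
    "normalization",
    "interaction_strength",
    "imin_scan",
    "consensus",
    "hubs",
    "lmi",
    "paths",
    "metagraph",
)


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, defaulting to the published
    protocol values (0.45 nm contact cutoff; I_min scan 0–40 in steps of 0.2;
    edge persistence 0.5; correlation cutoff 0.5; path occurrence 0.15; more
    than three nodes per path; long-range at eight or more nodes; hub degree
    four or more)."""

    input_path: str | None = None
    input_format: str = "pdb"
    topology: str | None = None
    selection_policy: str = "side-chain-heavy"
    cutoff: float = 0.45  # nm
    seq_exclusion: int = 2
    imin_start: float = 0.0
    imin_stop: float = 40.0
    imin_step: float = 0.2
    i_min: float | None = None  # None: use the detected I_crit
    persistence_threshold: float = 0.5
    window_frames: int | None = None  # None: use the ensemble's frames_per_window
    lmi_cutoff: float = 0.5
    min_occurrence: float = 0.15
    min_node_count: int = 4
    long_range_nodes: int = 8
    hub_min_degree: int = 4
    normalization: dict | None = None  # residue-type -> N; None: self-normalize
    targets: list = field(default_factory=list)
    seed: int = 0
    output_dir: str = "psncomm_run"

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise InvalidArgumentError("cutoff must be > 0")
        if self.imin_step <= 0:
            raise InvalidArgumentError("imin_step must be > 0")
        if not 0.0 < self.persistence_threshold <= 1.0:
            raise InvalidArgumentError("persistence_threshold must be in (0, 1]")
        if not 0.0 < self.lmi_cutoff < 1.0:
            raise InvalidArgumentError("lmi_cutoff must be in (0, 1)")
        if not 0.0 <= self.min_occurrence <= 1.0:
            raise InvalidArgumentError("min_occurrence must be in [0, 1]")
        if self.min_node_count < 2:
            raise InvalidArgumentError("min_node_count must be >= 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


class CommunicationModel:
    """The ensemble-communication model: a conformational ensemble, a target
    residue set, and the analysis parameters.

    Parameters
    ----------
    ensemble
        The conformational ensemble to analyse.
    targets
        Residue indices of the target region paths are directed to (e.g. the
        DNA-binding loops); may be empty, in which case the path stages are
        skipped.
    config
        Analysis parameters; defaults to the published protocol values.
    """

    def __init__(self, ensemble: Ensemble, targets=None, config: AnalysisConfig | None = None):
        self.ensemble = ensemble
        self.config = config or AnalysisConfig()
        self.config.validate()
        if targets is not None:
            self.config.targets = sorted(int(t) for t in targets)

    @classmethod
    def from_file(cls, path, targets=None, config: AnalysisConfig | None = None, **read_kwargs):
        cfg = config or AnalysisConfig()
        ens = read_ensemble(
            path,
            format=cfg.input_format,
            topology=cfg.topology,
            **read_kwargs,
        )
        return cls(ens, targets=targets, config=cfg)

    def fit(self) -> "CommunicationResults":
        cfg = self.config
        ens = self.ensemble
        stage = "selection"
        try:
            side_sel = select_atoms(ens, cfg.selection_policy)
            ca_sel = select_atoms(ens, "calpha")

            stage = "contacts"
            per_frame_n = _psn.count_atom_pairs(
                ens, side_sel, cutoff=cfg.cutoff, seq_exclusion=cfg.seq_exclusion
            )
            mean_n = per_frame_n.mean(axis=0)

            stage = "normalization"
            if cfg.normalization:
                table = _psn.NormalizationTable(dict(cfg.normalization), provenance="config")
            else:
                table = _psn.self_normalization(
                    ens, side_sel, cutoff=cfg.cutoff, seq_exclusion=cfg.seq_exclusion
                )

            stage = "interaction_strength"
            res_types = ens.residue_names
            per_frame_I = _psn.interaction_strength(per_frame_n, res_types, table)
            mean_I = _psn.interaction_strength(mean_n, res_types, table)

            stage = "imin_scan"
            scan = _psn.imin_scan(mean_I, cfg.imin_start, cfg.imin_stop, cfg.imin_step)
            try:
                icrit = _psn.detect_icrit(scan)
            except PsncommError:
                icrit = None
            i_min = cfg.i_min if cfg.i_min is not None else (
                icrit.icrit if icrit is not None else 0.0
            )

            stage = "consensus"
            consensus, persistence = _psn.consensus_psn(
                per_frame_I, i_min, cfg.persistence_threshold
            )
            window_frames = cfg.window_frames or ens.frames_per_window
            window_graphs = _psn.window_consensus_graphs(
                per_frame_I, i_min, window_frames, cfg.persistence_threshold
            )

            stage = "hubs"
            hub_list, degree_profile = _psn.hubs(consensus, cfg.hub_min_degree)

            stage = "lmi"
            lmi_windows, lmi_average = _lmi.lmi_windows(ens, ca_sel, window_frames)

            stage = "paths"
            path_set = None
            partition = None
            metagraph = None
            if cfg.targets:
                path_set = _paths.paths_to_targets(
                    consensus,
                    lmi_average,
                    window_graphs,
                    cfg.targets,
                    min_occurrence=cfg.min_occurrence,
                    min_node_count=cfg.min_node_count,
                    lmi_cutoff=cfg.lmi_cutoff,
                )
                partition = _paths.classify_long_range(path_set.paths, cfg.long_range_nodes)
                stage = "metagraph"
                if path_set.paths:
                    metagraph = _paths.build_metagraph(path_set.paths)
        except PsncommError as exc:
            raise PsncommError(f"pipeline stage {stage!r} failed: {exc}") from exc

        return CommunicationResults(
            model=self,
            per_frame_n=per_frame_n,
            mean_n=mean_n,
            normalization=table,
            per_frame_I=per_frame_I,
            mean_I=mean_I,
            scan=scan,
            icrit=icrit,
            i_min=float(i_min),
            consensus=consensus,
            persistence=persistence,
            window_graphs=window_graphs,
            hub_list=hub_list,
            degree_profile=degree_profile,
            lmi_windows=lmi_windows,
            lmi_average=lmi_average,
            path_set=path_set,
            long_range=partition,
            metagraph=metagraph,
        )


@dataclass
class CommunicationResults:
    """Everything the fitted pipeline computed, with reporting helpers."""

    model: CommunicationModel
    per_frame_n: np.ndarray
    mean_n: np.ndarray
    normalization: _psn.NormalizationTable
    per_frame_I: np.ndarray
    mean_I: np.ndarray
    scan: _psn.IminScanProfile
    icrit: _psn.IcritResult | None
    i_min: float
    consensus: _psn.PSNGraph
    persistence: np.ndarray
    window_graphs: list
    hub_list: list
    degree_profile: dict
    lmi_windows: list
    lmi_average: _lmi.CorrelationMatrix
    path_set: _paths.PathSet | None
    long_range: _paths.LongRangePartition | None
    metagraph: _paths.MetaGraph | None

    # -- reporting -------------------------------------------------------------

    def summary(self) -> str:
        ens = self.model.ensemble
        cfg = self.model.config
        lines = [
            "Ensemble communication analysis",
            "=" * 47,
            f"frames: {ens.n_frames}   residues: {ens.n_residues}   atoms: {ens.n_atoms}",
            f"contact cutoff: {cfg.cutoff} nm   selection: {cfg.selection_policy}",
            f"I_min scan: {cfg.imin_start}..{cfg.imin_stop} step {cfg.imin_step}",
        ]
        if self.icrit is not None:
            lines.append(
                f"I_crit: {self.icrit.icrit:.1f} (largest-cluster drop {self.icrit.drop})"
            )
        lines.append(f"I_min used: {self.i_min:.1f}")
        lines.append(
            f"consensus network: {len(self.consensus.edges)} edges, "
            f"{len(self.consensus.clusters)} clusters "
            f"(largest {self.consensus.largest_cluster_size}), "
            f"{len(self.consensus.orphans)} orphans"
        )
        lines.append(
            f"hubs (degree >= {cfg.hub_min_degree}): "
            + (
                ", ".join(f"{n}({d})" for n, d in self.hub_list[:10])
                if self.hub_list
                else "none"
            )
        )
        lines.append(
            f"LMI: {len(self.lmi_windows)} windows of "
            f"{self.lmi_windows[0].n_frames if self.lmi_windows else 0} frames; "
            f"significant pairs (r >= {cfg.lmi_cutoff}): "
            f"{int(_lmi.apply_significance_cutoff(self.lmi_average, cfg.lmi_cutoff).sum() // 2)}"
        )
        if self.path_set is not None:
            lines.append(
                f"paths to targets {cfg.targets}: {len(self.path_set)} retained "
                f"({len(self.path_set.direct_edges)} direct edges reported apart; "
                f"rejected: {self.path_set.rejected})"
            )
            if self.long_range is not None:
                lines.append(
                    f"long-range (>= {cfg.long_range_nodes} nodes): "
                    f"{len(self.long_range.long_range)} of {self.long_range.total}"
                )
            if self.metagraph is not None:
                med = self.metagraph.top_mediators[:5]
                lines.append(f"top mediator residues: {med}")
        return "\n".join(lines)

    # -- plotting --------------------------------------------------------------

    def plot_scan(self, ax=None):
        """Largest-cluster size vs I_min (the transition profile)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.scan.i_min_values, self.scan.sizes, drawstyle="steps-post")
        if self.icrit is not None:
            ax.axvline(self.icrit.icrit, linestyle="--", color="crimson")
        ax.set_xlabel("$I_{min}$")
        ax.set_ylabel("largest cluster size")
        return ax

    def plot_degree_profile(self, ax=None):
        """Per-residue node degree in the consensus network."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        nodes = sorted(self.degree_profile)
        ax.bar(nodes, [self.degree_profile[n] for n in nodes], width=0.8)
        ax.axhline(self.model.config.hub_min_degree, linestyle="--", color="gray")
        ax.set_xlabel("residue")
        ax.set_ylabel("degree")
        return ax

    def plot_path_length_histogram(self, ax=None):
        """Distribution of retained path lengths in nodes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.long_range is not None:
            hist = self.long_range.histogram
            ax.bar(list(hist), list(hist.values()), width=0.8)
        ax.set_xlabel("path length (nodes)")
        ax.set_ylabel("paths")
        return ax

    # -- persistence -----------------------------------------------------------

    def save(self, run_dir) -> Path:
        """Write the run directory of artifacts and its manifest."""
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        ens = self.model.ensemble
        cfg = self.model.config
        labels = [f"{name}{rid}" for name, rid in zip(ens.residue_names, ens.residue_ids)]

        _io.write_matrix_csv(self.mean_n, labels, run_dir / "nij_mean.csv")
        _io.write_matrix_csv(self.mean_I, labels, run_dir / "iij_mean.csv")
        _io.write_scan_csv(self.scan, run_dir / "imin_scan.csv")
        _io.write_graph(
            self.consensus.graph,
            run_dir / "consensus_psn.gml",
            run_dir / "consensus_psn.dot",
        )
        _io.write_json(
            {
                "hub_min_degree": cfg.hub_min_degree,
                "hubs": [{"residue": n, "degree": d} for n, d in self.hub_list],
                "degree_profile": {str(k): v for k, v in self.degree_profile.items()},
            },
            run_dir / "hubs.json",
        )
        _io.write_matrix_csv(self.lmi_average.values, labels, run_dir / "lmi_average.csv")
        _io.write_square_dat(self.lmi_average.values, run_dir / "lmi_average.dat")
        for m in self.lmi_windows:
            _io.write_square_dat(m.values, run_dir / f"lmi_window_{m.window:03d}.dat")
        if self.path_set is not None:
            _io.write_paths_json(self.path_set, run_dir / "paths.json", labels)
            _io.write_json(
                {
                    "min_nodes": self.long_range.min_nodes,
                    "histogram": {str(k): v for k, v in self.long_range.histogram.items()},
                    "long_range": [p.to_dict(labels) for p in self.long_range.long_range],
                    "shorter": [p.to_dict(labels) for p in self.long_range.shorter],
                },
                run_dir / "long_range.json",
            )
        if self.metagraph is not None:
            _io.write_graph(
                self.metagraph.graph, run_dir / "metagraph.gml", run_dir / "metagraph.dot"
            )
            _io.write_json(
                {
                    "n_paths": self.metagraph.n_paths,
                    "participation": {str(k): v for k, v in self.metagraph.participation.items()},
                },
                run_dir / "mediators.json",
            )
        cfg.to_yaml(run_dir / "config_resolved.yaml")
        _io.write_json(self._manifest(), run_dir / "manifest.json")
        return run_dir

    def _manifest(self) -> dict:
        import networkx
        import numpy
        import scipy

        cfg = self.model.config
        return {
            "stages_complete": list(_STAGES),
            "parameters": cfg.to_dict(),
            "seed": cfg.seed,
            "n_frames": self.model.ensemble.n_frames,
            "n_residues": self.model.ensemble.n_residues,
            "icrit": None if self.icrit is None else self.icrit.icrit,
            "i_min_used": self.i_min,
            "n_consensus_edges": len(self.consensus.edges),
            "n_paths_retained": None if self.path_set is None else len(self.path_set),
            "versions": {
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "networkx": networkx.__version__,
            },
        }

    # -- comparison ------------------------------------------------------------

    def compare(self, other: "CommunicationResults") -> dict:
        """Free-vs-bound style comparison against another fitted result."""
        degree_delta = {
            n: other.degree_profile.get(n, 0) - self.degree_profile.get(n, 0)
            for n in sorted(set(self.degree_profile) | set(other.degree_profile))
        }
        out = {
            "hub_degree_delta": {k: v for k, v in degree_delta.items() if v != 0},
            "lmi_frobenius": _lmi.frobenius_norm(self.lmi_average, other.lmi_average).frobenius,
        }
        if self.path_set is not None and other.path_set is not None:
            cmp_sets = _paths.compare_path_sets(
                self.path_set.paths,
                other.path_set.paths,
                self.model.config.long_range_nodes,
            )
            out["paths"] = {
                "only_a": [list(p.nodes) for p in cmp_sets.only_a],
                "only_b": [list(p.nodes) for p in cmp_sets.only_b],
                "shared": [list(p.nodes) for p in cmp_sets.shared],
                "long_range_count_a": cmp_sets.long_range_count_a,
                "long_range_count_b": cmp_sets.long_range_count_b,
                "long_range_relative_change": cmp_sets.long_range_relative_change,
            }
        return out


def run_pipeline(config: AnalysisConfig, ensemble: Ensemble | None = None) -> Path:
    """Run the full pipeline from a config and write the run directory.

    ``ensemble`` may be passed directly (e.g. a synthetic one); otherwise it
    is read from ``config.input_path``.  On a stage failure the partial run
    directory is kept with a ``FAILED`` marker naming the stage.
    """
    config.validate()
    run_dir = Path(config.output_dir)
    if ensemble is None:
        if config.input_path is None:
            raise InvalidArgumentError("config.input_path is required (or pass an ensemble)")
        try:
            ensemble = read_ensemble(
                config.input_path, format=config.input_format, topology=config.topology
            )
        except PsncommError as exc:
            raise PsncommError(f"pipeline stage 'read' failed: {exc}") from exc
    model = CommunicationModel(ensemble, config=config)
    try:
        results = model.fit()
    except PsncommError as exc:
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "FAILED").write_text(str(exc) + "\n")
        raise
    results.save(run_dir)
    return run_dir


def compare_runs(run_a, run_b) -> dict:
    """Compare two completed run directories (hubs, paths, correlation)."""
    import json

    run_a, run_b = Path(run_a), Path(run_b)
    for rd in (run_a, run_b):
        if not (rd / "manifest.json").exists() or (rd / "FAILED").exists():
            raise InvalidArgumentError(f"run directory {rd} is not a complete run")
    hubs_a = json.loads((run_a / "hubs.json").read_text())
    hubs_b = json.loads((run_b / "hubs.json").read_text())
    prof_a = {int(k): v for k, v in hubs_a["degree_profile"].items()}
    prof_b = {int(k): v for k, v in hubs_b["degree_profile"].items()}
    if set(prof_a) != set(prof_b):
        raise InvalidArgumentError(
            "runs use different residue numbering; re-run with a common mapping"
        )
    degree_delta = {n: prof_b[n] - prof_a[n] for n in sorted(prof_a) if prof_b[n] != prof_a[n]}

    lmi_a = _io.read_matrix_csv(run_a / "lmi_average.csv").to_numpy()
    lmi_b = _io.read_matrix_csv(run_b / "lmi_average.csv").to_numpy()
    cmp_lmi = _lmi.frobenius_norm(
        _lmi.CorrelationMatrix(lmi_a), _lmi.CorrelationMatrix(lmi_b)
    )

    out = {
        "hub_degree_delta": degree_delta,
        "lmi_frobenius": cmp_lmi.frobenius,
        "lmi_max_abs_difference": cmp_lmi.max_abs_difference,
    }
    paths_a_file = run_a / "paths.json"
    paths_b_file = run_b / "paths.json"
    if paths_a_file.exists() and paths_b_file.exists():
        manifest_a = json.loads((run_a / "manifest.json").read_text())
        long_range_nodes = manifest_a["parameters"]["long_range_nodes"]
        pa = [
            _paths.CommunicationPath(
                p["nodes"], occurrence=p["occurrence"], correlation_ok=p["correlation_ok"]
            )
            for p in json.loads(paths_a_file.read_text())["paths"]
        ]
        pb = [
            _paths.CommunicationPath(
                p["nodes"], occurrence=p["occurrence"], correlation_ok=p["correlation_ok"]
            )
            for p in json.loads(paths_b_file.read_text())["paths"]
        ]
        cmp_sets = _paths.compare_path_sets(pa, pb, long_range_nodes)
        out["paths"] = {
            "only_a": [list(p.nodes) for p in cmp_sets.only_a],
            "only_b": [list(p.nodes) for p in cmp_sets.only_b],
            "shared": [list(p.nodes) for p in cmp_sets.shared],
            "long_range_count_a": cmp_sets.long_range_count_a,
            "long_range_count_b": cmp_sets.long_range_count_b,
            "long_range_relative_change": cmp_sets.long_range_relative_change,
        }
    return out
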
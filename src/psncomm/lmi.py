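"""Linear mutual information between residue motions.

Correlated motions are quantified by the Gaussian (linear) mutual information
between the 3-D displacement vectors of two residues' Cα atoms,

    MI(i, j) = 1/2 [ ln det C_i + ln det C_j - ln det C_ij ],

where C_i and C_j are the 3x3 displacement covariance blocks and C_ij the
joint 6x6 block, mapped onto a generalized correlation coefficient

    r(i, j) = sqrt(1 - exp(-2 MI / 3))  in [0, 1],

which is 0 for uncorrelated and 1 for fully correlated motions and — unlike
the plain Pearson cross-correlation of displacements — does not depend on the
relative orientation of the fluctuations.  For isotropic equal-variance
motions with per-axis correlation ρ, r equals |ρ| exactly, which the
synthetic-ensemble generator exploits for estimator validation.

Matrices are computed over non-overlapping frame windows (the stand-in for
fixed-time windows, e.g. five ns) after least-squares superposition of each
window's frames onto the window-mean Cα structure, so rigid-body motion does
not masquerade as correlation.  A significance cutoff (default 0.5,
inclusive) separates meaningfully coupled pairs from noise, and matrices are
compared across replicates by the Frobenius norm of their difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .ensemble import AtomSelection, Ensemble
from .exceptions import InvalidArgumentError

DEFAULT_LMI_CUTOFF = 0.5
_REGULARIZATION = 1e-8  # nm², added to covariance diagonals


@dataclass
class CorrelationMatrix:
    """A residue x residue generalized-correlation matrix in [0, 1]."""

    values: np.ndarray
    window: object = "average"  # window index or "average"
    n_frames: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidArgumentError("correlation matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidArgumentError("correlation matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise InvalidArgumentError("correlation values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def order(self) -> int:
        return self.values.shape[0]


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` onto ``target`` (both (n, 3))."""
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    h = mc.T @ tc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mc @ rot + target.mean(axis=0)


def _superpose_window(coords: np.ndarray, n_iter: int = 3) -> np.ndarray:
    """Superpose every frame of a window onto the (iterated) window mean."""
    out = coords.copy()
    mean = out.mean(axis=0)
    for _ in range(n_iter):
        for f in range(out.shape[0]):
            out[f] = _kabsch(out[f], mean)
        mean = out.mean(axis=0)
    return out


def _gaussian_mi_matrix(disp: np.ndarray) -> np.ndarray:
    """Generalized correlation matrix from (frames, residues, 3) displacements."""
    n_frames, n_res, _ = disp.shape
    flat = disp.reshape(n_frames, n_res * 3)
    cov = (flat.T @ flat) / n_frames  # displacements are already mean-free
    cov = cov.reshape(n_res, 3, n_res, 3)
    reg = _REGULARIZATION * np.eye(3)
    logdet_marg = np.empty(n_res)
    for i in range(n_res):
        sign, logdet = np.linalg.slogdet(cov[i, :, i, :] + reg)
        if sign <= 0:
            warnings.warn(f"singular displacement covariance for residue {i}", stacklevel=2)
            logdet = -np.inf
        logdet_marg[i] = logdet
    r = np.eye(n_res)
    reg6 = _REGULARIZATION * np.eye(6)
    for i in range(n_res):
        for j in range(i + 1, n_res):
            joint = np.block(
                [[cov[i, :, i, :], cov[i, :, j, :]], [cov[j, :, i, :], cov[j, :, j, :]]]
            )
            sign, logdet_joint = np.linalg.slogdet(joint + reg6)
            mi = 0.5 * (logdet_marg[i] + logdet_marg[j] - logdet_joint)
            mi = max(mi, 0.0)  # numerical negatives mean independence
            val = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * mi / 3.0)))
            r[i, j] = r[j, i] = val
    return r


def lmi_windows(
    ensemble: Ensemble,
    calpha_selection: AtomSelection,
    window_frames: int | None = None,
    superpose: bool = True,
):
    """Windowed generalized-correlation matrices and their element-wise average.

    Frames are split into non-overlapping windows of ``window_frames``
    (defaulting to the ensemble's ``frames_per_window``); trailing frames not
    filling a window are dropped.  Returns ``(windows, average)`` where
    ``windows`` is a list of :class:`CorrelationMatrix` and ``average`` their
    element-wise mean.
    """
    if window_frames is None:
        window_frames = ensemble.frames_per_window
    if window_frames < 10:
        raise InvalidArgumentError("window_frames must be >= 10")
    if ensemble.n_frames < window_frames:
        raise InvalidArgumentError("total frames must be >= window_frames")
    if calpha_selection.policy != "calpha":
        raise InvalidArgumentError("lmi_windows requires the calpha selection")
    ca_idx = calpha_selection.flat
    n_windows = ensemble.n_frames // window_frames
    matrices = []
    for w in range(n_windows):
        chunk = ensemble.coords[w * window_frames : (w + 1) * window_frames, ca_idx, :]
        if superpose:
            chunk = _superpose_window(chunk)
        disp = chunk - chunk.mean(axis=0)
        matrices.append(
            CorrelationMatrix(_gaussian_mi_matrix(disp), window=w, n_frames=window_frames)
        )
    avg_values = np.mean([m.values for m in matrices], axis=0)
    average = CorrelationMatrix(avg_values, window="average", n_frames=n_windows * window_frames)
    return matrices, average


def apply_significance_cutoff(
    matrix: CorrelationMatrix, cutoff: float = DEFAULT_LMI_CUTOFF
) -> np.ndarray:
    """Boolean mask of significantly correlated residue pairs.

    True where the correlation is at or above the cutoff (inclusive) and
    i != j.
    """
    if not 0.0 < cutoff < 1.0:
        raise InvalidArgumentError("cutoff must be in (0, 1)")
    mask = matrix.values >= cutoff
    np.fill_diagonal(mask, False)
    return mask


@dataclass
class MatrixComparison:
    """Similarity summary of two correlation matrices."""

    frobenius: float
    max_abs_difference: float
    difference_quantiles: dict = field(default_factory=dict)


def frobenius_norm(A: CorrelationMatrix, B: CorrelationMatrix) -> MatrixComparison:
    """Frobenius norm of the difference, F = sqrt(sum_ij (a_ij - b_ij)^2).

    Also reports the maximum absolute element-wise difference and quantiles
    of |a_ij - b_ij| (the quantity whose tail characterizes replicate
    disagreement).
    """
    if A.order != B.order:
        raise InvalidArgumentError(
            f"matrix orders differ: {A.order} vs {B.order}"
        )
    diff = A.values - B.values
    abs_diff = np.abs(diff)
    qs = np.quantile(abs_diff, [0.5, 0.9, 0.99])
    return MatrixComparison(
        frobenius=float(np.sqrt(np.sum(diff**2))),
        max_abs_difference=float(abs_diff.max()),
        difference_quantiles={"q50": float(qs[0]), "q90": float(qs[1]), "q99": float(qs[2])},
    )


@dataclass
class ConsistencyReport:
    """Replicate-consistency report based on Frobenius norms.

    ``consistent`` is true when every pairwise replicate-to-replicate norm is
    smaller than every replicate-to-control norm — the ordering expected when
    replicates describe the same correlated motions and the control (e.g. an
    unfolding run) does not.
    """

    pairwise: dict
    vs_control: dict
    half_baseline: dict
    consistent: bool

    @property
    def max_pairwise(self) -> float:
        return max(self.pairwise.values()) if self.pairwise else float("nan")

    @property
    def min_vs_control(self) -> float:
        return min(self.vs_control.values()) if self.vs_control else float("nan")

    def to_dict(self) -> dict:
        return {
            "pairwise": {f"{i}-{j}": v for (i, j), v in self.pairwise.items()},
            "vs_control": {str(i): v for i, v in self.vs_control.items()},
            "half_baseline": {str(i): v for i, v in self.half_baseline.items()},
            "consistent": self.consistent,
        }


def replicate_consistency(
    matrices: list,
    control: CorrelationMatrix,
    per_window: list | None = None,
) -> ConsistencyReport:
    """Compare replicate average matrices with each other and with a control.

    ``per_window``, when given, is a per-replicate list of window matrices
    used to compute the within-trajectory baseline: the Frobenius norm
    between the averages of the first and second halves of each replicate's
    window sequence.
    """
    if len(matrices) < 2:
        raise InvalidArgumentError("need at least 2 replicate matrices")
    pairwise = {
        (i, j): frobenius_norm(matrices[i], matrices[j]).frobenius
        for i, j in combinations(range(len(matrices)), 2)
    }
    vs_control = {
        i: frobenius_norm(m, control).frobenius for i, m in enumerate(matrices)
    }
    half_baseline: dict = {}
    if per_window:
        for i, windows in enumerate(per_window):
            if len(windows) < 2:
                continue
            half = len(windows) // 2
            first = CorrelationMatrix(
                np.mean([w.values for w in windows[:half]], axis=0), window="first-half"
            )
            second = CorrelationMatrix(
                np.mean([w.values for w in windows[half:]], axis=0), window="second-half"
            )
            half_baseline[i] = frobenius_norm(first, second).frobenius
    consistent = max(pairwise.values()) < min(vs_control.values())
    return ConsistencyReport(
        pairwise=pairwise,
        vs_control=vs_control,
        half_baseline=half_baseline,
        consistent=consistent,
    )
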
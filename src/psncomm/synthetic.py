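"""Synthetic conformational ensembles with known ground truth.

Real ensemble-network studies start from MD trajectories that are rarely
deposited; this module replaces them with fully synthetic ensembles whose
correlation structure and contact network are known exactly, so that the
correlation estimator and the contact/path machinery can be validated against
planted truth:

* :func:`make_reference_polymer` builds a clash-free pseudo-polymer on a
  gentle helix, with one backbone carbon (CA) per residue and one to five
  pseudo-side-chain heavy atoms (glycine gets none, exercising the Cα
  fallback of the side-chain selection policy).
* :func:`sample_gaussian_ensemble` draws per-frame residue displacements from
  a multivariate normal with block-equicorrelation structure: residues in the
  same block share a per-axis correlation coefficient ρ, residues in
  different blocks are independent.  Side-chain atoms ride rigidly with their
  residue, so planted contact geometry survives sampling.
* :func:`plant_contact_chain` inserts a chain of persistent side-chain
  contacts: in exactly ``ceil(persistence * n_frames)`` frames (chosen by the
  chain's RNG seed) each consecutive residue pair of the chain has at least
  ``min_atom_pairs`` distinct side-chain atom pairs within 0.45 nm, and in
  all remaining frames those pairs are parked more than 0.6 nm apart.
  Contact atoms are added as extra pseudo-side-chain atoms positioned per
  frame, so pre-existing atoms (and hence all residue pairs outside the
  chain) are untouched.

The backbone spacing (1.2 nm) is deliberately larger than a real Cα-Cα
distance: it guarantees that non-adjacent residues have no background
contacts at the 0.45 nm cutoff, so the planted chain is the only contact
signal in the ensemble.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import Ensemble
from .exceptions import InvalidArgumentError

#: residue templates: three-letter code -> pseudo-side-chain atom names
#: (element = first letter).  Sizes span 0 (GLY) to 5 heavy atoms.
RESIDUE_TEMPLATES: dict[str, list[str]] = {
    "GLY": [],
    "ALA": ["CB"],
    "CYS": ["CB", "SG"],
    "THR": ["CB", "OG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1"],
}

_BACKBONE_SPACING = 1.2  # nm between consecutive CA atoms
_HELIX_RADIUS = 12.0  # nm
_HELIX_PITCH = 1.0  # nm per radian
_SIDECHAIN_OFFSET = 0.25  # nm, centroid distance from CA, radially outward
_SIDECHAIN_JITTER = 0.12  # nm, max atom distance from the centroid
_CONTACT_CUTOFF = 0.45  # nm
_PARK_MIN_SEPARATION = 0.6  # nm


@dataclass
class CovarianceSpec:
    """Ground-truth covariance of per-frame residue displacements.

    ``blocks`` is a list of ``(residue_set, rho)`` pairs: within each block
    every residue pair shares per-axis correlation ``rho``; across blocks and
    for unlisted residues displacements are independent.  All axes share the
    same structure and the same ``baseline_variance`` (nm²), which makes the
    generalized correlation coefficient of a block pair equal |rho| in closed
    form.
    """

    n_residues: int
    blocks: list[tuple[frozenset, float]] = field(default_factory=list)
    baseline_variance: float = 0.0025  # nm² (sigma = 0.5 Å, a typical RMSF scale)

    def __post_init__(self) -> None:
        if self.baseline_variance <= 0:
            raise InvalidArgumentError("baseline_variance must be > 0")
        self.blocks = [(frozenset(res), float(rho)) for res, rho in self.blocks]
        seen: set[int] = set()
        for res, rho in self.blocks:
            if not 0.0 <= rho < 1.0:
                raise InvalidArgumentError(f"block correlation {rho} outside [0, 1)")
            if any(r < 0 or r >= self.n_residues for r in res):
                raise InvalidArgumentError("block residue outside [0, n_residues)")
            if seen & res:
                raise InvalidArgumentError("block residue sets must be disjoint")
            seen |= res

    def correlation_matrix(self) -> np.ndarray:
        """The planted per-axis residue-residue correlation matrix."""
        corr = np.eye(self.n_residues)
        for res, rho in self.blocks:
            idx = sorted(res)
            for i in idx:
                for j in idx:
                    if i != j:
                        corr[i, j] = rho
        return corr

    def to_dict(self) -> dict:
        return {
            "n_residues": self.n_residues,
            "blocks": [[sorted(res), rho] for res, rho in self.blocks],
            "baseline_variance": self.baseline_variance,
        }


@dataclass
class PlantedChain:
    """A planted chain of persistent side-chain contacts.

    ``residues`` is the ordered node list of the ground-truth communication
    path; consecutive residues must be non-adjacent in sequence (|i-j| >= 2)
    so the contacts are non-covalent by the network's own convention.
    """

    residues: tuple
    min_atom_pairs: int = 4
    persistence: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.residues = tuple(int(r) for r in self.residues)
        if len(self.residues) < 2:
            raise InvalidArgumentError("a chain needs at least two residues")
        if len(set(self.residues)) != len(self.residues):
            raise InvalidArgumentError("chain residues must be distinct")
        for a, b in zip(self.residues, self.residues[1:]):
            if abs(a - b) < 2:
                raise InvalidArgumentError(
                    f"consecutive chain residues {a},{b} are sequence-adjacent"
                )
        if not 0.0 <= self.persistence <= 1.0:
            raise InvalidArgumentError("persistence must be in [0, 1]")
        if self.min_atom_pairs < 1 or self.min_atom_pairs > 8:
            raise InvalidArgumentError("min_atom_pairs must be in [1, 8]")

    @property
    def edges(self) -> list[tuple]:
        return list(zip(self.residues, self.residues[1:]))

    def to_dict(self) -> dict:
        return {
            "residues": list(self.residues),
            "min_atom_pairs": self.min_atom_pairs,
            "persistence": self.persistence,
            "rng_seed": self.rng_seed,
        }


def make_reference_polymer(
    n_residues: int,
    seed: int,
    sequence: list[str] | None = None,
    frames_per_window: int = 100,
) -> Ensemble:
    """Build a single-frame clash-free pseudo-polymer.

    Backbone carbons sit on a gentle helix with 1.2 nm spacing; each residue
    carries the pseudo-side-chain atoms of its (randomly drawn or supplied)
    residue type, placed radially outward within 0.3 nm of a side-chain
    centroid.  Deterministic for a fixed seed.
    """
    if n_residues < 5:
        raise InvalidArgumentError("n_residues must be >= 5")
    rng = np.random.default_rng(seed)
    if sequence is None:
        names = list(RESIDUE_TEMPLATES)
        sequence = [names[i] for i in rng.integers(0, len(names), size=n_residues)]
    elif len(sequence) != n_residues:
        raise InvalidArgumentError("sequence length must equal n_residues")
    for name in sequence:
        if name not in RESIDUE_TEMPLATES:
            raise InvalidArgumentError(f"unknown residue template {name!r}")

    arc_step = _BACKBONE_SPACING / math.hypot(_HELIX_RADIUS, _HELIX_PITCH)
    rows = []
    coords = []
    for res in range(n_residues):
        theta = res * arc_step
        ca = np.array(
            [
                _HELIX_RADIUS * math.cos(theta),
                _HELIX_RADIUS * math.sin(theta),
                _HELIX_PITCH * theta,
            ]
        )
        outward = np.array([math.cos(theta), math.sin(theta), 0.0])
        rows.append((res, res + 1, sequence[res], "CA", "C", False))
        coords.append(ca)
        centroid = ca + _SIDECHAIN_OFFSET * outward
        tangent = np.array([-math.sin(theta), math.cos(theta), 0.0])
        axial = np.array([0.0, 0.0, 1.0])
        for k, atom_name in enumerate(RESIDUE_TEMPLATES[sequence[res]]):
            # deterministic small offsets inside the jitter ball, plus a touch
            # of seeded noise so distinct seeds give distinct geometry
            angle = 2 * math.pi * k / 5.0
            offset = (
                _SIDECHAIN_JITTER
                * 0.8
                * (math.cos(angle) * tangent + math.sin(angle) * axial)
            )
            offset = offset + rng.uniform(-0.02, 0.02, size=3)
            rows.append((res, res + 1, sequence[res], atom_name, atom_name[0], False))
            coords.append(centroid + offset)
    atoms = pd.DataFrame(rows, columns=["res_index", "res_id", "res_name", "atom_name", "element", "is_hydrogen"])
    ensemble = Ensemble(
        coords=np.asarray(coords)[None, :, :],
        atoms=atoms,
        frames_per_window=frames_per_window,
    )
    _assert_clash_free(ensemble)
    return ensemble


def _assert_clash_free(ensemble: Ensemble, min_dist: float = 0.2) -> None:
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(ensemble.coords[0]))
    res = ensemble.atoms["res_index"].to_numpy()
    bonded = np.abs(res[:, None] - res[None, :]) <= 1  # same or adjacent residue
    np.fill_diagonal(d, np.inf)
    d[bonded] = np.inf
    if d.min() < min_dist:
        raise InvalidArgumentError(
            f"generated polymer has a clash: min non-bonded distance {d.min():.3f} nm"
        )


def sample_gaussian_ensemble(
    reference: Ensemble,
    spec: CovarianceSpec,
    n_frames: int,
    seed: int,
) -> Ensemble:
    """Sample an ensemble by Gaussian residue displacements around a reference.

    Each frame displaces every residue rigidly (all its atoms together) by a
    3-vector whose per-axis residue-residue correlation matrix is the one
    planted in ``spec``; the three axes are mutually independent.
    """
    if n_frames < 2:
        raise InvalidArgumentError("n_frames must be >= 2")
    if spec.n_residues != reference.n_residues:
        raise InvalidArgumentError(
            f"spec has {spec.n_residues} residues but reference has "
            f"{reference.n_residues}"
        )
    rng = np.random.default_rng(seed)
    corr = spec.correlation_matrix()
    cov = spec.baseline_variance * corr
    chol = np.linalg.cholesky(cov)
    n_res = spec.n_residues
    # (frames, residues, axes): axes independent, same covariance
    z = rng.standard_normal(size=(3, n_frames, n_res))
    disp = np.einsum("afr,sr->afs", z, chol)  # (3, frames, residues)
    disp = np.moveaxis(disp, 0, 2)  # (frames, residues, 3)

    res_of_atom = reference.atoms["res_index"].to_numpy()
    coords = reference.coords[0][None, :, :] + disp[:, res_of_atom, :]
    return Ensemble(
        coords=coords,
        atoms=reference.atoms.copy(),
        frames_per_window=reference.frames_per_window,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        return np.array([0.0, 0.0, 1.0])
    return v / n


def plant_contact_chain(ensemble: Ensemble, chain: PlantedChain) -> Ensemble:
    """Return a new ensemble with a planted persistent contact chain.

    For each consecutive residue pair (a, b) of the chain, ``min_atom_pairs``
    extra pseudo-side-chain atoms are added to residue b.  In contact frames
    they cluster within 0.45 nm of a's side-chain anchor atom; in the
    remaining frames they are parked radially outward beyond b's own side
    chain, more than 0.6 nm from every atom of a.  Pre-existing atoms are
    never moved.
    """
    n_res = ensemble.n_residues
    for r in chain.residues:
        if r < 0 or r >= n_res:
            raise InvalidArgumentError(f"chain residue {r} outside ensemble")
    n_frames = ensemble.n_frames
    n_contact = math.ceil(chain.persistence * n_frames)
    rng = np.random.default_rng(chain.rng_seed)
    contact_frames = np.zeros(n_frames, dtype=bool)
    if n_contact:
        contact_frames[rng.choice(n_frames, size=n_contact, replace=False)] = True

    atoms = ensemble.atoms
    res_of_atom = atoms["res_index"].to_numpy()
    names = atoms["atom_name"].to_numpy()
    is_h = atoms["is_hydrogen"].to_numpy()

    def anchor_index(res: int) -> int:
        idx = np.flatnonzero(res_of_atom == res)
        side = [i for i in idx if names[i] not in ("N", "CA", "C", "O", "OXT") and not is_h[i]]
        if side:
            return side[0]
        ca = [i for i in idx if names[i] == "CA"]
        if not ca:
            raise InvalidArgumentError(f"residue {res} has no anchor atom (no side chain, no CA)")
        return ca[0]

    ca_indices = np.flatnonzero(names == "CA")

    new_rows = []
    new_coords = []  # list of (n_frames, 3) arrays
    for edge_num, (a, b) in enumerate(chain.edges):
        anch_a = anchor_index(a)
        anch_b = anchor_index(b)
        res_name_b = atoms.loc[atoms["res_index"] == b, "res_name"].iloc[0]
        res_id_b = int(atoms.loc[atoms["res_index"] == b, "res_id"].iloc[0])
        for k in range(chain.min_atom_pairs):
            new_rows.append((b, res_id_b, res_name_b, f"X{edge_num % 10}{k}", "C", False))
            pos = np.empty((n_frames, 3))
            new_coords.append(pos)

        base = len(new_coords) - chain.min_atom_pairs
        for f in range(n_frames):
            frame = ensemble.coords[f]
            center = frame[ca_indices].mean(axis=0)
            if contact_frames[f]:
                target = frame[anch_a]
            else:
                target = frame[anch_b]
            d = _unit(target - center)
            # two tangential unit vectors for spreading atoms apart
            t1 = _unit(np.cross(d, [0.0, 0.0, 1.0]))
            if np.linalg.norm(np.cross(d, [0.0, 0.0, 1.0])) < 1e-8:
                t1 = np.array([1.0, 0.0, 0.0])
            t2 = _unit(np.cross(d, t1))
            for k in range(chain.min_atom_pairs):
                angle = 2 * math.pi * k / max(chain.min_atom_pairs, 1)
                # park well beyond the side-chain shell so parked atoms of one
                # chain never fall inside the contact sphere of another
                radial = 0.28 if contact_frames[f] else 0.90
                spread = 0.05 * (math.cos(angle) * t1 + math.sin(angle) * t2)
                new_coords[base + k][f] = target + radial * d + spread

    new_atoms = pd.concat(
        [atoms, pd.DataFrame(new_rows, columns=list(atoms.columns))],
        ignore_index=True,
    )
    coords = np.concatenate(
        [ensemble.coords, np.stack(new_coords, axis=1)], axis=1
    )
    # keep atoms grouped by residue for tidy PDB output
    order = np.argsort(new_atoms["res_index"].to_numpy(), kind="stable")
    new_atoms = new_atoms.iloc[order].reset_index(drop=True)
    coords = coords[:, order, :]
    return Ensemble(
        coords=coords,
        atoms=new_atoms,
        frames_per_window=ensemble.frames_per_window,
    )


def write_ground_truth(
    path,
    spec: CovarianceSpec | None = None,
    chains: list[PlantedChain] | None = None,
) -> None:
    """Record the planted covariance and contact chains as JSON."""
    payload = {
        "covariance_spec": spec.to_dict() if spec is not None else None,
        "planted_chains": [c.to_dict() for c in (chains or [])],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
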
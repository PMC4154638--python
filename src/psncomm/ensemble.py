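"""Conformational-ensemble container, multi-model PDB I/O and atom selections.

An :class:`Ensemble` holds a stack of frames over a fixed atom roster, with
coordinates in nanometres (the contact cutoff of the structure-network stage
is quoted in nm, so nm is the internal unit; PDB I/O converts from/to Å).

Atom selections resolve the two policies consumed downstream:

``side-chain-heavy``
    all non-hydrogen atoms outside the backbone set {N, CA, C, O, OXT};
    glycine, which has no side-chain heavy atom, falls back to its Cα so it
    can still act as a network node.
``calpha``
    exactly one CA atom per residue (the selection entering the
    linear-mutual-information stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import FormatError, InvalidArgumentError, SelectionError

#: Backbone heavy-atom names excluded from side-chain contact counting.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

ATOM_COLUMNS = ("res_index", "res_id", "res_name", "atom_name", "element", "is_hydrogen")


@dataclass
class Ensemble:
    """A conformational ensemble: frames x atoms x 3 coordinates in nm.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)``, float, nanometres.
    atoms
        DataFrame with one row per atom and columns ``res_index`` (0-based
        contiguous internal residue index), ``res_id`` (author numbering kept
        for reporting), ``res_name`` (three-letter code), ``atom_name``,
        ``element`` and ``is_hydrogen``.
    frames_per_window
        How many frames constitute one averaging window.  This stands in for
        a physical window length (e.g. five ns) when frames carry no
        timestep.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    frames_per_window: int = 100

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atoms = self.atoms.reset_index(drop=True)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise InvalidArgumentError(
                f"coords must have shape (frames, atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.atoms):
            raise InvalidArgumentError(
                f"coordinate atom axis ({self.coords.shape[1]}) does not match "
                f"atom table length ({len(self.atoms)})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise InvalidArgumentError("coordinates must be finite")
        idx = self.atoms["res_index"].to_numpy()
        uniq = np.unique(idx)
        if len(uniq) and not np.array_equal(uniq, np.arange(uniq[-1] + 1)):
            raise InvalidArgumentError("residue indices must be 0-based and contiguous")

    # -- basic shape accessors -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return int(self.atoms["res_index"].max()) + 1 if len(self.atoms) else 0

    @property
    def residue_names(self) -> list[str]:
        """Three-letter residue name per internal residue index."""
        first = self.atoms.drop_duplicates("res_index").sort_values("res_index")
        return list(first["res_name"])

    @property
    def residue_ids(self) -> list[int]:
        """Author residue numbering per internal residue index."""
        first = self.atoms.drop_duplicates("res_index").sort_values("res_index")
        return [int(r) for r in first["res_id"]]

    def copy(self) -> "Ensemble":
        return replace(self, coords=self.coords.copy(), atoms=self.atoms.copy())

    def atom_indices_of_residue(self, res_index: int) -> np.ndarray:
        return np.flatnonzero(self.atoms["res_index"].to_numpy() == res_index)


@dataclass
class AtomSelection:
    """A resolved atom-selection policy.

    ``per_residue[i]`` lists the flat atom indices selected for residue ``i``;
    the selection is defined over atom indices, not coordinates, so it is
    stable across frames by construction.
    """

    policy: str
    per_residue: list[np.ndarray]
    atom_residue: np.ndarray = field(init=False)
    flat: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        flat: list[int] = []
        owner: list[int] = []
        for res, idx in enumerate(self.per_residue):
            flat.extend(int(a) for a in idx)
            owner.extend([res] * len(idx))
        self.flat = np.asarray(flat, dtype=np.intp)
        self.atom_residue = np.asarray(owner, dtype=np.intp)

    @property
    def n_residues(self) -> int:
        return len(self.per_residue)


def select_atoms(ensemble: Ensemble, policy: str) -> AtomSelection:
    """Resolve an atom-selection policy on an ensemble.

    Raises
    ------
    SelectionError
        If some residue has no selectable atom under the policy (naming the
        residue), or the policy is unknown.
    """
    if policy not in ("side-chain-heavy", "calpha"):
        raise SelectionError(f"unknown selection policy {policy!r}")
    atoms = ensemble.atoms
    per_residue: list[np.ndarray] = []
    for res in range(ensemble.n_residues):
        sub = atoms[atoms["res_index"] == res]
        if policy == "calpha":
            sel = sub.index[sub["atom_name"] == "CA"]
            if len(sel) != 1:
                raise SelectionError(
                    f"residue {res} ({sub['res_name'].iloc[0]}): expected exactly "
                    f"one CA atom, found {len(sel)}"
                )
        else:
            mask = (~sub["is_hydrogen"]) & (~sub["atom_name"].isin(BACKBONE_ATOMS))
            sel = sub.index[mask]
            if len(sel) == 0:
                # glycine (or any residue with no side-chain heavy atom)
                # falls back to its Cα
                sel = sub.index[sub["atom_name"] == "CA"]
            if len(sel) == 0:
                raise SelectionError(
                    f"residue {res} ({sub['res_name'].iloc[0]}) has no selectable "
                    f"atom under policy {policy!r}"
                )
        per_residue.append(np.asarray(sel, dtype=np.intp))
    return AtomSelection(policy=policy, per_residue=per_residue)


# -- multi-model PDB I/O -------------------------------------------------------

_HYDROGEN_ELEMENTS = {"H", "D"}


def read_ensemble(path, format: str = "pdb", topology=None, frames_per_window: int = 100) -> Ensemble:
    """Read a conformational ensemble from disk.

    ``format="pdb"`` reads a strict multi-model PDB (one MODEL per frame);
    any other format name is treated as a trajectory read through MDAnalysis
    and requires ``topology``.  Coordinates are converted from Å to nm.
    Hydrogens are retained but flagged.  Non-protein chains (e.g. nucleic
    acids, water) are dropped with a warning: network edges are defined
    between protein residues only.
    """
    if format == "pdb":
        return _read_pdb(path, frames_per_window)
    return _read_trajectory(path, topology, frames_per_window)


def _read_pdb(path, frames_per_window: int) -> Ensemble:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise FormatError(f"cannot parse multi-model PDB {path}: {exc}") from exc
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise FormatError(f"{path} contains no frames")
    amino = struc.filter_amino_acids(stack)
    if not np.all(amino):
        import warnings

        warnings.warn(
            f"{path}: ignoring {int((~amino).sum())} non-protein atoms "
            "(nucleic acids/solvent are outside the network definition)",
            stacklevel=3,
        )
        stack = stack[..., amino]
        if stack.array_length() == 0:
            raise FormatError(f"{path} contains no protein atoms")
    res_ids = stack.res_id
    # internal contiguous residue index in order of appearance
    _, res_index = np.unique(res_ids, return_inverse=True)
    order = np.argsort(np.unique(res_ids))
    # np.unique sorts; res_id order in PDB files is non-decreasing in practice,
    # keep the sorted mapping.
    del order
    elements = np.asarray(stack.element)
    atoms = pd.DataFrame(
        {
            "res_index": res_index.astype(int),
            "res_id": res_ids.astype(int),
            "res_name": np.asarray(stack.res_name),
            "atom_name": np.asarray(stack.atom_name),
            "element": elements,
            "is_hydrogen": np.isin(elements, list(_HYDROGEN_ELEMENTS)),
        }
    )
    coords = stack.coord / 10.0  # Å -> nm
    return Ensemble(coords=coords, atoms=atoms, frames_per_window=frames_per_window)


def _read_trajectory(path, topology, frames_per_window: int) -> Ensemble:
    if topology is None:
        raise InvalidArgumentError("trajectory formats require a topology file")
    import MDAnalysis as mda

    try:
        universe = mda.Universe(str(topology), str(path))
    except Exception as exc:
        raise FormatError(f"cannot read trajectory {path}: {exc}") from exc
    protein = universe.select_atoms("protein")
    if protein.n_atoms == 0:
        raise FormatError(f"{path} contains no protein atoms")
    res_index = protein.resindices - protein.resindices.min()
    elements = np.array(
        [getattr(a, "element", a.name[:1]).upper() for a in protein.atoms], dtype=object
    )
    atoms = pd.DataFrame(
        {
            "res_index": res_index.astype(int),
            "res_id": protein.resids.astype(int),
            "res_name": protein.resnames,
            "atom_name": protein.names,
            "element": elements,
            "is_hydrogen": [e in _HYDROGEN_ELEMENTS for e in elements],
        }
    )
    coords = np.stack([protein.positions.copy() for _ in universe.trajectory]) / 10.0
    return Ensemble(coords=coords, atoms=atoms, frames_per_window=frames_per_window)


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble as a strict multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n_atoms = ensemble.n_atoms
    array = struc.AtomArray(n_atoms)
    array.res_id = ensemble.atoms["res_id"].to_numpy().astype(int)
    array.res_name = ensemble.atoms["res_name"].to_numpy().astype("U5")
    array.atom_name = ensemble.atoms["atom_name"].to_numpy().astype("U6")
    array.element = ensemble.atoms["element"].to_numpy().astype("U2")
    array.chain_id = np.full(n_atoms, "A", dtype="U4")
    array.hetero = np.zeros(n_atoms, dtype=bool)
    stack = struc.AtomArrayStack(ensemble.n_frames, n_atoms)
    for key in ("res_id", "res_name", "atom_name", "element", "chain_id", "hetero"):
        stack.set_annotation(key, array.get_annotation(key))
    stack.coord = ensemble.coords * 10.0  # nm -> Å
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))
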
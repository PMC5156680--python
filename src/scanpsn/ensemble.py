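"""Conformational ensembles: multi-model structure I/O and side-chain centers of mass.

An ensemble is an ordered stack of frames (NMR conformers or trajectory
snapshots) sharing one atom/residue composition.  Coordinates are stored in
nanometres internally; PDB Angstrom values are divided by 10 on load, so all
distance cutoffs downstream are expressed in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "ResidueId",
    "MassTable",
    "ConformationalEnsemble",
    "EnsembleLoadError",
    "load_ensemble",
    "write_pdb",
    "load_xyz_table",
    "write_xyz_table",
    "sidechain_com",
    "subsample_frames",
    "subsample_indices",
]

#: Three-letter codes accepted at load time.
STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Backbone heavy atoms excluded from side-chain centers of mass.
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
#: Backbone-attached hydrogens (amide and alpha protons), likewise excluded.
BACKBONE_HYDROGENS = {"H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3", "1H", "2H", "3H"}

#: Standard atomic masses in unified amu.
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}


class EnsembleLoadError(ValueError):
    """Raised for malformed or inconsistent multi-model input."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """Identity of a residue: chain label, author residue number, 3-letter code."""

    chain: str
    resnum: int
    resname: str

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("chain label must be non-empty")
        if self.resnum < 1:
            raise ValueError(f"residue number must be >= 1, got {self.resnum}")

    def __str__(self) -> str:  # e.g. "PRO58:A"
        return f"{self.resname}{self.resnum}:{self.chain}"


class MassTable:
    """Element masses with optional per-atom-name overrides.

    Force fields redefine some atomic masses (e.g. hydrogen-mass
    repartitioning); ``overrides`` maps an atom *name* to the mass to use
    regardless of its element.
    """

    def __init__(self, overrides: dict[str, float] | None = None):
        self.overrides = dict(overrides or {})
        for name, m in self.overrides.items():
            if not m > 0:
                raise ValueError(f"mass override for {name!r} must be > 0, got {m}")

    def mass(self, atom_name: str, element: str) -> float:
        if atom_name in self.overrides:
            return self.overrides[atom_name]
        try:
            return ELEMENT_MASSES[element.upper()]
        except KeyError:
            raise KeyError(f"no mass for element {element!r} (atom {atom_name!r})") from None


def _infer_element(atom_name: str) -> str:
    """Guess the element from a PDB-style atom name (used by the table reader)."""
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped[:2].upper() == "SE":
        return "SE"
    return stripped[0].upper()


@dataclass
class ConformationalEnsemble:
    """Frames of atomic coordinates over a fixed residue/atom composition.

    Attributes
    ----------
    coords : (n_frames, n_atoms, 3) float array, nm.
    residues : ordered residue identities, shared by all frames.
    atom_names, atom_elements : per-atom metadata, length n_atoms.
    atom_residue_index : per-atom index into ``residues``.
    masses : the mass table used for center-of-mass computations.
    """

    coords: np.ndarray
    residues: list[ResidueId]
    atom_names: list[str]
    atom_elements: list[str]
    atom_residue_index: np.ndarray
    masses: MassTable = field(default_factory=MassTable)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_residue_index = np.asarray(self.atom_residue_index, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n_atoms = self.coords.shape[1]
        if not (len(self.atom_names) == len(self.atom_elements) == n_atoms
                == len(self.atom_residue_index)):
            raise ValueError("atom metadata lengths disagree with coordinate array")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residue identities")
        self._residue_lookup = {r: i for i, r in enumerate(self.residues)}
        self._key_lookup = {(r.chain, r.resnum): r for r in self.residues}

    # -- introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue(self, chain: str, resnum: int) -> ResidueId:
        """Look a residue up by chain and author number."""
        try:
            return self._key_lookup[(chain, resnum)]
        except KeyError:
            raise KeyError(f"no residue {resnum} in chain {chain!r}") from None

    def residue_atom_indices(self, residue: ResidueId) -> np.ndarray:
        try:
            ridx = self._residue_lookup[residue]
        except KeyError:
            raise KeyError(f"residue {residue} not in ensemble") from None
        return np.flatnonzero(self.atom_residue_index == ridx)

    def atom_index(self, residue: ResidueId, atom_name: str) -> int:
        for i in self.residue_atom_indices(residue):
            if self.atom_names[i] == atom_name:
                return int(i)
        raise KeyError(f"atom {atom_name!r} not found in residue {residue}")

    def with_frames(self, indices: Sequence[int]) -> "ConformationalEnsemble":
        """A new ensemble restricted to the given frame indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return ConformationalEnsemble(
            coords=self.coords[idx],
            residues=list(self.residues),
            atom_names=list(self.atom_names),
            atom_elements=list(self.atom_elements),
            atom_residue_index=self.atom_residue_index.copy(),
            masses=self.masses,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_ensemble(path: str | Path, masses: MassTable | None = None) -> ConformationalEnsemble:
    """Read a (multi-)model PDB file into a :class:`ConformationalEnsemble`.

    One frame per MODEL record (a file without MODEL records yields a single
    frame).  Every model must contain exactly the same atoms in the same
    order; the first offending model is named in the error.  Residue names
    outside the twenty standard amino acids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise EnsembleLoadError(f"{path}: no models found")

    template: list[tuple[str, int, str, str]] | None = None
    frames: list[np.ndarray] = []
    residues: list[ResidueId] = []
    atom_names: list[str] = []
    atom_elements: list[str] = []
    atom_residue_index: list[int] = []

    for model_number, model in enumerate(structure, start=1):
        sig: list[tuple[str, int, str, str]] = []
        xyz: list[tuple[float, float, float]] = []
        res_seen: dict[ResidueId, int] = {}
        for chain in model:
            for res in chain:
                if res.name not in STANDARD_RESIDUES:
                    raise EnsembleLoadError(
                        f"{path}: unknown residue name {res.name!r} "
                        f"(chain {chain.name}, residue {res.seqid.num})"
                    )
                rid = ResidueId(chain.name, res.seqid.num, res.name)
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    sig.append((chain.name, res.seqid.num, res.name, atom.name))
                    xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    if model_number == 1:
                        if rid not in res_seen:
                            res_seen[rid] = len(residues)
                            residues.append(rid)
                        atom_names.append(atom.name)
                        atom_elements.append(atom.element.name.upper() or _infer_element(atom.name))
                        atom_residue_index.append(res_seen[rid])
        if template is None:
            template = sig
        elif sig != template:
            raise EnsembleLoadError(
                f"{path}: model {model_number} has a different atom composition "
                f"than model 1 ({len(sig)} vs {len(template)} atoms)"
            )
        frames.append(np.asarray(xyz, dtype=float) / 10.0)  # Angstrom -> nm

    return ConformationalEnsemble(
        coords=np.stack(frames),
        residues=residues,
        atom_names=atom_names,
        atom_elements=atom_elements,
        atom_residue_index=np.asarray(atom_residue_index),
        masses=masses or MassTable(),
    )


def write_pdb(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write the ensemble as a multi-model PDB file (nm converted back to A)."""
    lines: list[str] = []
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        serial = 0
        for a in range(ensemble.n_atoms):
            serial += 1
            rid = ensemble.residues[ensemble.atom_residue_index[a]]
            name = ensemble.atom_names[a]
            pdb_name = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = ensemble.coords[f, a] * 10.0
            elem = ensemble.atom_elements[a]
            lines.append(
                f"ATOM  {serial:5d} {pdb_name}{'':1s}{rid.resname:>3s} "
                f"{rid.chain:1s}{rid.resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


_XYZ_COLUMNS = ["frame", "chain", "resnum", "resname", "atom", "x", "y", "z"]


def load_xyz_table(path: str | Path, masses: MassTable | None = None) -> ConformationalEnsemble:
    """Read the plain tabular ensemble format (tab-separated, coordinates in nm).

    Columns: frame, chain, resnum, resname, atom, x, y, z.  This is the
    escape hatch for synthetic or pre-processed data that never lived in a
    PDB file.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "atom": str, "resname": str})
    missing = [c for c in _XYZ_COLUMNS if c not in df.columns]
    if missing:
        raise EnsembleLoadError(f"{path}: missing columns {missing}")
    frames_ids = sorted(df["frame"].unique())
    first = df[df["frame"] == frames_ids[0]].reset_index(drop=True)

    residues: list[ResidueId] = []
    res_seen: dict[ResidueId, int] = {}
    atom_residue_index = []
    for _, row in first.iterrows():
        if row["resname"] not in STANDARD_RESIDUES:
            raise EnsembleLoadError(f"{path}: unknown residue name {row['resname']!r}")
        rid = ResidueId(str(row["chain"]), int(row["resnum"]), str(row["resname"]))
        if rid not in res_seen:
            res_seen[rid] = len(residues)
            residues.append(rid)
        atom_residue_index.append(res_seen[rid])

    sig0 = list(zip(first["chain"], first["resnum"], first["atom"]))
    coords = []
    for fid in frames_ids:
        sub = df[df["frame"] == fid].reset_index(drop=True)
        if list(zip(sub["chain"], sub["resnum"], sub["atom"])) != sig0:
            raise EnsembleLoadError(f"{path}: frame {fid} has a different atom composition")
        coords.append(sub[["x", "y", "z"]].to_numpy(dtype=float))

    return ConformationalEnsemble(
        coords=np.stack(coords),
        residues=residues,
        atom_names=[str(a) for a in first["atom"]],
        atom_elements=[_infer_element(str(a)) for a in first["atom"]],
        atom_residue_index=np.asarray(atom_residue_index),
        masses=masses or MassTable(),
    )


def write_xyz_table(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    rows = []
    for f in range(ensemble.n_frames):
        for a in range(ensemble.n_atoms):
            rid = ensemble.residues[ensemble.atom_residue_index[a]]
            x, y, z = ensemble.coords[f, a]
            rows.append((f, rid.chain, rid.resnum, rid.resname,
                         ensemble.atom_names[a], x, y, z))
    pd.DataFrame(rows, columns=_XYZ_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def sidechain_com(
    ensemble: ConformationalEnsemble,
    residue: ResidueId,
    include_hydrogens: bool = False,
) -> np.ndarray:
    """Mass-weighted side-chain center of mass per frame, shape (n_frames, 3).

    The side chain is every atom except the backbone N, CA, C, O (+OXT) and
    the backbone-attached hydrogens.  Glycine has no side chain and is
    rejected explicitly; heavy atoms only by default.
    """
    if residue.resname == "GLY":
        raise ValueError(f"{residue}: glycine is excluded (no side chain)")
    idx = ensemble.residue_atom_indices(residue)
    side = []
    weights = []
    for i in idx:
        name = ensemble.atom_names[i]
        elem = ensemble.atom_elements[i]
        if name in BACKBONE_ATOMS or name in BACKBONE_HYDROGENS:
            continue
        if elem == "H" and not include_hydrogens:
            continue
        side.append(i)
        weights.append(ensemble.masses.mass(name, elem))
    if not side:
        raise ValueError(f"{residue}: no side-chain atoms found")
    w = np.asarray(weights)
    pts = ensemble.coords[:, side, :]  # (frames, k, 3)
    return (pts * w[None, :, None]).sum(axis=1) / w.sum()


def subsample_indices(n_frames: int, k: int) -> np.ndarray:
    """Equally spaced frame indices including both endpoints.

    ``k = 1`` returns the first frame (endpoint convention);
    index i is round(i*(N-1)/(k-1)) otherwise.
    """
    if not 1 <= k <= n_frames:
        raise ValueError(f"k must be in [1, {n_frames}], got {k}")
    if k == 1:
        return np.array([0])
    return np.array([round(i * (n_frames - 1) / (k - 1)) for i in range(k)], dtype=int)


def subsample_frames(ensemble: ConformationalEnsemble, k: int) -> ConformationalEnsemble:
    """Keep ``k`` equally spaced frames (first and last always included)."""
    return ensemble.with_frames(subsample_indices(ensemble.n_frames, k))
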
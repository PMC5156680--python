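"""Shared fixtures: tiny hand-built ensembles and generated inputs."""

import numpy as np
import pytest

from scanpsn.ensemble import ConformationalEnsemble, MassTable, ResidueId
from scanpsn import synthetic as syn


def build_ensemble(residue_atoms, n_frames=1, jitter=None):
    """Assemble an ensemble from a list of residues.

    ``residue_atoms`` is a list of (chain, resnum, resname, atoms) where
    atoms is a list of (name, element, (x, y, z)) in nm.  All frames are
    identical unless ``jitter`` (an (n_frames, n_atoms, 3) array) is given.
    """
    residues, atom_names, atom_elements, atom_residue_index, xyz = [], [], [], [], []
    for chain, resnum, resname, atoms in residue_atoms:
        rid = ResidueId(chain, resnum, resname)
        residues.append(rid)
        for name, elem, pos in atoms:
            atom_names.append(name)
            atom_elements.append(elem)
            atom_residue_index.append(len(residues) - 1)
            xyz.append(pos)
    coords = np.tile(np.asarray(xyz, dtype=float), (n_frames, 1, 1))
    if jitter is not None:
        coords = coords + jitter
    return ConformationalEnsemble(
        coords=coords,
        residues=residues,
        atom_names=atom_names,
        atom_elements=atom_elements,
        atom_residue_index=np.asarray(atom_residue_index),
        masses=MassTable(),
    )


def point_residue(chain, resnum, pos, resname="ALA"):
    """A minimal residue whose side chain is a single CB atom at ``pos``."""
    return (chain, resnum, resname,
            [("N", "N", (pos[0] - 0.15, pos[1] + 0.1, pos[2])),
             ("CA", "C", (pos[0] - 0.1, pos[1], pos[2])),
             ("C", "C", (pos[0] - 0.15, pos[1] - 0.1, pos[2])),
             ("O", "O", (pos[0] - 0.2, pos[1] - 0.15, pos[2])),
             ("CB", "C", tuple(pos))])


@pytest.fixture
def toy_dimer_ensemble():
    """20-frame, two-chain ensemble with three planted persistences."""
    specs = [
        syn.ContactSpec(("A", 1), ("B", 1), persistence=1.0),
        syn.ContactSpec(("A", 2), ("B", 2), persistence=0.5),
        syn.ContactSpec(("A", 3), ("B", 3), persistence=0.15),
    ]
    return syn.make_dimer_ensemble(20, 5, specs, seed=7), specs
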
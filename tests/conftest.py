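"""Shared fixtures: tiny hand-built structures and trajectories."""

import numpy as np
import pytest

from trajmech.structure_io import AtomRecord, Frame, Trajectory

SINGLE_MODEL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 12.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 11.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00 13.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00 15.00           C
END
"""


def _atom(serial, name, element, res_name, res_seq, chain="A", b=0.0):
    return AtomRecord(serial=serial, name=name, element=element,
                      res_name=res_name, res_seq=res_seq, chain_id=chain,
                      b_factor=b)


@pytest.fixture
def single_model_text(tmp_path):
    p = tmp_path / "single.pdb"
    p.write_text(SINGLE_MODEL_PDB)
    return p


@pytest.fixture
def tiny_topology():
    """Two residues: a donor N and an acceptor O plus carbon padding."""
    return [
        _atom(1, "N", "N", "GLY", 1),
        _atom(2, "CA", "C", "GLY", 1),
        _atom(3, "O", "O", "SER", 2),
        _atom(4, "CA", "C", "SER", 2),
    ]


def make_pair_trajectory(distances, topology):
    """Frames where the residue-1 N and residue-2 O sit at given distances."""
    frames = []
    for t, d in enumerate(distances):
        coords = np.array([
            [0.0, 0.0, 0.0],
            [0.0, 5.0, 0.0],
            [d, 0.0, 0.0],
            [d, -5.0, 0.0],
        ])
        frames.append(Frame(coords, time=float(t)))
    return Trajectory(topology=topology, frames=frames)


@pytest.fixture
def pair_trajectory(tiny_topology):
    """Four frames; the N–O pair is inside the 3.2 Å cutoff in frame 0 only."""
    return make_pair_trajectory([2.9, 4.5, 4.5, 4.5], tiny_topology)
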
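"""Geometric hydrogen-bond detection and trajectory occupancy.

A hydrogen bond is scored on the donor-heavy-atom to acceptor distance with
an inclusive cutoff (default ≤ 3.2 Å).  An optional D–H···A angle filter is
available but disabled by default, matching a distance-only criterion.
Occupancy is the percentage of examined frames in which a pair is bonded,
reported at both atom-pair and residue-pair granularity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import Selection, Trajectory, select

__all__ = [
    "HBondCriterion",
    "HBondEvent",
    "OccupancyTable",
    "assign_roles",
    "detect_frame",
    "occupancy",
    "pair_occupancy",
]

log = logging.getLogger(__name__)

# Donor/acceptor roles for standard protein atoms, keyed (res_name, atom name).
# Backbone N is a donor and backbone O/OXT an acceptor for every residue;
# hydroxyls and His ring nitrogens can play both roles.
_SIDECHAIN_ROLES: dict[tuple[str, str], str] = {
    ("ARG", "NE"): "donor", ("ARG", "NH1"): "donor", ("ARG", "NH2"): "donor",
    ("LYS", "NZ"): "donor",
    ("ASN", "ND2"): "donor", ("ASN", "OD1"): "acceptor",
    ("GLN", "NE2"): "donor", ("GLN", "OE1"): "acceptor",
    ("ASP", "OD1"): "acceptor", ("ASP", "OD2"): "acceptor",
    ("GLU", "OE1"): "acceptor", ("GLU", "OE2"): "acceptor",
    ("SER", "OG"): "both", ("THR", "OG1"): "both", ("TYR", "OH"): "both",
    ("HIS", "ND1"): "both", ("HIS", "NE2"): "both",
    ("TRP", "NE1"): "donor", ("MET", "SD"): "acceptor", ("CYS", "SG"): "both",
}


def assign_roles(traj: Trajectory) -> tuple[list[int], list[int]]:
    """Default donor and acceptor atom indices from residue + atom name.

    Falls back on the element (N → donor, O → acceptor) for atoms outside
    the built-in table; apolar atoms are excluded silently.
    """
    donors, acceptors = [], []
    for i, a in enumerate(traj.topology):
        if a.name == "N":
            donors.append(i)
            continue
        if a.name in ("O", "OXT"):
            acceptors.append(i)
            continue
        role = _SIDECHAIN_ROLES.get((a.res_name, a.name))
        if role is None:
            if a.element == "N":
                role = "donor"
            elif a.element == "O":
                role = "acceptor"
        if role in ("donor", "both"):
            donors.append(i)
        if role in ("acceptor", "both"):
            acceptors.append(i)
    return donors, acceptors


@dataclass(frozen=True)
class HBondCriterion:
    """Distance cutoff (Å, inclusive) with optional D–H···A angle minimum."""

    cutoff: float = 3.2
    angle_min: float | None = None  # degrees; None disables the angle term

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.angle_min is not None and not 0 < self.angle_min <= 180:
            raise ValueError("angle_min must be in (0, 180]")


@dataclass(frozen=True)
class HBondEvent:
    donor: int
    acceptor: int
    distance: float
    frame: int


def _resolve(traj: Trajectory, sel) -> list[int]:
    if sel is None:
        return []
    if isinstance(sel, (Selection, str)):
        return select(traj, sel)
    return list(sel)


def _donor_hydrogens(traj: Trajectory, coords: np.ndarray, donor: int) -> list[int]:
    d = traj.topology[donor]
    out = []
    for j, a in enumerate(traj.topology):
        if a.element == "H" and a.residue_id == d.residue_id:
            if np.linalg.norm(coords[j] - coords[donor]) <= 1.2:
                out.append(j)
    return out


def detect_frame(
    traj: Trajectory,
    frame: int,
    crit: HBondCriterion = HBondCriterion(),
    donors=None,
    acceptors=None,
    *,
    exclude_intra_residue: bool = True,
) -> list[HBondEvent]:
    """All donor→acceptor contacts satisfying the criterion in one frame.

    Exhaustive over the donor × acceptor cross-product; pairs within one
    residue are excluded by default.
    """
    if not -traj.n_frames <= frame < traj.n_frames:
        raise IndexError(f"frame {frame} out of range (n_frames={traj.n_frames})")
    frame = frame % traj.n_frames
    don = _resolve(traj, donors) if donors is not None else assign_roles(traj)[0]
    acc = _resolve(traj, acceptors) if acceptors is not None else assign_roles(traj)[1]
    if not don or not acc:
        return []
    coords = traj.coords(frame)
    dist = cdist(coords[don], coords[acc])
    events = []
    for di, ai in zip(*np.nonzero(dist <= crit.cutoff)):
        d_idx, a_idx = don[di], acc[ai]
        if d_idx == a_idx:
            continue
        ra, rb = traj.topology[d_idx].residue_id, traj.topology[a_idx].residue_id
        if exclude_intra_residue and ra == rb:
            continue
        if crit.angle_min is not None:
            hyds = _donor_hydrogens(traj, coords, d_idx)
            ok = False
            for h in hyds:
                v1 = coords[d_idx] - coords[h]
                v2 = coords[a_idx] - coords[h]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= crit.angle_min:
                    ok = True
                    break
            if not ok:
                continue
        events.append(HBondEvent(d_idx, a_idx, float(dist[di, ai]), frame))
    return events


@dataclass
class OccupancyTable:
    """Percent-of-frames occupancy at atom-pair and residue-pair level.

    Residue-pair occupancy counts frames with at least one bonded atom pair
    between the two residues, so it is ≥ every constituent atom-pair value.
    Residue keys are (chain_id, res_seq); storage is symmetric.
    """

    n_frames: int
    atom_pairs: dict[tuple[int, int], float] = field(default_factory=dict)
    residue_pairs: dict[frozenset, float] = field(default_factory=dict)

    def residue_pair(self, res_a, res_b) -> float:
        key = frozenset((_res_key(res_a), _res_key(res_b)))
        return self.residue_pairs.get(key, 0.0)


def _res_key(res) -> tuple[str, int]:
    """Accept (chain, resseq) tuples or bare residue numbers on chain A."""
    if isinstance(res, tuple):
        return res
    return ("A", int(res))


def occupancy(
    traj: Trajectory,
    crit: HBondCriterion = HBondCriterion(),
    stride: int = 1,
    donors=None,
    acceptors=None,
) -> OccupancyTable:
    """Per-pair H-bond occupancy over the trajectory (every `stride`-th frame)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frames = range(0, traj.n_frames, stride)
    n = len(frames)
    if n == 0:
        raise ValueError("no frames to examine")
    don = _resolve(traj, donors) if donors is not None else assign_roles(traj)[0]
    acc = _resolve(traj, acceptors) if acceptors is not None else assign_roles(traj)[1]

    atom_counts: dict[tuple[int, int], int] = {}
    res_counts: dict[frozenset, int] = {}
    for f in frames:
        seen_res = set()
        for ev in detect_frame(traj, f, crit, don, acc):
            atom_counts[(ev.donor, ev.acceptor)] = (
                atom_counts.get((ev.donor, ev.acceptor), 0) + 1
            )
            rkey = frozenset(
                (traj.topology[ev.donor].residue_id,
                 traj.topology[ev.acceptor].residue_id)
            )
            seen_res.add(rkey)
        for rkey in seen_res:
            res_counts[rkey] = res_counts.get(rkey, 0) + 1

    return OccupancyTable(
        n_frames=n,
        atom_pairs={k: 100.0 * c / n for k, c in atom_counts.items()},
        residue_pairs={k: 100.0 * c / n for k, c in res_counts.items()},
    )


def pair_occupancy(table: OccupancyTable, res_a, res_b) -> float:
    """Residue-pair occupancy in percent; 0 for a pair never bonded."""
    return table.residue_pair(res_a, res_b)
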
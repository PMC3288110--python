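"""Synthetic multi-model trajectories with known ground truth.

Real 50 ns MD trajectories of angiogenin variants are far outside desk
scale, so every analysis stage is exercised instead on generated
trajectories that emulate the three observables the pipeline measures:

* a His114-like HA-CA-CB-CG quad whose dihedral hops between a native
  (−80°) and an altered (−179°) state via a two-state Markov chain,
* labelled donor–acceptor atom pairs that sit at 2.9 Å when hydrogen
  bonded and 4.5 Å when not (Bernoulli per frame at a target occupancy),
* an Arg-Arg-Arg nuclear-localization-signal triplet that is either
  extended (solvent exposed) or radially collapsed behind a shell of
  occluding pseudo-atoms (buried).

Everything is deterministic given the seed, and the realized per-frame
states are returned as a SyntheticTruth for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .structure_io import AtomRecord, Frame, Trajectory

__all__ = [
    "ScenarioSpec",
    "SyntheticTruth",
    "generate",
    "scenario_defaults",
    "SCENARIOS",
]

NATIVE_CENTER = -80.0
ALTERED_CENTER = -179.0

BONDED_DISTANCE = 2.9   # inside the 3.2 A cutoff with noise margin
UNBONDED_DISTANCE = 4.5  # safely outside

_RES_NAMES = {
    12: "GLN", 13: "HIS", 15: "ASP", 17: "LYS", 26: "THR", 28: "SER",
    31: "ARG", 32: "ARG", 33: "ARG", 35: "LEU", 40: "LYS", 44: "THR",
    46: "ILE", 60: "LYS", 80: "THR", 106: "ALA", 112: "PRO", 113: "VAL",
    114: "HIS", 115: "LEU", 116: "ASP", 117: "GLN", 118: "SER",
}
_MUTANT_RES = {
    "K17I": (17, "ILE"), "S28N": (28, "ASN"), "L35P": (35, "PRO"),
    "K60E": (60, "GLU"), "P112L": (112, "LEU"), "V113I": (113, "ILE"),
}

_NLS_RESIDUES = (31, 32, 33)
_NLS_CENTER = np.array([0.0, -200.0, 0.0])
_SHELL_RES_SEQ = 500
_SHELL_N = 128
_SHELL_RADIUS_CLOSED = 5.0
_SHELL_RADIUS_OPEN = 60.0
_NLS_CONTRACTION = 0.18


@dataclass
class ScenarioSpec:
    """Full parameterization of one synthetic variant trajectory."""

    scenario: str = "custom"
    n_frames: int = 2000
    frame_dt: float = 25.0  # ps; 2000 frames x 25 ps spans the 50 ns study window
    seed: int = 0
    dihedral_altered_fraction: float = 0.0
    dihedral_noise_sd: float = 10.0
    dihedral_mean_dwell: float = 50.0  # frames; Markov dwell so switches come in segments
    hbond_occupancies: dict[tuple[int, int], float] = field(default_factory=dict)
    nls_state: str = "open"  # open | closed | transition
    nls_transition_frame: int = 0
    mutation_site: int | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 <= self.dihedral_altered_fraction <= 1.0:
            raise ValueError("dihedral_altered_fraction must be in [0, 1]")
        for pair, frac in self.hbond_occupancies.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"occupancy for pair {pair} must be in [0, 1]")
        if self.nls_state not in ("open", "closed", "transition"):
            raise ValueError("nls_state must be open, closed or transition")
        if self.nls_state == "transition" and not (
            0 <= self.nls_transition_frame < self.n_frames
        ):
            raise ValueError("nls_transition_frame must lie inside [0, n_frames)")
        if self.frame_dt <= 0:
            raise ValueError("frame_dt must be positive")


@dataclass
class SyntheticTruth:
    """Realized per-frame states, recomputable from the seed."""

    bond_indicator: dict[tuple[int, int], np.ndarray]  # pair -> bool per frame
    dihedral_state: np.ndarray  # 0 = native, 1 = altered
    dihedral_angle: np.ndarray  # noiseless state centers are recoverable from this
    nls_closed: np.ndarray  # bool per frame

    @property
    def altered_fraction(self) -> float:
        return float(np.mean(self.dihedral_state))

    def bond_fraction(self, pair: tuple[int, int]) -> float:
        return float(np.mean(self.bond_indicator[pair]))

    def to_json(self) -> str:
        obj = {
            "bond_indicator": {
                f"{a}-{b}": arr.astype(int).tolist()
                for (a, b), arr in self.bond_indicator.items()
            },
            "dihedral_state": self.dihedral_state.astype(int).tolist(),
            "dihedral_angle": np.round(self.dihedral_angle, 4).tolist(),
            "nls_closed": self.nls_closed.astype(int).tolist(),
        }
        return json.dumps(obj, indent=1)


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def place_fourth_atom(p1, p2, p3, bond_length: float, bond_angle_deg: float,
                      dihedral_deg: float) -> np.ndarray:
    """Position of atom 4 given three anchors, internal coordinates and the
    desired 1-2-3-4 dihedral (NeRF construction)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    n = np.cross(p2 - p1, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    theta = np.radians(bond_angle_deg)
    chi = np.radians(dihedral_deg)
    d = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit directions (golden-section spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _markov_states(rng: np.random.Generator, n: int, frac: float,
                   mean_dwell: float) -> np.ndarray:
    """Two-state chain with stationary altered fraction `frac` and mean
    altered dwell ~= mean_dwell frames."""
    if frac <= 0.0:
        return np.zeros(n, dtype=int)
    if frac >= 1.0:
        return np.ones(n, dtype=int)
    p_an = min(1.0, 1.0 / mean_dwell)            # altered -> native
    p_na = min(1.0, p_an * frac / (1.0 - frac))  # native -> altered
    states = np.empty(n, dtype=int)
    states[0] = 1 if rng.random() < frac else 0
    u = rng.random(n - 1)
    for t in range(1, n):
        if states[t - 1] == 1:
            states[t] = 0 if u[t - 1] < p_an else 1
        else:
            states[t] = 1 if u[t - 1] < p_na else 0
    return states


def _wrap_deg(a):
    """Wrap to (−180, 180]."""
    w = (np.asarray(a) + 180.0) % 360.0 - 180.0
    return np.where(np.isclose(w, -180.0), 180.0, w)


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------

def _res_name(seq: int, scenario: str) -> str:
    site = _MUTANT_RES.get(scenario)
    if site and site[0] == seq:
        return site[1]
    return _RES_NAMES.get(seq, "GLY")


def generate(spec: ScenarioSpec) -> tuple[Trajectory, SyntheticTruth]:
    """Build a synthetic trajectory plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    pairs = list(spec.hbond_occupancies.items())

    # ---- assemble atoms grouped by residue ------------------------------
    # dict: res_seq -> list of (name, element, base position)
    residues: dict[int, list[tuple[str, str, np.ndarray]]] = {}

    def add(seq: int, name: str, element: str, pos) -> None:
        residues.setdefault(seq, []).append((name, element, np.asarray(pos, float)))

    # dihedral quad at residue 114, near the origin
    ha = np.array([-0.363, 1.028, 0.0])
    ca = np.array([0.0, 0.0, 0.0])
    cb = np.array([1.54, 0.0, 0.0])
    add(114, "HA", "H", ha)
    add(114, "CA", "C", ca)
    add(114, "CB", "C", cb)
    add(114, "CG", "C", place_fourth_atom(ha, ca, cb, 1.52, 109.47, NATIVE_CENTER))

    # one isolated donor/acceptor site per labelled pair, on a wide grid
    for k, ((don_res, acc_res), _) in enumerate(pairs):
        site = np.array([20.0 * k, 200.0, 0.0])
        add(don_res, f"N{k}", "N", site)
        add(acc_res, f"O{k}", "O", site + np.array([UNBONDED_DISTANCE, 0.0, 0.0]))

    # NLS triplet: CA anchor + 7 side-chain atoms extending radially
    side_names = ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"]
    side_elems = ["C", "C", "C", "N", "C", "N", "N"]
    for r, seq in enumerate(_NLS_RESIDUES):
        ang = np.radians(120.0 * r)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        add(seq, "CA", "C", _NLS_CENTER + 3.0 * u)
        for j, (nm, el) in enumerate(zip(side_names, side_elems), start=1):
            add(seq, nm, el, _NLS_CENTER + (3.0 + 1.8 * j) * u)

    # occluding shell (parked far away while the NLS is open)
    shell_dirs = _fibonacci_sphere(_SHELL_N)
    for i, u in enumerate(shell_dirs):
        add(_SHELL_RES_SEQ, f"C{i}", "C", _NLS_CENTER + _SHELL_RADIUS_OPEN * u)

    topology: list[AtomRecord] = []
    base: list[np.ndarray] = []
    index: dict[tuple[int, str], int] = {}
    serial = 1
    for seq in sorted(residues):
        for name, element, pos in residues[seq]:
            index[(seq, name)] = len(topology)
            topology.append(
                AtomRecord(serial=serial, name=name, element=element,
                           res_name=_res_name(seq, spec.scenario),
                           res_seq=seq, chain_id="A")
            )
            base.append(pos)
            serial += 1
    base_arr = np.array(base)

    # ---- per-frame state draws ------------------------------------------
    n = spec.n_frames
    dstate = _markov_states(rng, n, spec.dihedral_altered_fraction,
                            spec.dihedral_mean_dwell)
    centers = np.where(dstate == 1, ALTERED_CENTER, NATIVE_CENTER)
    noise = rng.normal(0.0, spec.dihedral_noise_sd, n) if spec.dihedral_noise_sd > 0 else 0.0
    angles = _wrap_deg(centers + noise)

    bond_ind: dict[tuple[int, int], np.ndarray] = {}
    for (pair, frac) in pairs:
        bond_ind[pair] = rng.random(n) < frac

    if spec.nls_state == "open":
        nls_closed = np.zeros(n, dtype=bool)
    elif spec.nls_state == "closed":
        nls_closed = np.ones(n, dtype=bool)
    else:
        nls_closed = np.arange(n) >= spec.nls_transition_frame

    # ---- realize frames --------------------------------------------------
    cg_idx = index[(114, "CG")]
    nls_idx = [index[(seq, nm)] for seq in _NLS_RESIDUES
               for nm in ["CA"] + side_names]
    shell_idx = [index[(_SHELL_RES_SEQ, f"C{i}")] for i in range(_SHELL_N)]
    shell_closed = _NLS_CENTER + _SHELL_RADIUS_CLOSED * shell_dirs
    nls_contracted = _NLS_CENTER + _NLS_CONTRACTION * (base_arr[nls_idx] - _NLS_CENTER)

    frames = []
    for t in range(n):
        coords = base_arr.copy()
        coords[cg_idx] = place_fourth_atom(ha, ca, cb, 1.52, 109.47, angles[t])
        for k, (pair, _) in enumerate(pairs):
            d = BONDED_DISTANCE if bond_ind[pair][t] else UNBONDED_DISTANCE
            coords[index[(pair[1], f"O{k}")]] = base_arr[index[(pair[0], f"N{k}")]] \
                + np.array([d, 0.0, 0.0])
        if nls_closed[t]:
            coords[nls_idx] = nls_contracted
            coords[shell_idx] = shell_closed
        frames.append(Frame(coords, time=t * spec.frame_dt))

    traj = Trajectory(topology=topology, frames=frames)
    truth = SyntheticTruth(bond_indicator=bond_ind, dihedral_state=dstate,
                           dihedral_angle=angles, nls_closed=nls_closed)
    return traj, truth


# --------------------------------------------------------------------------
# named scenarios
# --------------------------------------------------------------------------

def _table1(variant: str) -> dict[tuple[int, int], float]:
    from .reference import path_occupancies

    return {pair: pct / 100.0 for pair, pct in path_occupancies(variant).items()}


def _special(variant: str) -> dict[tuple[int, int], float]:
    from .reference import special_pair_occupancies

    t44_t80, d116_s118 = special_pair_occupancies(variant)
    return {(44, 80): t44_t80 / 100.0, (116, 118): d116_s118 / 100.0}


def _scenario_table(n_frames: int) -> dict[str, dict]:
    """Qualitative per-variant behaviours: altered-state fraction of the
    His114 dihedral and open/closed NLS packing.  The fractions are
    qualitative stand-ins for the published time traces (the source reports
    them only graphically), not fitted values."""
    late = max(1, n_frames // 5)   # NLS collapse within the first 10 of 50 ns
    early = max(1, n_frames // 25)  # within the first 2 ns (V113I)
    wt_ext = {(114, 106): 0.2733, (106, 113): 0.4310}
    return {
        "WT": dict(altered=0.0, nls=("open", 0), site=17,
                   hb={**_table1("WT"), **_special("WT")}),
        "K17I": dict(altered=0.8, nls=("open", 0), site=17,
                     hb={**_table1("K17I"), **_special("K17I")}),
        "S28N": dict(altered=0.5, nls=("transition", late), site=28,
                     hb={(28, 46): 0.25, (46, 13): 0.35, (13, 115): 0.20,
                         (115, 117): 0.30, (117, 116): 0.18, (116, 114): 0.08,
                         **wt_ext, **_special("S28N")}),
        "P112L": dict(altered=0.2, nls=("transition", late), site=112,
                      hb={(112, 113): 0.30, **wt_ext, **_special("P112L")}),
        "L35P": dict(altered=0.4, nls=("transition", late), site=35,
                     hb={**_table1("L35P-Leu115"), **_table1("L35P-Thr44"),
                         **_special("L35P")}),
        "K60E": dict(altered=0.0, nls=("open", 0), site=60,
                     hb={(60, 40): 0.30, (40, 12): 0.14, (12, 13): 0.10,
                         (13, 44): 0.22, (44, 117): 0.25, (117, 116): 0.16,
                         (116, 114): 0.03, **wt_ext, **_special("K60E")}),
        "V113I": dict(altered=0.0, nls=("transition", early), site=113,
                      hb={(112, 113): 0.30, **wt_ext, **_special("V113I")}),
    }


SCENARIOS = ("WT", "K17I", "S28N", "P112L", "L35P", "K60E", "V113I")


def scenario_defaults(name: str, *, n_frames: int = 2000, frame_dt: float = 25.0,
                      seed: int = 0) -> ScenarioSpec:
    """Documented default ScenarioSpec for a named variant.

    Raises a ValueError listing the valid names for an unknown scenario.
    """
    table = _scenario_table(n_frames)
    if name not in table:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {', '.join(SCENARIOS)}"
        )
    row = table[name]
    nls_state, trans = row["nls"]
    return ScenarioSpec(
        scenario=name,
        n_frames=n_frames,
        frame_dt=frame_dt,
        seed=seed,
        dihedral_altered_fraction=row["altered"],
        hbond_occupancies=row["hb"],
        nls_state=nls_state,
        nls_transition_frame=trans,
        mutation_site=row["site"],
    )
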
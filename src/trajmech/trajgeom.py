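"""Trajectory geometry: superposition, fluctuations, dihedral states, SASA
and NLS enclosing-sphere volume.

The observables here are the mechanistic readouts for angiogenin variants:
the His114 HA-CA-CB-CG dihedral assigned to a native (−80°) or altered
(−179°) state, the Shrake–Rupley solvent-accessible surface area of the
³¹RRR³³ nuclear localization signal with a 1.4 Å probe, and the volume of
the sphere whose diameter is the widest atom–atom distance across the NLS
triplet (a packing proxy: open ≫ closed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist, pdist

from .structure_io import Frame, Selection, Trajectory, select

__all__ = [
    "DihedralStateModel",
    "DihedralStateSeries",
    "SasaParams",
    "SasaSeries",
    "SphereVolumeSeries",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "bfactor_to_rmsf",
    "rmsf_to_bfactor",
    "dihedral",
    "dihedral_series",
    "assign_states",
    "sasa_frame",
    "sasa_series",
    "enclosing_sphere_volume",
    "sphere_volume_series",
    "BONDI_RADII",
]

log = logging.getLogger(__name__)

# Bondi van der Waals radii (Å) for common protein elements.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


def _resolve(traj: Trajectory, sel) -> list[int]:
    if sel is None:
        return list(range(traj.n_atoms))
    if isinstance(sel, (Selection, str)):
        return select(traj, sel)
    return list(sel)


# --------------------------------------------------------------------------
# superposition / fluctuations
# --------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rigid superposition of `mobile` onto `reference`.

    Returns (rotation, translation, rmsd) with a proper rotation
    (det = +1); apply as ``coords @ rotation.T + translation``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have identical shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) geometry")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return rot, trans, rmsd


def rmsd_series(traj: Trajectory, reference: Frame | np.ndarray, subset=None) -> np.ndarray:
    """Per-frame RMSD (Å) to the reference after Kabsch fit on the subset."""
    idx = _resolve(traj, subset)
    ref = reference.coords if isinstance(reference, Frame) else np.asarray(reference)
    ref = ref[idx]
    return np.array(
        [kabsch_superpose(fr.coords[idx], ref)[2] for fr in traj.frames]
    )


def rmsf(traj: Trajectory, subset=None, *, fit: bool = True):
    """Per-atom RMSF (Å) about the time-average position, plus a per-residue
    mean aggregation.

    With ``fit=True`` every frame is first superposed onto frame 0 on the
    subset, removing rigid-body drift.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _resolve(traj, subset)
    ref = traj.frames[0].coords[idx]
    stack = np.empty((traj.n_frames, len(idx), 3))
    for t, fr in enumerate(traj.frames):
        x = fr.coords[idx]
        if fit:
            rot, trans, _ = kabsch_superpose(x, ref)
            x = x @ rot.T + trans
        stack[t] = x
    mean = stack.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((stack - mean) ** 2, axis=2), axis=0))
    per_residue: dict[tuple[str, int], float] = {}
    groups: dict[tuple[str, int], list[float]] = {}
    for i, v in zip(idx, per_atom):
        groups.setdefault(traj.topology[i].residue_id, []).append(v)
    for rid, vals in groups.items():
        per_residue[rid] = float(np.mean(vals))
    return per_atom, per_residue


def bfactor_to_rmsf(b) -> np.ndarray | float:
    """Crystallographic B-factor (Å²) to RMSF (Å): RMSF = sqrt(3B/(8π²))."""
    b = np.asarray(b, float)
    if np.any(b < 0):
        raise ValueError("B-factor must be non-negative")
    out = np.sqrt(3.0 * b / (8.0 * np.pi**2))
    return float(out) if out.ndim == 0 else out


def rmsf_to_bfactor(r) -> np.ndarray | float:
    """Inverse of :func:`bfactor_to_rmsf`: B = (8π²/3)·RMSF²."""
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ValueError("RMSF must be non-negative")
    out = 8.0 * np.pi**2 / 3.0 * r**2
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# dihedrals and two-state assignment
# --------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle 1-2-3-4 in degrees, IUPAC sign, range (−180, 180]."""
    p = [np.asarray(x, float) for x in (p1, p2, p3, p4)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    for a, b in ((p[0], p[1]), (p[1], p[2]), (p[2], p[3])):
        if np.allclose(a, b):
            raise ValueError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("collinear triple; dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = -float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))
    return 180.0 if np.isclose(ang, -180.0) else ang


def dihedral_series(traj: Trajectory, quad) -> np.ndarray:
    """Per-frame dihedral (degrees) over four atom indices."""
    i, j, k, l = quad
    return np.array(
        [dihedral(fr.coords[i], fr.coords[j], fr.coords[k], fr.coords[l])
         for fr in traj.frames]
    )


@dataclass(frozen=True)
class DihedralStateModel:
    """Two-state model: native −80°, altered −179°, assignment tolerance 45°.

    The centers are 99° apart, so a 45° tolerance leaves the windows
    disjoint; an overlapping configuration is accepted but logged.
    """

    native_center: float = -80.0
    altered_center: float = -179.0
    tolerance: float = 45.0

    def __post_init__(self) -> None:
        for c in (self.native_center, self.altered_center):
            if not -180.0 < c <= 180.0:
                raise ValueError("state centers must lie in (−180, 180]")
        if not 0.0 < self.tolerance < 90.0:
            raise ValueError("tolerance must be in (0, 90)")
        if circular_distance(self.native_center, self.altered_center) <= 2 * self.tolerance:
            log.warning("dihedral state windows overlap; ambiguous angles go native")

    @property
    def separation(self) -> float:
        """Circular distance between the two state centers (degrees)."""
        return circular_distance(self.native_center, self.altered_center)


def circular_distance(a, b) -> np.ndarray | float:
    """Shortest angular distance in degrees, in [0, 180]."""
    d = np.abs((np.asarray(a, float) - np.asarray(b, float) + 180.0) % 360.0 - 180.0)
    return float(d) if d.ndim == 0 else d


@dataclass
class DihedralStateSeries:
    angles: np.ndarray
    labels: np.ndarray  # 'native' | 'altered' | 'unassigned'
    model: DihedralStateModel = field(default_factory=DihedralStateModel)

    @property
    def altered_fraction(self) -> float:
        assigned = self.labels != "unassigned"
        if not assigned.any():
            return float("nan")
        return float(np.sum(self.labels == "altered") / np.sum(assigned))

    @property
    def switch_events(self) -> list[int]:
        """Frame indices where the assigned label flips native↔altered."""
        out = []
        prev = None
        for i, lab in enumerate(self.labels):
            if lab == "unassigned":
                continue
            if prev is not None and lab != prev:
                out.append(i)
            prev = lab
        return out


def assign_states(angles, model: DihedralStateModel = DihedralStateModel()) -> DihedralStateSeries:
    """Label each frame native/altered by circular proximity to the state
    centers (nearest center within tolerance wins; exact ties go native)."""
    angles = np.asarray(angles, float)
    dn = circular_distance(angles, model.native_center)
    da = circular_distance(angles, model.altered_center)
    labels = np.full(angles.shape, "unassigned", dtype=object)
    native_ok = dn <= model.tolerance
    altered_ok = da <= model.tolerance
    labels[native_ok & (dn <= da)] = "native"
    labels[altered_ok & (da < dn)] = "altered"
    labels[native_ok & ~(dn <= da) & ~altered_ok] = "native"
    if np.any(native_ok & altered_ok & (dn == da)):
        log.info("equidistant angles assigned to the native state")
    return DihedralStateSeries(angles=angles, labels=labels.astype(str), model=model)


# --------------------------------------------------------------------------
# solvent-accessible surface area (Shrake–Rupley)
# --------------------------------------------------------------------------

def _golden_spiral(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass(frozen=True)
class SasaParams:
    """Numerical SASA parameters: 1.4 Å water probe, deterministic
    golden-spiral quadrature (no RNG, bit-reproducible), Bondi radii."""

    probe_radius: float = 1.4
    n_sphere_points: int = 960
    radii: dict = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")
        if self.n_sphere_points < 16:
            raise ValueError("need at least 16 sphere points")

    def radius_of(self, element: str) -> float:
        r = self.radii.get(element.upper())
        if r is None:
            log.warning("no van der Waals radius for element %r; using %.2f",
                        element, DEFAULT_RADIUS)
            r = DEFAULT_RADIUS
        return r


def sasa_frame(
    traj: Trajectory,
    frame: int,
    params: SasaParams = SasaParams(),
    subset=None,
):
    """Shrake–Rupley SASA (Å²) for the subset atoms of one frame.

    For each atom, test points are spread quasi-uniformly on its expanded
    sphere (vdW + probe); the accessible fraction — points not inside any
    other atom's expanded sphere — scales the sphere area.  Occluders are
    *all* atoms of the frame, not just the subset.

    Returns (per_atom, per_residue): a {atom_index: Å²} dict and a
    {residue_id: Å²} dict.
    """
    idx = _resolve(traj, subset)
    coords = traj.coords(frame)
    radii = np.array([params.radius_of(a.element) for a in traj.topology])
    expanded = radii + params.probe_radius
    unit = _golden_spiral(params.n_sphere_points)
    tree = cKDTree(coords)
    max_r = expanded.max()

    per_atom: dict[int, float] = {}
    for i in idx:
        pts = coords[i] + expanded[i] * unit
        neigh = np.array(
            [j for j in tree.query_ball_point(coords[i], expanded[i] + max_r)
             if j != i],
            dtype=int,
        )
        alive = np.ones(len(pts), dtype=bool)
        if len(neigh):
            # nearest occluders first so full burial short-circuits early
            order = np.argsort(np.linalg.norm(coords[neigh] - coords[i], axis=1))
            neigh = neigh[order]
            for k in range(0, len(neigh), 16):
                chunk = neigh[k:k + 16]
                d2 = cdist(pts[alive], coords[chunk], "sqeuclidean")
                buried = np.any(d2 < expanded[chunk] ** 2, axis=1)
                alive[np.nonzero(alive)[0][buried]] = False
                if not alive.any():
                    break
        per_atom[i] = float(alive.mean() * 4.0 * np.pi * expanded[i] ** 2)

    per_residue: dict[tuple[str, int], float] = {}
    for i, v in per_atom.items():
        rid = traj.topology[i].residue_id
        per_residue[rid] = per_residue.get(rid, 0.0) + v
    return per_atom, per_residue


@dataclass
class SasaSeries:
    """Per-residue SASA over time with windowed means.

    `values` has shape (n_frames, n_residues) for `residues`; `windows`
    lists (t_start_ns, t_end_ns) intervals and `window_means` the matching
    per-residue means.  The final window is the classification quantity.
    """

    times_ps: np.ndarray
    residues: list
    values: np.ndarray
    windows: list
    window_means: np.ndarray

    @property
    def final_window_per_residue(self) -> np.ndarray:
        return self.window_means[-1]

    @property
    def final_window_total(self) -> float:
        return float(np.sum(self.window_means[-1]))

    def totals(self) -> np.ndarray:
        return self.values.sum(axis=1)


def sasa_series(
    traj: Trajectory,
    params: SasaParams = SasaParams(),
    subset="resid 31-33",
    window_ns: float = 10.0,
    stride: int = 1,
) -> SasaSeries:
    """Per-frame, per-residue SASA of the subset plus `window_ns` means.

    A window longer than the trajectory degrades to a single window (with a
    warning).  `stride` subsamples frames for the expensive quadrature.
    """
    idx = _resolve(traj, subset)
    if not idx:
        raise ValueError("empty SASA selection")
    residues = sorted({traj.topology[i].residue_id for i in idx})
    frames = list(range(0, traj.n_frames, stride))
    times = traj.times[frames]
    values = np.zeros((len(frames), len(residues)))
    for row, f in enumerate(frames):
        _, per_res = sasa_frame(traj, f, params, idx)
        values[row] = [per_res.get(r, 0.0) for r in residues]

    dt = times[1] - times[0] if len(times) > 1 else window_ns * 1000.0
    duration = times[-1] - times[0] + dt
    win_ps = window_ns * 1000.0
    if win_ps >= duration:
        if win_ps > duration:
            log.warning("window (%.1f ns) exceeds trajectory span; using one window",
                        window_ns)
        n_win = 1
    else:
        n_win = int(np.ceil((duration - 1e-9) / win_ps))
    # half-open windows [t0 + k*win, t0 + (k+1)*win); last window absorbs the tail
    which = np.minimum(((times - times[0]) // win_ps).astype(int), n_win - 1)
    windows = []
    means = []
    for k in range(n_win):
        mask = which == k
        if not mask.any():
            continue
        windows.append(
            ((times[0] + k * win_ps) / 1000.0, (times[0] + (k + 1) * win_ps) / 1000.0)
        )
        means.append(values[mask].mean(axis=0))
    return SasaSeries(times_ps=times, residues=residues, values=values,
                      windows=windows, window_means=np.array(means))


# --------------------------------------------------------------------------
# enclosing sphere
# --------------------------------------------------------------------------

def _circumsphere(points: np.ndarray):
    """Smallest sphere through ≤ 4 boundary points."""
    n = len(points)
    if n == 0:
        return np.zeros(3), 0.0
    if n == 1:
        return points[0], 0.0
    if n == 2:
        return (points[0] + points[1]) / 2, np.linalg.norm(points[1] - points[0]) / 2
    # solve |x - p_i|^2 = |x - p_0|^2 for the center in the affine hull
    a = 2.0 * (points[1:] - points[0])
    b = np.sum(points[1:] ** 2 - points[0] ** 2, axis=1)
    center, *_ = np.linalg.lstsq(a, b, rcond=None)
    return center, float(np.linalg.norm(points[0] - center))


def _welzl(points: np.ndarray):
    """Exact minimal enclosing sphere (move-to-front Welzl)."""
    pts = [np.asarray(p, float) for p in points]

    def mb(interior, boundary):
        if not interior or len(boundary) == 4:
            return _circumsphere(np.array(boundary) if boundary else np.empty((0, 3)))
        p = interior[0]
        c, r = mb(interior[1:], boundary)
        if np.linalg.norm(p - c) <= r + 1e-9:
            return c, r
        return mb(interior[1:], boundary + [p])

    return mb(pts, [])


def enclosing_sphere_volume(
    traj_or_frame,
    frame: int | None = None,
    subset=None,
    mode: str = "diameter",
) -> float:
    """Volume (Å³) of the sphere enclosing the subset atom centers.

    ``diameter`` mode takes the diameter as the maximum pairwise distance
    (the packing proxy used for the NLS triplet); ``welzl`` computes the
    exact minimal enclosing sphere as a cross-check — its radius can exceed
    half the max pairwise distance by up to a factor sqrt(3/2) in 3D.
    """
    if isinstance(traj_or_frame, Trajectory):
        idx = _resolve(traj_or_frame, subset)
        pts = traj_or_frame.coords(0 if frame is None else frame)[idx]
    else:
        pts = np.asarray(traj_or_frame, float)
        if subset is not None:
            pts = pts[list(subset)]
    if len(pts) < 2:
        raise ValueError("need at least 2 atoms for an enclosing sphere")
    if mode == "diameter":
        radius = float(pdist(pts).max()) / 2.0
    elif mode == "welzl":
        _, radius = _welzl(pts)
    else:
        raise ValueError("mode must be 'diameter' or 'welzl'")
    return 4.0 / 3.0 * np.pi * radius**3


@dataclass
class SphereVolumeSeries:
    times_ps: np.ndarray
    volumes: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.volumes))


def sphere_volume_series(
    traj: Trajectory, subset="resid 31-33", mode: str = "diameter",
    stride: int = 1,
) -> SphereVolumeSeries:
    """Per-frame enclosing-sphere volume for the subset, plus its mean."""
    idx = _resolve(traj, subset)
    frames = list(range(0, traj.n_frames, stride))
    vols = np.array(
        [enclosing_sphere_volume(traj, f, idx, mode) for f in frames]
    )
    return SphereVolumeSeries(times_ps=traj.times[frames], volumes=vols)
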
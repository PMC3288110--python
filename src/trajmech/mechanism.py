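"""Loss-of-function verdicts from trajectory evidence.

Two independent activities are judged per variant:

* **ribonucleolytic** — read from the fraction of frames the His114
  HA-CA-CB-CG dihedral spends in the altered (−179°) state: ``lost`` at
  ≥ 0.5, ``partial`` in [0.1, 0.5), else ``retained``.  The cutpoints are a
  package convention chosen to mirror the published severe/mild/
  insignificant ordering; the underlying studies rank variants only by how
  often the dihedral leaves its native state.
* **nuclear translocation** — read from the final-window (last 10 ns) total
  SASA of the ³¹RRR³³ triplet: ``lost`` at ≤ 15 Å², ``retained`` at
  ≥ 385 Å², else ``indeterminate``.  The NLS enclosing-sphere volume is
  recorded as corroborating evidence only: the published volume bound
  (804 Å³) is contradicted by one of its own tabulated variants
  (V113I, 804.55 Å³), so SASA decides.

``run_pipeline`` orchestrates the full analysis — H-bond occupancy, the
shortest mutation-site→His114 path and its occupancy sum, the dihedral
state series, NLS SASA and sphere volume — into one MechanismReport.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import hbnetwork, trajgeom
from .hbond import HBondCriterion, occupancy, pair_occupancy
from .structure_io import Trajectory
from .trajgeom import (
    DihedralStateModel,
    DihedralStateSeries,
    SasaParams,
    SasaSeries,
    SphereVolumeSeries,
)

__all__ = [
    "Thresholds",
    "AnalysisConfig",
    "MechanismReport",
    "classify_ribonucleolytic",
    "classify_translocation",
    "separation_metrics",
    "run_pipeline",
]


@dataclass(frozen=True)
class Thresholds:
    """Decision bounds for the two activities (Å², Å³, state fractions)."""

    sasa_lost_max: float = 15.0
    sasa_retained_min: float = 385.0
    volume_lost_max: float = 804.0
    volume_retained_min: float = 2502.0
    altered_fraction_lost_min: float = 0.5
    altered_fraction_partial_min: float = 0.1

    def __post_init__(self) -> None:
        if self.sasa_lost_max >= self.sasa_retained_min:
            raise ValueError("sasa_lost_max must be below sasa_retained_min")
        if self.volume_lost_max >= self.volume_retained_min:
            raise ValueError("volume_lost_max must be below volume_retained_min")
        if not 0 <= self.altered_fraction_partial_min < self.altered_fraction_lost_min <= 1:
            raise ValueError("need 0 <= partial_min < lost_min <= 1")


def classify_ribonucleolytic(series: DihedralStateSeries, th: Thresholds = Thresholds()) -> str:
    """Verdict on ribonucleolytic activity from the altered-state fraction."""
    f = series.altered_fraction
    if np.isnan(f):
        return "indeterminate"
    if f >= th.altered_fraction_lost_min:
        return "lost"
    if f >= th.altered_fraction_partial_min:
        return "partial"
    return "retained"


def classify_translocation(
    sasa: SasaSeries | float,
    vol: SphereVolumeSeries | float | None = None,
    th: Thresholds = Thresholds(),
) -> str:
    """Verdict on nuclear translocation from the final-window NLS SASA total.

    Accepts a SasaSeries or the final-window total directly; the sphere
    volume is accepted for the report but does not flip the verdict.
    """
    total = sasa.final_window_total if isinstance(sasa, SasaSeries) else float(sasa)
    if total <= th.sasa_lost_max:
        return "lost"
    if total >= th.sasa_retained_min:
        return "retained"
    return "indeterminate"


def separation_metrics(totals: dict[str, float], retained, lost) -> float:
    """Minimum between-group gap of final-window SASA totals (Å²):
    min over the retained group minus max over the lost group."""
    retained, lost = list(retained), list(lost)
    if not retained or not lost:
        raise ValueError("both groups must be non-empty")
    return min(totals[v] for v in retained) - max(totals[v] for v in lost)


@dataclass
class AnalysisConfig:
    """Knobs for the end-to-end pipeline."""

    variant: str = "custom"
    mutation_site: int = 17
    catalytic_residue: int = 114
    dihedral_atoms: tuple = ("HA", "CA", "CB", "CG")
    nls_selection: str = "resid 31-33"
    path_extension: tuple = (106, 113)
    hbond_cutoff: float = 3.2
    min_occupancy: float = 0.0
    stride: int = 1
    window_ns: float = 10.0
    sasa_params: SasaParams = field(default_factory=SasaParams)
    state_model: DihedralStateModel = field(default_factory=DihedralStateModel)
    thresholds: Thresholds = field(default_factory=Thresholds)
    chain: str = "A"
    seed: int | None = None


@dataclass
class MechanismReport:
    """Per-variant verdicts plus the evidence metrics behind them."""

    variant: str
    ribonucleolytic: str
    translocation: str
    altered_fraction: float
    switch_event_count: int
    final_window_sasa_total: float
    final_window_sasa_per_residue: dict
    mean_sphere_volume: float
    shortest_path: list
    shortest_path_multiplicity: int
    path_occupancy_sum: float
    thr44_thr80_occupancy: float
    asp116_ser118_occupancy: float
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MechanismReport":
        obj = json.loads(text)
        obj["shortest_path"] = [tuple(x) if isinstance(x, list) else x
                                for x in obj["shortest_path"]]
        return cls(**obj)

    def summary(self) -> str:
        path = "-".join(str(r[1]) for r in self.shortest_path) or "(none)"
        return (
            f"variant {self.variant}: ribonucleolytic {self.ribonucleolytic} "
            f"(altered fraction {self.altered_fraction:.3f}, "
            f"{self.switch_event_count} switches); "
            f"translocation {self.translocation} "
            f"(last-window NLS SASA {self.final_window_sasa_total:.2f} A^2, "
            f"mean sphere volume {self.mean_sphere_volume:.1f} A^3); "
            f"path {path} (occupancy sum {self.path_occupancy_sum:.2f})"
        )


def run_pipeline(traj: Trajectory, config: AnalysisConfig = AnalysisConfig()) -> MechanismReport:
    """Execute the full analysis chain on one trajectory.

    Stages: H-bond occupancy → residue graph and shortest
    mutation-site→catalytic-residue path (+ fixed extension) → dihedral
    state series → NLS SASA windows → sphere volume → classifiers.
    Deterministic for fixed inputs.
    """
    cfg = config
    crit = HBondCriterion(cutoff=cfg.hbond_cutoff)

    # --- hydrogen bonds and path ---------------------------------------
    try:
        table = occupancy(traj, crit, stride=cfg.stride)
    except Exception as exc:  # noqa: BLE001 - stage naming contract
        raise RuntimeError(f"hbond stage failed: {exc}") from exc
    graph = hbnetwork.build_graph(table, "occupancy-threshold", cfg.min_occupancy)
    src = (cfg.chain, cfg.mutation_site)
    dst = (cfg.chain, cfg.catalytic_residue)
    if src in graph and dst in graph:
        paths = hbnetwork.shortest_paths(graph, src, dst, extend=cfg.path_extension)
    else:
        paths = []
    if paths:
        best = paths[0]
        path_residues = list(best.residues)
        path_sum = hbnetwork.path_occupancy_sum(best.residues, table)
    else:
        path_residues, path_sum = [], 0.0

    # --- dihedral states -------------------------------------------------
    try:
        quad = [
            traj.atom_index(cfg.chain, cfg.catalytic_residue, nm)
            for nm in cfg.dihedral_atoms
        ]
    except KeyError as exc:
        raise RuntimeError(f"trajgeom stage failed: {exc}") from exc
    angles = trajgeom.dihedral_series(traj, quad)
    series = trajgeom.assign_states(angles, cfg.state_model)

    # --- NLS accessibility and packing -----------------------------------
    sasa = trajgeom.sasa_series(
        traj, cfg.sasa_params, cfg.nls_selection, cfg.window_ns, stride=cfg.stride
    )
    vol = trajgeom.sphere_volume_series(traj, cfg.nls_selection, stride=cfg.stride)

    report = MechanismReport(
        variant=cfg.variant,
        ribonucleolytic=classify_ribonucleolytic(series, cfg.thresholds),
        translocation=classify_translocation(sasa, vol, cfg.thresholds),
        altered_fraction=series.altered_fraction,
        switch_event_count=len(series.switch_events),
        final_window_sasa_total=sasa.final_window_total,
        final_window_sasa_per_residue={
            str(r[1]): float(v)
            for r, v in zip(sasa.residues, sasa.final_window_per_residue)
        },
        mean_sphere_volume=vol.mean,
        shortest_path=path_residues,
        shortest_path_multiplicity=len(paths),
        path_occupancy_sum=path_sum,
        thr44_thr80_occupancy=pair_occupancy(table, (cfg.chain, 44), (cfg.chain, 80)),
        asp116_ser118_occupancy=pair_occupancy(table, (cfg.chain, 116), (cfg.chain, 118)),
        provenance={
            "hbond_cutoff": cfg.hbond_cutoff,
            "min_occupancy": cfg.min_occupancy,
            "stride": cfg.stride,
            "window_ns": cfg.window_ns,
            "probe_radius": cfg.sasa_params.probe_radius,
            "n_sphere_points": cfg.sasa_params.n_sphere_points,
            "state_centers": [cfg.state_model.native_center,
                              cfg.state_model.altered_center],
            "state_tolerance": cfg.state_model.tolerance,
            "thresholds": asdict(cfg.thresholds),
            "seed": cfg.seed,
            "n_frames": traj.n_frames,
        },
    )
    return report
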
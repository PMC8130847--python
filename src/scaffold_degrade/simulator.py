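"""Time-stepping degradation engine.

Couples the strain-modulated kinetics to the element-level scaffold model:
each step advances the damage of alive elements at their (frozen) deployment
strain, updates fracture strains, and removes elements whose fracture strain
has fallen to or below the strain they carry (element death).  Deaths are
applied simultaneously at the end of the step, so results do not depend on
element ordering.  The trajectory logs mass-loss ratio, alive-graph
component count and a scaffold-capacity surrogate; full states are retained
at snapshot times (whole months by default, 30 days/month).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import kinetics
from .kinetics import DegradationCoefficients, TABLE_COEFFICIENTS
from .scaffold import ScaffoldField, ScaffoldState, detect_discontinuity, mass_loss_ratio

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "FractureEvent",
    "SimulationResult",
    "run",
    "capacity_surrogate",
    "fracture_time_table",
    "write_outputs",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Stepping controls for a degradation run.

    ``dt`` and ``horizon`` are in days; snapshots (full retained states) are
    taken every ``snapshot_interval`` days, which must be a multiple of
    ``dt``.  ``mode`` selects the damage accumulation rule (see
    :func:`scaffold_degrade.kinetics.advance_damage`).
    """

    dt: float = 0.5
    horizon: float = 180.0
    snapshot_interval: float = 30.0
    coefficients: DegradationCoefficients = TABLE_COEFFICIENTS
    mode: str = "equivalent_time"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.horizon < self.dt:
            raise ValueError(f"horizon ({self.horizon}) must be >= dt ({self.dt})")
        ratio = self.snapshot_interval / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"snapshot_interval ({self.snapshot_interval}) must be a multiple of dt ({self.dt})"
            )
        if self.mode not in ("equivalent_time", "global_time"):
            raise ValueError(f"unknown accumulation mode {self.mode!r}")


@dataclass(frozen=True)
class FractureEvent:
    """One element death: when it fractured and in what state."""

    element_id: int
    time_days: float
    strain: float
    degree: float


@dataclass
class SimulationResult:
    """Everything a run produces.

    ``trajectory`` has one row per step (plus t=0) with columns
    ``time_days, mass_loss_ratio, n_alive, n_components, capacity``;
    ``snapshots`` are full :class:`ScaffoldState` copies at snapshot times;
    ``fracture_curve`` tabulates the closed-form time-to-fracture over the
    field's strain range for plotting against the simulated deaths.
    """

    trajectory: pd.DataFrame
    events: list[FractureEvent]
    snapshots: list[ScaffoldState]
    final_state: ScaffoldState
    fracture_curve: pd.DataFrame = dc_field(default_factory=pd.DataFrame)

    @property
    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.element_id, e.time_days, e.strain, e.degree) for e in self.events],
            columns=["element_id", "time_days", "strain", "degree"],
        )

    def death_time(self, element_id: int) -> float:
        """Simulated death time of an element, or +inf if it survived."""
        for e in self.events:
            if e.element_id == element_id:
                return e.time_days
        return float("inf")


def _has_cycle(field: ScaffoldField, mask: np.ndarray | None = None) -> bool:
    g = field.graph(mask)
    return g.number_of_edges() > g.number_of_nodes() - nx.number_connected_components(g)


def capacity_surrogate(state: ScaffoldState, field: ScaffoldField) -> float:
    """Scaffold-capacity surrogate in [0, 1].

    Alive mass fraction, zeroed once every closed load path is lost: if the
    intact scaffold graph contains cycles (the circumferential rings) and the
    alive subgraph has become acyclic, no hoop-wise load path remains and the
    capacity is 0.  This is a connectivity surrogate for the stent-artery
    contact force, which requires a full contact solution; it is reported as
    such, never as a force.
    """
    if state.n_alive == 0:
        return 0.0
    alive_fraction = float(field.volumes[state.alive].sum() / field.total_volume)
    if _has_cycle(field) and not _has_cycle(field, state.alive):
        return 0.0
    return alive_fraction


def fracture_time_table(field: ScaffoldField,
                        coeffs: DegradationCoefficients = TABLE_COEFFICIENTS,
                        n: int = 50) -> pd.DataFrame:
    """Closed-form time-to-fracture t*(eps) over the field's strain range."""
    lo = max(float(field.strains.min()), 1e-3)
    hi = max(float(field.strains.max()), lo * (1 + 1e-9))
    eps = np.linspace(lo, hi, n)
    return pd.DataFrame({"strain": eps, "fracture_time_days": kinetics.fracture_time(eps, coeffs)})


def run(field: ScaffoldField, config: SimulationConfig = SimulationConfig()) -> SimulationResult:
    """Evolve the scaffold from the intact state to the horizon.

    Per step, for alive elements: advance degree, update fracture strain
    ``eps0*(1-D)``, then kill every element whose fracture strain is at or
    below its maximum principal strain.  With the strain field frozen the
    death time of each element matches the closed-form
    :func:`~scaffold_degrade.kinetics.fracture_time` within one step.
    """
    if not np.all(np.isfinite(field.strains)):
        raise ValueError("non-finite strain in field")
    coeffs = config.coefficients
    n = field.n_elements
    state = ScaffoldState.initial(field, coeffs)

    snap_every = int(round(config.snapshot_interval / config.dt))
    n_steps = int(np.floor(config.horizon / config.dt + 1e-9))

    events: list[FractureEvent] = []
    snapshots: list[ScaffoldState] = [state.copy()]
    report = detect_discontinuity(field, state)
    n_comp = report.n_components
    capacity = capacity_surrogate(state, field)

    rows = [(0.0, 0.0, n, n_comp, capacity)]
    for k in range(1, n_steps + 1):
        t = k * config.dt
        alive = state.alive
        state.degree[alive] = kinetics.advance_damage(
            state.degree[alive], field.strains[alive], config.dt,
            coeffs, mode=config.mode, elapsed_days=t,
        )
        state.fracture_strain[alive] = coeffs.epsilon0 * (1.0 - state.degree[alive])
        state.time_days = t

        # death criterion, applied simultaneously at end of step
        dying = alive & (state.fracture_strain <= field.strains)
        if np.any(dying):
            for i in np.flatnonzero(dying):
                events.append(FractureEvent(
                    int(field.element_ids[i]), t,
                    float(field.strains[i]), float(state.degree[i]),
                ))
            state.alive = alive & ~dying
            state.dead_volume = float(field.volumes[~state.alive].sum())
            n_comp = detect_discontinuity(field, state).n_components
            capacity = capacity_surrogate(state, field)
            logger.debug("t=%.2f d: %d elements died, %d alive, %d components",
                         t, int(dying.sum()), state.n_alive, n_comp)

        rows.append((t, mass_loss_ratio(state, field), state.n_alive, n_comp, capacity))
        if k % snap_every == 0:
            snapshots.append(state.copy())

    trajectory = pd.DataFrame(
        rows, columns=["time_days", "mass_loss_ratio", "n_alive", "n_components", "capacity"]
    )
    return SimulationResult(
        trajectory=trajectory,
        events=events,
        snapshots=snapshots,
        final_state=state,
        fracture_curve=fracture_time_table(field, coeffs),
    )


def write_outputs(result: SimulationResult, field: ScaffoldField, outdir: str | Path) -> None:
    """Write trajectory.csv, events.csv, fracture_curve.csv and per-snapshot
    files (VTK when the field carries mesh geometry, CSV otherwise)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.trajectory.to_csv(outdir / "trajectory.csv", index=False)
    result.events_frame.to_csv(outdir / "events.csv", index=False)
    result.fracture_curve.to_csv(outdir / "fracture_curve.csv", index=False)
    for snap in result.snapshots:
        tag = f"{snap.time_days:07.2f}".replace(".", "_")
        if field.points is not None and field.cells is not None:
            from .vtk_io import write_state_vtk

            write_state_vtk(field, snap, outdir / f"snapshot_t{tag}.vtk")
        else:
            pd.DataFrame({
                "element_id": field.element_ids,
                "degree": snap.degree,
                "fracture_strain": snap.fracture_strain,
                "alive": snap.alive.astype(int),
            }).to_csv(outdir / f"snapshot_t{tag}.csv", index=False)
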
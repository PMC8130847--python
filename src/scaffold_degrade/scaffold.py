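"""Discretized-scaffold data model and bookkeeping.

A deployed scaffold is represented per element: volume, the maximum
principal strain frozen from the acute-deployment state, and shared-face
adjacency.  Degradation state (degree, fracture strain, alive flag) lives in
:class:`ScaffoldState`.  The module also provides the reporting quantities of
a degradation run — mass-loss ratio, mass-weighted strain histogram, and
strut-discontinuity detection on the alive-element graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .kinetics import DegradationCoefficients, TABLE_COEFFICIENTS

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldField",
    "ScaffoldState",
    "DiscontinuityReport",
    "read_field",
    "write_field_csv",
    "mass_loss_ratio",
    "strain_histogram",
    "detect_discontinuity",
    "DEFAULT_BIN_EDGES",
]

#: Strain interval edges matching the representative material points used to
#: bin scaffold mass by deployment strain (descending as conventionally
#: reported).
DEFAULT_BIN_EDGES = (0.29, 0.16, 0.098, 0.067, 0.047, 0.036)


@dataclass
class ScaffoldField:
    """Per-element scaffold substrate.

    ``neighbors`` holds, for each element (by position), the element *ids* of
    its shared-face neighbors; adjacency is symmetric.  ``labels`` optionally
    tags elements by structural role (crown / link / body) for synthetic
    fields.  ``points``/``cells`` optionally carry hexahedral geometry when
    the field came from a mesh, enabling VTK snapshot output.
    """

    element_ids: np.ndarray
    volumes: np.ndarray
    strains: np.ndarray
    neighbors: list[frozenset]
    labels: np.ndarray | None = None
    points: np.ndarray | None = None
    cells: np.ndarray | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.element_ids = np.asarray(self.element_ids, dtype=np.int64)
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.strains = np.asarray(self.strains, dtype=float)
        n = self.element_ids.size
        if n == 0:
            raise ValueError("scaffold field must contain at least one element")
        if np.unique(self.element_ids).size != n:
            raise ValueError("element ids must be unique")
        if not (self.volumes.size == n and self.strains.size == n and len(self.neighbors) == n):
            raise ValueError("volumes, strains and neighbors must match element count")
        if np.any(self.volumes <= 0):
            bad = self.element_ids[self.volumes <= 0]
            raise ValueError(f"non-positive volumes for elements {bad.tolist()}")
        if not np.all(np.isfinite(self.strains)):
            bad = self.element_ids[~np.isfinite(self.strains)]
            raise ValueError(f"non-finite strains for elements {bad.tolist()}")
        if np.any(self.strains < 0):
            raise ValueError("strains must be clamped to >= 0 before constructing the field")
        self._index = {int(e): i for i, e in enumerate(self.element_ids)}
        self.neighbors = [frozenset(int(v) for v in s) for s in self.neighbors]
        for eid, nbrs in zip(self.element_ids, self.neighbors):
            for other in nbrs:
                if other not in self._index:
                    raise ValueError(f"element {eid} lists unknown neighbor {other}")
                if int(eid) not in self.neighbors[self._index[other]]:
                    raise ValueError(f"adjacency not symmetric between {eid} and {other}")

    @property
    def n_elements(self) -> int:
        return int(self.element_ids.size)

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    def index_of(self, element_id: int) -> int:
        return self._index[int(element_id)]

    def graph(self, mask: np.ndarray | None = None) -> nx.Graph:
        """Adjacency graph over elements; ``mask`` restricts to a subset."""
        g = nx.Graph()
        keep = np.ones(self.n_elements, bool) if mask is None else np.asarray(mask, bool)
        for i, eid in enumerate(self.element_ids):
            if keep[i]:
                g.add_node(int(eid))
        for i, eid in enumerate(self.element_ids):
            if not keep[i]:
                continue
            for other in self.neighbors[i]:
                if keep[self._index[other]] and int(eid) < other:
                    g.add_edge(int(eid), other)
        return g


@dataclass
class ScaffoldState:
    """Degradation state of every element at one time point.

    Invariants maintained by the simulator: fracture strain of alive elements
    equals ``epsilon0 * (1 - degree)``; dead mass is the volume sum of dead
    elements; alive mass + dead mass equals the field's total mass exactly.
    """

    time_days: float
    degree: np.ndarray
    fracture_strain: np.ndarray
    alive: np.ndarray
    dead_volume: float = 0.0

    @classmethod
    def initial(cls, field: ScaffoldField,
                coeffs: DegradationCoefficients = TABLE_COEFFICIENTS) -> "ScaffoldState":
        n = field.n_elements
        return cls(
            time_days=0.0,
            degree=np.zeros(n),
            fracture_strain=np.full(n, coeffs.epsilon0),
            alive=np.ones(n, dtype=bool),
            dead_volume=0.0,
        )

    def copy(self) -> "ScaffoldState":
        return ScaffoldState(
            self.time_days, self.degree.copy(), self.fracture_strain.copy(),
            self.alive.copy(), self.dead_volume,
        )

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())


def read_field(path: str | Path, format: str | None = None) -> ScaffoldField:
    """Read a scaffold field from CSV (or legacy VTK via ``vtk_io``).

    CSV dialect: header ``element_id,volume,max_principal_strain,neighbors``
    with ``neighbors`` a semicolon-separated id list (may be listed on one
    side only; adjacency is symmetrised).  Negative principal strains are
    clamped to 0 with a logged count — compression does not drive the
    tensile degradation law.
    """
    path = Path(path)
    if format is None:
        format = "vtk" if path.suffix.lower() == ".vtk" else "csv"
    if format == "vtk":
        from .vtk_io import field_from_vtk

        return field_from_vtk(path)
    if format != "csv":
        raise ValueError(f"unknown field format {format!r}")

    df = pd.read_csv(path, dtype={"neighbors": str})
    required = ["element_id", "volume", "max_principal_strain", "neighbors"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    dup = df["element_id"][df["element_id"].duplicated()]
    if not dup.empty:
        rows = (dup.index + 2).tolist()  # 1-based, plus header line
        raise ValueError(f"{path}: duplicate element ids at rows {rows}")
    bad_vol = df.index[df["volume"] <= 0]
    if len(bad_vol):
        raise ValueError(f"{path}: non-positive volumes at rows {(bad_vol + 2).tolist()}")

    strains = df["max_principal_strain"].to_numpy(float)
    n_neg = int((strains < 0).sum())
    if n_neg:
        logger.warning("%s: clamped %d negative principal strains to 0", path, n_neg)
        strains = np.maximum(strains, 0.0)

    ids = df["element_id"].to_numpy(np.int64)
    idx = {int(e): i for i, e in enumerate(ids)}
    nbrs: list[set] = [set() for _ in ids]
    for i, raw in enumerate(df["neighbors"].fillna("")):
        for tok in str(raw).split(";"):
            tok = tok.strip()
            if not tok:
                continue
            other = int(tok)
            if other not in idx:
                raise ValueError(f"{path}: row {i + 2} lists unknown neighbor {other}")
            nbrs[i].add(other)
            nbrs[idx[other]].add(int(ids[i]))  # symmetrise one-sided listings

    return ScaffoldField(
        element_ids=ids,
        volumes=df["volume"].to_numpy(float),
        strains=strains,
        neighbors=[frozenset(s) for s in nbrs],
    )


def write_field_csv(field: ScaffoldField, path: str | Path) -> None:
    """Write a field in the CSV dialect accepted by :func:`read_field`."""
    rows = []
    for i, eid in enumerate(field.element_ids):
        nbrs = ";".join(str(v) for v in sorted(field.neighbors[i]))
        rows.append((int(eid), field.volumes[i], field.strains[i], nbrs))
    df = pd.DataFrame(rows, columns=["element_id", "volume", "max_principal_strain", "neighbors"])
    if field.labels is not None:
        df["label"] = field.labels
    df.to_csv(path, index=False)


def mass_loss_ratio(state: ScaffoldState, field: ScaffoldField) -> float:
    """Absorbed (dead) mass over total scaffold mass, in [0, 1]."""
    if state.alive.size != field.n_elements:
        raise ValueError("state and field element counts differ")
    return float(field.volumes[~state.alive].sum() / field.total_volume)


def strain_histogram(field: ScaffoldField, bin_edges=DEFAULT_BIN_EDGES) -> pd.Series:
    """Mass fraction of the scaffold per strain interval.

    ``bin_edges`` must be strictly monotone (either direction); elements
    beyond the outermost edges are collected in open end bins, so the
    fractions always sum to 1.  Returns a Series indexed by interval label,
    ordered from the lowest-strain bin upward.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 1:
        raise ValueError("at least one bin edge is required")
    diffs = np.diff(edges)
    if edges.size > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise ValueError(f"bin edges must be strictly monotone, got {bin_edges!r}")
    edges = np.sort(edges)

    which = np.digitize(field.strains, edges)  # 0 .. len(edges)
    mass = np.bincount(which, weights=field.volumes, minlength=edges.size + 1)
    labels = [f"[0, {edges[0]:g})"]
    labels += [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels += [f"[{edges[-1]:g}, inf)"]
    return pd.Series(mass / field.total_volume, index=labels, name="mass_fraction")


@dataclass(frozen=True)
class DiscontinuityReport:
    """Connectivity of the alive-element graph versus the intact scaffold."""

    n_components: int
    components: tuple[frozenset, ...]
    n_components_initial: int

    @property
    def is_discontinuous(self) -> bool:
        return self.n_components > self.n_components_initial


def detect_discontinuity(field: ScaffoldField, state: ScaffoldState | None = None) -> DiscontinuityReport:
    """Connected components of the alive-element adjacency graph.

    A discontinuity event is an increase of the component count relative to
    the fully-alive graph (struts can only break, never rejoin, because
    element death is irreversible).
    """
    n0 = nx.number_connected_components(field.graph())
    mask = None if state is None else state.alive
    g = field.graph(mask)
    comps = tuple(frozenset(c) for c in nx.connected_components(g))
    return DiscontinuityReport(len(comps), comps, n0)
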
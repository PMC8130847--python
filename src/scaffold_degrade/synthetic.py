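"""Synthetic inputs: stent-like strain fields and degradation datasets.

Real deployment strain fields come out of a finite-element contact
simulation, which is outside this package.  What degradation cares about is
the strain *structure* after acute deployment: high tensile strain at the
crowns (U-bends) of each ring, intermediate strain in the connecting links,
low strain along straight strut bodies.  ``generate_stent_field`` builds a
coarse ring-and-link graph with exactly that ordering — rings of alternating
struts joined by link chains, mirroring the device topology (two rings of
six peaks joined by three links at device scale) — and assigns each role a
strain level with multiplicative lognormal scatter so strains stay positive.

``generate_degradation_dataset`` emulates the coupon experiments used for
coefficient fitting: pre-stretch levels crossed with retrieval times, the
forward degradation law plus Gaussian measurement noise, clipped to [0, 1].

Both generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import (
    DegradationCoefficients,
    DegradationRecord,
    TABLE_COEFFICIENTS,
    degradation_degree,
)
from .scaffold import ScaffoldField

__all__ = ["StentFieldSpec", "generate_stent_field", "generate_degradation_dataset",
           "COUPON_DESIGN"]

#: Pre-stretch strains and retrieval times of the coupon experiments the
#: kinetic coefficients are fitted to.
COUPON_DESIGN = {"strains": (0.0, 0.2, 0.4), "times": (3.0, 10.0, 20.0, 30.0)}


@dataclass(frozen=True)
class StentFieldSpec:
    """Recipe for a synthetic deployment strain field.

    Strain levels are maximum principal strains after deployment; the crown
    default 0.3 puts U-bends in the fractures-within-a-month regime while
    the body default 0.03 keeps straight struts intact for many months.
    ``volume`` is mm^3 per element (default: a 0.03 mm cube, the device's
    brick-element scale).  ``sigma_log`` is the lognormal scatter of the
    strain multipliers.
    """

    n_rings: int = 2
    peaks_per_ring: int = 6
    elements_per_strut: int = 4
    n_links: int = 3
    crown_strain: float = 0.3
    link_strain: float = 0.12
    body_strain: float = 0.03
    volume: float = 2.7e-5
    sigma_log: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rings, self.peaks_per_ring, self.elements_per_strut) < 1:
            raise ValueError("ring/peak/strut counts must be positive")
        if self.n_links < 0:
            raise ValueError("n_links must be non-negative")
        if min(self.crown_strain, self.link_strain, self.body_strain) < 0:
            raise ValueError("strain levels must be non-negative")
        if self.volume <= 0:
            raise ValueError("element volume must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be non-negative")


def generate_stent_field(spec: StentFieldSpec = StentFieldSpec()) -> ScaffoldField:
    """Build the ring-and-link scaffold graph with role-based strains.

    Each ring is a closed chain of ``2 * peaks_per_ring`` struts of
    ``elements_per_strut`` elements; the element at each strut junction is a
    crown (turning point).  ``n_links`` chains of elements join consecutive
    rings at evenly spaced valleys.  Element labels ("crown" / "link" /
    "body") are attached for downstream analysis.
    """
    rng = np.random.default_rng(spec.seed)
    per_ring = 2 * spec.peaks_per_ring * spec.elements_per_strut

    ids: list[int] = []
    labels: list[str] = []
    edges: list[tuple[int, int]] = []
    ring_elem: list[list[int]] = []
    next_id = 0

    for _ in range(spec.n_rings):
        ring = list(range(next_id, next_id + per_ring))
        next_id += per_ring
        ring_elem.append(ring)
        ids.extend(ring)
        for j, eid in enumerate(ring):
            labels.append("crown" if j % spec.elements_per_strut == 0 else "body")
            edges.append((eid, ring[(j + 1) % per_ring]))

    for r in range(spec.n_rings - 1):
        for k in range(spec.n_links):
            # attach links at evenly spaced valleys of ring r
            pos = (k * per_ring) // max(spec.n_links, 1)
            a = ring_elem[r][pos]
            b = ring_elem[r + 1][pos]
            chain = list(range(next_id, next_id + spec.elements_per_strut))
            next_id += spec.elements_per_strut
            ids.extend(chain)
            labels.extend(["link"] * len(chain))
            edges.append((a, chain[0]))
            for u, v in zip(chain[:-1], chain[1:]):
                edges.append((u, v))
            edges.append((chain[-1], b))

    level = {"crown": spec.crown_strain, "link": spec.link_strain, "body": spec.body_strain}
    base = np.array([level[lab] for lab in labels])
    scatter = rng.lognormal(mean=0.0, sigma=spec.sigma_log, size=base.size)
    strains = base * scatter

    nbrs: list[set] = [set() for _ in ids]
    for u, v in edges:
        nbrs[u].add(v)
        nbrs[v].add(u)

    return ScaffoldField(
        element_ids=np.array(ids),
        volumes=np.full(len(ids), spec.volume),
        strains=strains,
        neighbors=[frozenset(s) for s in nbrs],
        labels=np.array(labels),
    )


def generate_degradation_dataset(
    coeffs: DegradationCoefficients = TABLE_COEFFICIENTS,
    design: dict = COUPON_DESIGN,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[DegradationRecord]:
    """Full-factorial coupon dataset from the forward degradation law.

    One record per (strain, time) pair with degree
    ``D(strain, time) + N(0, noise_sd)``, clipped to [0, 1]; seeded and
    reproducible.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    strains = list(design.get("strains", ()))
    times = list(design.get("times", ()))
    if not strains or not times:
        raise ValueError("design must provide non-empty 'strains' and 'times'")
    rng = np.random.default_rng(seed)
    records = []
    for eps in strains:
        for t in times:
            d = degradation_degree(eps, t, coeffs)
            if noise_sd > 0:
                d = float(np.clip(d + rng.normal(0.0, noise_sd), 0.0, 1.0))
            records.append(DegradationRecord(float(eps), float(t), d))
    return records
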
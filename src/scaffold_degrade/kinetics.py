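"""Degradation kinetics of strained PLLA.

The constitutive picture: a semi-crystalline poly-l-lactide coupon held at a
tensile pre-stretch ``eps`` and immersed in buffered saline loses ductility
over time.  The loss is tracked by a scalar *degradation degree*

    D(eps, t) = a * (b + c * eps**n) * t**m,          t in days,

capped at 1, with the fracture strain degrading linearly with D,

    eps_t = eps0 * (1 - D).

Material fails once its fracture strain drops to the strain it actually
carries; inverting the power law gives the closed-form time-to-fracture used
throughout the simulator.  The five constants (a, b, c, m, n) come from a
least-squares fit to degradation experiments (pre-stretch 0 / 0.2 / 0.4,
retrieval at 3 / 10 / 20 / 30 days); the defaults below are that fit.

All evaluation functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DegradationCoefficients",
    "DegradationRecord",
    "FitResult",
    "degradation_degree",
    "fracture_strain",
    "fracture_time",
    "equivalent_time",
    "advance_damage",
    "fit_coefficients",
    "read_degradation_records",
    "write_degradation_records",
]


@dataclass(frozen=True)
class DegradationCoefficients:
    """Constants of the degradation law plus the virgin fracture strain.

    a, b, c are dimensionless amplitudes; m and n are the time and strain
    exponents; ``epsilon0`` is the fracture strain of undegraded PLLA
    (default 1.22, i.e. 122% engineering strain at break).
    """

    a: float = 0.385
    b: float = 0.152
    c: float = 0.616
    m: float = 0.342
    n: float = 0.236
    epsilon0: float = 1.22

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"coefficient a must be positive, got {self.a}")
        if self.b < 0 or self.c < 0:
            raise ValueError(
                f"coefficients b, c must be non-negative, got b={self.b}, c={self.c}"
            )
        if not (self.m > 0 and self.n > 0):
            raise ValueError(
                f"exponents m, n must be positive, got m={self.m}, n={self.n}"
            )
        if not (self.epsilon0 > 0):
            raise ValueError(f"epsilon0 must be positive, got {self.epsilon0}")

    def as_array(self) -> np.ndarray:
        """The five fitted constants (a, b, c, m, n) as a vector."""
        return np.array([self.a, self.b, self.c, self.m, self.n])


#: Published coefficients for Absorb-type PLLA (see module docstring).
TABLE_COEFFICIENTS = DegradationCoefficients()


@dataclass(frozen=True)
class DegradationRecord:
    """One degradation-experiment observation: coupon pre-stretched to
    ``strain``, retrieved after ``time_days``, measured degree ``degree``."""

    strain: float
    time_days: float
    degree: float

    def __post_init__(self) -> None:
        if self.strain < 0:
            raise ValueError(f"strain must be >= 0, got {self.strain}")
        if self.time_days < 0:
            raise ValueError(f"time_days must be >= 0, got {self.time_days}")
        if not (0.0 <= self.degree <= 1.0):
            raise ValueError(f"degree must lie in [0, 1], got {self.degree}")


def _check_nonnegative(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return arr


def degradation_degree(strain, time_days, coeffs: DegradationCoefficients = TABLE_COEFFICIENTS):
    """Degradation degree D(eps, t), capped at 1.

    Non-decreasing in both strain and time; exactly 0 at t = 0.  Negative
    strain is a caller error here — compressive principal strains are clamped
    upstream when reading scaffold fields, not silently accepted.
    """
    eps = _check_nonnegative("strain", strain)
    t = _check_nonnegative("time_days", time_days)
    raw = coeffs.a * (coeffs.b + coeffs.c * eps**coeffs.n) * t**coeffs.m
    out = np.minimum(1.0, raw)
    return float(out) if out.ndim == 0 else out


def fracture_strain(degree, coeffs: DegradationCoefficients = TABLE_COEFFICIENTS):
    """Current fracture strain eps_t = eps0 * (1 - D); linear in D."""
    d = np.asarray(degree, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError(f"degree must lie in [0, 1], got {degree!r}")
    out = coeffs.epsilon0 * (1.0 - d)
    return float(out) if out.ndim == 0 else out


def fracture_time(strain, coeffs: DegradationCoefficients = TABLE_COEFFICIENTS):
    """Days until material strained to ``strain`` reaches its fracture strain.

    Solves D(eps, t) = 1 - eps/eps0 for t:

        t* = [ (1 - eps/eps0) / (a*(b + c*eps**n)) ]**(1/m)

    Returns 0 where strain already equals or exceeds eps0.  Strictly
    decreasing in strain on (0, eps0).
    """
    eps = _check_nonnegative("strain", strain)
    target = 1.0 - eps / coeffs.epsilon0
    rate = coeffs.a * (coeffs.b + coeffs.c * eps**coeffs.n)
    with np.errstate(invalid="ignore"):
        t = np.where(target <= 0.0, 0.0, (np.maximum(target, 0.0) / rate) ** (1.0 / coeffs.m))
    return float(t) if t.ndim == 0 else t


def equivalent_time(degree, strain, coeffs: DegradationCoefficients = TABLE_COEFFICIENTS):
    """Pseudo-time t_eq at which D(strain, t_eq) equals ``degree``.

    The inverse of the degradation law in time at fixed strain; the anchor of
    the strain-hardening accumulation rule in :func:`advance_damage`.
    """
    d = np.asarray(degree, dtype=float)
    eps = _check_nonnegative("strain", strain)
    rate = coeffs.a * (coeffs.b + coeffs.c * eps**coeffs.n)
    t = (np.clip(d, 0.0, 1.0) / rate) ** (1.0 / coeffs.m)
    return float(t) if t.ndim == 0 else t


def advance_damage(
    current_degree,
    strain,
    dt: float,
    coeffs: DegradationCoefficients = TABLE_COEFFICIENTS,
    mode: str = "equivalent_time",
    elapsed_days: float | None = None,
):
    """Advance the damage state by one step of ``dt`` days at ``strain``.

    ``mode="equivalent_time"`` (default) uses the strain-hardening scheme:
    find the pseudo-time t_eq giving the current degree at the *current*
    strain, then evaluate the law at t_eq + dt.  Under constant strain this
    composes exactly to the closed form, independent of step partition.

    ``mode="global_time"`` re-evaluates the law at the global elapsed time
    with the current strain (the naive alternative, kept for comparison);
    it requires ``elapsed_days`` = time at the *end* of the step.

    Damage is irreversible: the result is never below ``current_degree`` and
    a degree of 1 is absorbing.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    d = np.asarray(current_degree, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError(f"current_degree must lie in [0, 1], got {current_degree!r}")

    if mode == "equivalent_time":
        t_eq = equivalent_time(d, strain, coeffs)
        new = degradation_degree(strain, np.asarray(t_eq) + dt, coeffs)
    elif mode == "global_time":
        if elapsed_days is None:
            raise ValueError("global_time mode requires elapsed_days")
        new = degradation_degree(strain, elapsed_days, coeffs)
    else:
        raise ValueError(f"unknown accumulation mode {mode!r}")

    out = np.where(d >= 1.0, 1.0, np.maximum(d, new))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FitResult:
    """Outcome of a coefficient fit."""

    coefficients: DegradationCoefficients
    residual_norm: float
    residuals: np.ndarray = field(repr=False)
    n_records: int = 0


DEFAULT_BOUNDS = (np.array([0.0, 0.0, 0.0, 0.01, 0.01]),
                  np.array([10.0, 10.0, 10.0, 3.0, 3.0]))


def fit_coefficients(
    records: Sequence[DegradationRecord] | pd.DataFrame,
    init: DegradationCoefficients | None = None,
    bounds: tuple[np.ndarray, np.ndarray] = DEFAULT_BOUNDS,
) -> FitResult:
    """Least-squares fit of (a, b, c, m, n) to degradation observations.

    Bounded trust-region least squares (scipy ``least_squares``, method
    ``trf``), initialised at the published constants unless ``init`` is
    given; deterministic for a fixed initialisation.  ``epsilon0`` is not
    fitted — it is carried over from ``init``.

    Raises an identifiability error when fewer than five records are given
    or the design has fewer than two distinct strains or times: with a
    single strain the strain terms (c, n) are invisible, with a single time
    the exponent m is.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            DegradationRecord(r.strain, r.time_days, r.degree)
            for r in records.itertuples(index=False)
        ]
    records = list(records)
    eps = np.array([r.strain for r in records])
    t = np.array([r.time_days for r in records])
    d_obs = np.array([r.degree for r in records])

    if len(records) < 5:
        raise ValueError(
            f"need at least 5 records to fit 5 coefficients, got {len(records)}"
        )
    if np.unique(eps).size < 2:
        raise ValueError(
            "design is degenerate: at least 2 distinct strains are required "
            "to identify the strain terms (c, n)"
        )
    if np.unique(t[t > 0]).size < 2:
        raise ValueError(
            "design is degenerate: at least 2 distinct positive times are "
            "required to identify the time exponent m"
        )

    init = init or TABLE_COEFFICIENTS

    def residual(x: np.ndarray) -> np.ndarray:
        a, b, c, m, n = x
        with np.errstate(invalid="ignore"):
            pred = np.minimum(1.0, a * (b + c * eps**n) * t**m)
        return pred - d_obs

    sol = least_squares(residual, init.as_array(), bounds=bounds, method="trf")
    a, b, c, m, n = sol.x
    fitted = replace(init, a=a, b=b, c=c, m=m, n=n)
    return FitResult(
        coefficients=fitted,
        residual_norm=float(np.linalg.norm(sol.fun)),
        residuals=sol.fun,
        n_records=len(records),
    )


def read_degradation_records(path: str | Path) -> list[DegradationRecord]:
    """Read records from a CSV with header ``strain,time_days,degree``."""
    df = pd.read_csv(path)
    missing = {"strain", "time_days", "degree"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        DegradationRecord(float(r.strain), float(r.time_days), float(r.degree))
        for r in df.itertuples(index=False)
    ]


def write_degradation_records(records: Iterable[DegradationRecord], path: str | Path) -> None:
    """Write records to CSV (header ``strain,time_days,degree``)."""
    pd.DataFrame(
        [(r.strain, r.time_days, r.degree) for r in records],
        columns=["strain", "time_days", "degree"],
    ).to_csv(path, index=False)
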
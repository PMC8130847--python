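"""Hyperelastic artery response and deployment bookkeeping.

The artery wall is modelled as an incompressible isotropic reduced-polynomial
hyperelastic solid,

    U(I1b) = sum_{i=1..6} Ci0 * (I1b - 3)**i        [MPa],

with I1b the first invariant of the isochoric Cauchy-Green tensor.  From U
the module derives the incompressible uniaxial Cauchy stress and the
small-strain modulus (6*C10).  It also provides elastic-recoil bookkeeping
and a reduced-order lumen-diameter trend driven by the simulator's
scaffold-capacity surrogate — a documented stand-in for the full
contact-mechanics coupling, not an FE prediction.

Coefficient units are MPa by the usual convention for coronary tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ArteryCoefficients",
    "strain_energy",
    "uniaxial_stress",
    "initial_modulus",
    "recoil_rate",
    "lumen_trend",
]


@dataclass(frozen=True)
class ArteryCoefficients:
    """Reduced-polynomial coefficients C10..C60 in MPa (coronary wall fit)."""

    C10: float = 6.52e-3
    C20: float = 4.89e-2
    C30: float = 9.26e-3
    C40: float = 0.76
    C50: float = -0.43
    C60: float = 8.69e-2

    def __post_init__(self) -> None:
        for name in ("C10", "C20", "C30", "C40", "C50", "C60"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.C10, self.C20, self.C30, self.C40, self.C50, self.C60])


TABLE_ARTERY = ArteryCoefficients()


def strain_energy(I1bar, coeffs: ArteryCoefficients = TABLE_ARTERY):
    """Strain energy density U(I1b) in MPa; zero in the undeformed state."""
    x = np.asarray(I1bar, dtype=float) - 3.0
    if np.any(x < 0):
        raise ValueError(f"I1bar must be >= 3, got {I1bar!r}")
    c = coeffs.as_array()
    out = sum(c[i] * x ** (i + 1) for i in range(6))
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def _dU_dI1(x: np.ndarray, coeffs: ArteryCoefficients) -> np.ndarray:
    c = coeffs.as_array()
    return sum((i + 1) * c[i] * x**i for i in range(6))


def uniaxial_stress(stretch, coeffs: ArteryCoefficients = TABLE_ARTERY):
    """Incompressible uniaxial Cauchy stress at stretch lambda, in MPa.

    sigma = 2*(lambda^2 - 1/lambda) * dU/dI1 evaluated at
    I1b = lambda^2 + 2/lambda; zero at lambda = 1, tensile for lambda > 1.
    """
    lam = np.asarray(stretch, dtype=float)
    if np.any(lam <= 0):
        raise ValueError(f"stretch must be positive, got {stretch!r}")
    x = lam**2 + 2.0 / lam - 3.0
    out = 2.0 * (lam**2 - 1.0 / lam) * _dU_dI1(x, coeffs)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def initial_modulus(coeffs: ArteryCoefficients = TABLE_ARTERY) -> float:
    """Small-strain uniaxial modulus d(sigma)/d(lambda) at lambda=1: 6*C10."""
    return 6.0 * coeffs.C10


def recoil_rate(expanded_d: float, recoiled_d: float) -> float:
    """Elastic recoil in percent, 100*(De - Dr)/De, reported to one decimal.

    ``expanded_d`` is the outer diameter at full balloon expansion and
    ``recoiled_d`` the diameter after balloon withdrawal, in mm.
    """
    if recoiled_d <= 0:
        raise ValueError(f"diameters must be positive, got recoiled {recoiled_d}")
    if recoiled_d > expanded_d:
        raise ValueError(
            f"recoiled diameter ({recoiled_d}) cannot exceed expanded diameter ({expanded_d})"
        )
    return round(100.0 * (expanded_d - recoiled_d) / expanded_d, 1)


def lumen_trend(capacity_trajectory, diameters: dict[str, float],
                mode: str = "linear"):
    """Reduced-order lumen diameter versus scaffold capacity.

    Monotone interpolation between the deployed diameter (capacity 1) and the
    unloaded vessel diameter (capacity 0): linear by default, or a smoothstep
    easing with ``mode="smoothstep"``.  ``diameters`` needs keys ``deployed``
    and ``unloaded`` in mm.  Accepts a scalar, array or pandas Series of
    capacities (the Series index, typically time, is preserved).
    """
    d1, d0 = float(diameters["deployed"]), float(diameters["unloaded"])
    index = capacity_trajectory.index if isinstance(capacity_trajectory, pd.Series) else None
    cap = np.asarray(capacity_trajectory, dtype=float)
    if np.any(cap < 0) or np.any(cap > 1):
        raise ValueError("capacity values must lie in [0, 1]")
    if cap.ndim > 0 and np.any(np.diff(cap) > 1e-9):
        raise ValueError("capacity trajectory must be non-increasing")
    if mode == "linear":
        w = cap
    elif mode == "smoothstep":
        w = cap**2 * (3.0 - 2.0 * cap)
    else:
        raise ValueError(f"unknown interpolation mode {mode!r}")
    out = d0 + (d1 - d0) * w
    if index is not None:
        return pd.Series(out, index=index, name="lumen_diameter_mm")
    return float(out) if out.ndim == 0 else out
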
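"""Center-of-mass calibration and kinematics.

During quasi-static motion the center of pressure tracks the projected
center of mass, so a least-squares regression of COP on hip and shoulder
translation yields coefficients (a, b, c) that reconstruct COM position
from the sway rods during dynamic trials.  The angular COM excursion about
the ankle is then ``arcsin(x_com / h_com)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationCoefficients",
    "RankDeficiencyError",
    "cop_from_torque",
    "fit_calibration",
    "compute_com",
    "com_angle",
    "GRAVITY",
]

GRAVITY = 9.81  # m/s^2


class RankDeficiencyError(ValueError):
    """Calibration regressors are collinear or constant."""


@dataclass(frozen=True)
class CalibrationCoefficients:
    """COM reconstruction coefficients with fit diagnostics.

    ``x_com = a + b * x_hip + c * x_sho``
    """

    a: float  # m
    b: float  # dimensionless hip weight
    c: float  # dimensionless shoulder weight
    residual_rms: float  # m
    n_samples: int
    condition_number: float = float("nan")

    def __post_init__(self):
        # tolerance keeps numerically-zero weights from tripping the warning
        if self.b < -1e-9 or self.c < -1e-9:
            warnings.warn(
                f"calibration weights b={self.b:.4g}, c={self.c:.4g} are "
                "negative; physically implausible for a two-segment stander",
                stacklevel=3,
            )


def cop_from_torque(
    torque: np.ndarray, body_mass: float, g: float = GRAVITY
) -> np.ndarray:
    """Center-of-pressure position (m) from ankle torque (N*m).

    Valid only for platform-stationary segments, where the measured torque is
    purely the subject's ankle torque: ``x_cop = torque / (body_mass * g)``.
    """
    if body_mass <= 0:
        raise ValueError(f"body_mass must be positive, got {body_mass}")
    return np.asarray(torque, dtype=float) / (body_mass * g)


def fit_calibration(
    x_hip: np.ndarray,
    x_sho: np.ndarray,
    x_cop: np.ndarray,
    max_condition: float = 1e8,
) -> CalibrationCoefficients:
    """Least-squares fit of ``x_cop ~ a + b * x_hip + c * x_sho``.

    Raises :class:`RankDeficiencyError` when the design matrix is rank
    deficient or its condition number exceeds ``max_condition`` (constant or
    collinear hip/shoulder channels).
    """
    x_hip = np.asarray(x_hip, dtype=float)
    x_sho = np.asarray(x_sho, dtype=float)
    x_cop = np.asarray(x_cop, dtype=float)
    if not (len(x_hip) == len(x_sho) == len(x_cop)):
        raise ValueError("x_hip, x_sho and x_cop must have equal length")
    n = len(x_cop)
    if n < 3:
        raise ValueError(f"need at least 3 samples to fit 3 coefficients, got {n}")

    design = np.column_stack([np.ones(n), x_hip, x_sho])
    cond = float(np.linalg.cond(design))
    rank = np.linalg.matrix_rank(design)
    if rank < 3 or not np.isfinite(cond) or cond > max_condition:
        raise RankDeficiencyError(
            "hip/shoulder regressors are collinear or constant "
            f"(rank {rank}, condition number {cond:.3g} > {max_condition:.3g})"
        )
    coef, _, _, _ = np.linalg.lstsq(design, x_cop, rcond=None)
    residuals = x_cop - design @ coef
    return CalibrationCoefficients(
        a=float(coef[0]),
        b=float(coef[1]),
        c=float(coef[2]),
        residual_rms=float(np.sqrt(np.mean(residuals**2))),
        n_samples=n,
        condition_number=cond,
    )


def compute_com(
    x_hip: np.ndarray, x_sho: np.ndarray, coeffs: CalibrationCoefficients
) -> np.ndarray:
    """Reconstruct COM position: ``a + b * x_hip + c * x_sho`` (m)."""
    x_hip = np.asarray(x_hip, dtype=float)
    x_sho = np.asarray(x_sho, dtype=float)
    if len(x_hip) != len(x_sho):
        raise ValueError("x_hip and x_sho must have equal length")
    return coeffs.a + coeffs.b * x_hip + coeffs.c * x_sho


def com_angle(x_com: np.ndarray, h_com: float) -> np.ndarray:
    """Angular COM sway about the ankle, ``arcsin(x_com / h_com)``, in degrees."""
    if h_com <= 0:
        raise ValueError(f"h_com must be positive, got {h_com}")
    x_com = np.asarray(x_com, dtype=float)
    bad = np.flatnonzero(np.abs(x_com) >= h_com)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"|x_com| >= h_com at sample {i} "
            f"(x_com={x_com[i]:.6g} m, h_com={h_com:.6g} m): arcsin undefined"
        )
    return np.degrees(np.arcsin(x_com / h_com))
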
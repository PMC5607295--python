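"""Mirror-polariser calibration: reference targets and coefficient regression.

The probe faces an external linear polariser backed by a front-surface
mirror.  Light crosses the polariser, reflects, and crosses it again; on
the return pass the polariser axis appears at ``180 - theta``, so the
known double-pass target is ``P(180 - theta) . M_mirror . P(theta)``.
Recording the nine pair intensities at several polariser angles
(0, 30, 60 deg by default) and regressing the reconstructed, m11-
normalized matrix against the known target yields the nine per-pair
coefficients c that undo unequal channel couplings.  The objective is
invariant under a global rescaling of c (normalization removes overall
scale), so the returned coefficients are gauge-fixed to mean(c) = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .mueller import linear_polariser, linear_submatrix, mirror
from .probe import (
    PAIR_SCHEME,
    MeasurementSet,
    NoiseModel,
    ProbeModel,
    simulate_measurement_set,
)
from .reconstruction import SystemMatrix

__all__ = [
    "DEFAULT_ANGLES",
    "CalibrationSession",
    "CalibrationResult",
    "reference_target",
    "simulate_calibration_session",
    "fit_coefficients",
]

DEFAULT_ANGLES: tuple[float, ...] = (0.0, 30.0, 60.0)


def reference_target(theta_deg: float,
                     polariser_matrices: dict[float, np.ndarray] | None = None
                     ) -> np.ndarray:
    """Known 3x3 target of the polariser double pass at ``theta``.

    By default the external polariser is ideal and the product is
    composed in 4x4 before truncation.  Independently measured 3x3
    polariser matrices may be supplied as a mapping angle -> matrix
    covering ``theta`` and ``180 - theta``; the mirror is always the
    ideal ``diag(1, 1, -1)``.  (For polarisers, which carry no V
    coupling, 3x3 composition is exact.)
    """
    if polariser_matrices is not None:
        second = np.asarray(polariser_matrices[180.0 - theta_deg], dtype=float)
        first = np.asarray(polariser_matrices[theta_deg], dtype=float)
        mir3 = np.diag([1.0, 1.0, -1.0])
        return second @ mir3 @ first
    m4 = (linear_polariser(180.0 - theta_deg) @ mirror()
          @ linear_polariser(theta_deg))
    return linear_submatrix(m4)


@dataclass(frozen=True)
class CalibrationSession:
    """Intensities of the nine pairs at each external-polariser angle."""

    angles: tuple[float, ...]
    measurements: dict[float, MeasurementSet]

    def __post_init__(self) -> None:
        if len(self.angles) != len(set(self.angles)):
            raise ValueError("calibration angles must be distinct")
        if set(self.measurements) != set(self.angles):
            raise ValueError("one measurement set per angle is required")

    def intensity(self, angle: float, pair: str) -> float:
        return self.measurements[angle].intensities[pair]

    def scaled(self, factors: dict[str, float]) -> "CalibrationSession":
        """Copy with per-pair intensity factors applied at every angle."""
        return CalibrationSession(
            self.angles,
            {a: ms.scaled(factors) for a, ms in self.measurements.items()})


def simulate_calibration_session(probe: ProbeModel,
                                 angles: tuple[float, ...] = DEFAULT_ANGLES,
                                 noise: NoiseModel | None = None,
                                 seed: int | None = None) -> CalibrationSession:
    """Forward-simulate a calibration run with the probe's true gains."""
    measurements = {}
    for k, angle in enumerate(angles):
        sub_seed = None if seed is None else seed + k
        measurements[angle] = simulate_measurement_set(
            probe, reference_target(angle), noise=noise, seed=sub_seed)
    return CalibrationSession(tuple(angles), measurements)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted per-pair coefficients, gauge-fixed to mean 1."""

    coefficients: dict[str, float]
    gauge: str
    objective_value: float
    converged: bool
    n_evaluations: int = 0

    def vector(self, pairs: tuple[str, ...] = PAIR_SCHEME) -> np.ndarray:
        return np.array([self.coefficients[p] for p in pairs])


def _session_objective(c: np.ndarray, z: np.ndarray,
                       y_by_angle: list[np.ndarray],
                       targets_norm: list[np.ndarray]) -> np.ndarray:
    """Residuals: elements of normalized reconstruction minus normalized target."""
    res = []
    for y, tn in zip(y_by_angle, targets_norm):
        sol, *_ = np.linalg.lstsq(z, c * y, rcond=None)
        m = 2.0 * sol.reshape(3, 3)
        if abs(m[0, 0]) < 1e-12:
            res.append(np.full(9, 1e6))
            continue
        res.append((m / m[0, 0] - tn).ravel())
    return np.concatenate(res)


def fit_coefficients(session: CalibrationSession, system: SystemMatrix,
                     targets: dict[float, np.ndarray] | None = None,
                     bounds: tuple[float, float] = (0.1, 10.0),
                     f_scale: float = 0.05,
                     max_nfev: int = 10_000) -> CalibrationResult:
    """Regress the nine coupling coefficients against the known targets.

    Minimizes the mean absolute difference between the elements of the
    m11-normalized reconstructed matrix and the m11-normalized target,
    over all session angles, via smoothed-L1 (soft_l1) least squares
    started at c = 1 within ``bounds``.  Requires at least two distinct
    angles; a single angle leaves the nine coefficients underdetermined.
    Deterministic given inputs and options.
    """
    if len(session.angles) < 2:
        raise ValueError(
            "calibration requires >= 2 distinct polariser angles; "
            f"got {session.angles}")
    if targets is None:
        targets = {a: reference_target(a) for a in session.angles}
    targets_norm = []
    y_by_angle = []
    for angle in session.angles:
        t = np.asarray(targets[angle], dtype=float)
        if t[0, 0] <= 0.0:
            raise ValueError(f"target at {angle} deg has non-positive m11")
        targets_norm.append(t / t[0, 0])
        y_by_angle.append(session.measurements[angle].vector(system.pairs))

    fit = least_squares(
        _session_objective, np.ones(9), bounds=bounds,
        loss="soft_l1", f_scale=f_scale,
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev,
        args=(system.z, y_by_angle, targets_norm))

    c = fit.x / np.mean(fit.x)  # gauge: mean(c) = 1; objective is scale-free
    objective = float(np.mean(np.abs(
        _session_objective(c, system.z, y_by_angle, targets_norm))))
    return CalibrationResult(
        coefficients={p: float(ci) for p, ci in zip(system.pairs, c)},
        gauge="mean(c) = 1",
        objective_value=objective,
        converged=bool(fit.status > 0),
        n_evaluations=int(fit.nfev),
    )
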
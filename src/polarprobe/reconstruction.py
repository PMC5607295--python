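"""System-matrix construction and linear Mueller-matrix inversion.

Each of the nine intensity measurements is a bilinear form in the
illumination Stokes triplet and the collection analyzer triplet, so the
nine unknown sample elements m11..m33 (row-major) satisfy a 9x9 linear
system ``y = (1/2) Z m``.  Row i of Z for pair (illuminate, collect) is
the Kronecker product ``kron([I_c, Q_c, -U_c], [I_i, Q_i, U_i])`` of the
channels' normalized exit Stokes parameters; the 1/2 from the analyzer
row is carried instead as the factor 2 in the inversion.  Z depends only
on the channel exit states, so it is fixed once per probe and immune to
fibre bending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .probe import PAIR_CHANNELS, PAIR_SCHEME, MeasurementSet, ProbeModel

__all__ = [
    "SystemMatrix",
    "ReconstructionResult",
    "build_system_matrix",
    "reconstruct",
    "condition_report",
]

#: Column ordering of the system matrix (frozen, row-major sample elements).
COLUMN_ORDER: tuple[str, ...] = (
    "m11", "m12", "m13", "m21", "m22", "m23", "m31", "m32", "m33")

#: Default condition-number threshold above which reconstruction warns.
CONDITION_WARN_THRESHOLD = 1e6


@dataclass(frozen=True)
class SystemMatrix:
    """The 9x9 system matrix Z with conditioning diagnostics.

    Rows follow the fixed nine-pair scheme; columns follow
    ``COLUMN_ORDER``.  Entries lie in [-1, 1] for normalized exit states.
    """

    z: np.ndarray
    pairs: tuple[str, ...] = PAIR_SCHEME

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.shape != (len(self.pairs), 9):
            raise ValueError(f"system matrix must be {len(self.pairs)}x9")
        object.__setattr__(self, "z", z)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.z))


@dataclass(frozen=True)
class ReconstructionResult:
    """Solved sample matrix on its raw scale and normalized by m11."""

    m: np.ndarray
    m_normalized: np.ndarray
    residual: float


def build_system_matrix(probe: ProbeModel) -> SystemMatrix:
    """Assemble Z from the probe's measured channel exit Stokes triplets."""
    rows = []
    for pair in PAIR_SCHEME:
        illum_label, collect_label = PAIR_CHANNELS[pair]
        s_i = probe.channels[illum_label].exit_stokes
        es_c = probe.channels[collect_label].exit_stokes
        a_c = np.array([es_c[0], es_c[1], -es_c[2]])  # collection U sign flip
        rows.append(np.kron(a_c, s_i))
    return SystemMatrix(np.array(rows))


def _coefficient_vector(coefficients, pairs: tuple[str, ...]) -> np.ndarray:
    if coefficients is None:
        return np.ones(len(pairs))
    if hasattr(coefficients, "coefficients"):  # CalibrationResult
        coefficients = coefficients.coefficients
    if isinstance(coefficients, dict):
        missing = set(pairs) - set(coefficients)
        if missing:
            raise ValueError(f"missing calibration coefficient(s): {sorted(missing)}")
        return np.array([float(coefficients[p]) for p in pairs])
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (len(pairs),):
        raise ValueError(f"expected {len(pairs)} coefficients, got shape {c.shape}")
    return c


def reconstruct(meas: MeasurementSet, system: SystemMatrix,
                coefficients=None, warn: bool = True) -> ReconstructionResult:
    """Solve ``m = 2 Z^+ (c o y)`` for the sample's nine Mueller elements.

    A least-squares solve is used rather than an explicit inverse so
    redundant (>9-row) schemes would work unchanged; for a well-posed
    9x9 system it coincides with the inverse.  ``coefficients`` may be a
    CalibrationResult, a pair->value mapping, a length-9 array, or None
    (unit coefficients).
    """
    y = meas.vector(system.pairs)
    c = _coefficient_vector(coefficients, system.pairs)
    rhs = c * y
    rank = np.linalg.matrix_rank(system.z)
    if rank < 9:
        raise np.linalg.LinAlgError(
            f"system matrix is singular (rank {rank} < 9)")
    cond = system.condition_number
    if warn and (not np.isfinite(cond) or cond > CONDITION_WARN_THRESHOLD):
        import warnings
        warnings.warn(
            f"system matrix is ill-conditioned (cond = {cond:.3g}); "
            "reconstruction may be unreliable", stacklevel=2)
    sol, *_ = np.linalg.lstsq(system.z, rhs, rcond=None)
    m = 2.0 * sol.reshape(3, 3)
    residual = float(np.linalg.norm(system.z @ sol - rhs))
    if abs(m[0, 0]) > 0.0:
        m_normalized = m / m[0, 0]
    else:
        m_normalized = m.copy()
    return ReconstructionResult(m=m, m_normalized=m_normalized,
                                residual=residual)


def condition_report(system: SystemMatrix,
                     warn_threshold: float = CONDITION_WARN_THRESHOLD) -> dict:
    """Conditioning diagnostics: condition number, spectrum, warning flag."""
    sv = np.linalg.svd(system.z, compute_uv=False)
    smin = sv[-1]
    cond = float(sv[0] / smin) if smin > 0.0 else float("inf")
    rank = int(np.sum(sv > sv[0] * max(system.z.shape) * np.finfo(float).eps))
    return {
        "condition_number": cond,
        "singular_values": sv,
        "rank": rank,
        "warn": bool(not np.isfinite(cond) or cond > warn_threshold),
        "warn_threshold": float(warn_threshold),
    }
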
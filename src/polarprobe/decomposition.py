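"""Polar decomposition of a 3x3 linear Mueller matrix.

Factorization order is ``M = M_Delta . M_R . M_D`` (diattenuator first,
then retarder, then depolariser), in the Lu-Chipman lineage restricted
to the linear (I, Q, U) subspace:

* ``M_D`` is built from the first row: diattenuation vector
  ``(m12, m13) / m11``, 2x2 part ``sqrt(1 - d^2) I + (1 - sqrt(1 - d^2))
  Dhat Dhat^T``.
* ``M' = (M / m11) . M_D^{-1}`` then carries the retarder and
  depolariser.  Its first column below 1 is the polarizance, which is
  assigned to the depolariser factor.
* The 2x2 block ``N = M'[1:, 1:]`` is separated as ``N = D . B`` with
  ``D = diag(a, b)`` the depolariser block and
  ``B = cos(delta) I + (1 - cos(delta)) n n^T`` (``n = (cos 2 theta,
  sin 2 theta)``) the linear truncation of a retarder of axis ``theta``
  and retardance ``delta``.  This is a four-unknown/four-equation system
  with a closed-form solution, exact for every matrix actually of that
  form; for matrices outside the model class a direct trace-formula
  fallback (``delta = arccos(sqrt((n11+n22)^2 + (n21-n12)^2) - 1)``,
  axis from ``atan2(n12+n21, n11-n22)/4``) is used and the depolariser
  absorbs the residual.

The 3x3 formalism cannot distinguish an axis from its 90-deg rotation
(a 0-deg and a 90-deg quarter-wave plate share the same linear block),
so the reported axis lives in [0, 90) and every result carries an
ambiguity flag.

In reflection geometry the measured retardance mixes the physical
retardance with a geometrical contribution from the helicity flip: for a
retarder with fast or slow axis vertical (or horizontal),
``delta_phys = 180 - delta_meas``.  The rule is not extrapolated to
oblique axes; results flag whether it applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecompositionResult",
    "diattenuation",
    "retarder_block",
    "physical_retardance",
    "depolarisation_percent",
    "polar_decompose",
]

#: |cos delta| below which the retarder block is treated as singular.
_SINGULAR_RETARDER_TOL = 1e-8
#: arccos-argument clamping beyond this magnitude triggers a warning.
_CLAMP_WARN = 1e-6


def diattenuation(m: np.ndarray) -> float:
    """Linear diattenuation ``sqrt(m12^2 + m13^2) / m11`` of a 3x3 matrix."""
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    if m[0, 0] <= 0.0:
        raise ValueError("diattenuation requires m11 > 0")
    return float(np.hypot(m[0, 1], m[0, 2]) / m[0, 0])


def retarder_block(axis_deg: float, delta_deg: float) -> np.ndarray:
    """Linear 3x3 block of an ideal retarder (axis ``theta``, retardance ``delta``).

    ``[[1, 0, 0], [0, c^2 + s^2 cd, sc (1 - cd)], [0, sc (1 - cd),
    s^2 + c^2 cd]]`` with ``c = cos 2 theta``, ``s = sin 2 theta``,
    ``cd = cos delta``.  Axes ``theta`` and ``theta + 90`` give the same
    block (the n -> -n degeneracy of the linear truncation).
    """
    th = np.deg2rad(axis_deg)
    d = np.deg2rad(delta_deg)
    c, s = np.cos(2 * th), np.sin(2 * th)
    cd = np.cos(d)
    return np.array([
        [1.0, 0.0, 0.0],
        [0.0, c * c + s * s * cd, s * c * (1.0 - cd)],
        [0.0, s * c * (1.0 - cd), s * s + c * c * cd],
    ])


def physical_retardance(delta_meas_deg: float) -> float:
    """Reflection-geometry correction ``delta_phys = 180 - delta_meas``.

    Valid for retarders whose fast or slow axis is vertical or
    horizontal (the probe's stretched-tissue geometry); for oblique axes
    the measured value mixes physical and geometric retardance and this
    rule is not applicable.
    """
    if not 0.0 <= delta_meas_deg <= 180.0:
        raise ValueError(
            f"measured retardance must lie in [0, 180] deg, got {delta_meas_deg}")
    return 180.0 - delta_meas_deg


def depolarisation_percent(m_delta: np.ndarray) -> float:
    """Net depolarisation (%) of a depolariser factor.

    ``100 (1 - (|l1| + |l2|) / 2)`` with ``l`` the eigenvalues of the
    lower-right 2x2 block.  Absolute values tolerate the sign structure
    of reflection-mode matrices.
    """
    m_delta = np.asarray(m_delta, dtype=float)
    if m_delta.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m_delta.shape}")
    if np.max(np.abs(m_delta[0] - np.array([1.0, 0.0, 0.0]))) > 1e-6:
        raise ValueError(
            "malformed depolariser factor: first row must be [1, 0, 0]")
    eig = np.linalg.eigvals(m_delta[1:, 1:])
    return float(100.0 * (1.0 - np.mean(np.abs(eig))))


@dataclass(frozen=True)
class DecompositionResult:
    """Retardance, depolarisation, diattenuation and the factor matrices.

    ``m_delta @ m_r @ m_d`` reproduces the m11-normalized input exactly
    up to ``residual``.  ``axis_deg`` lives in [0, 90) and is ambiguous
    modulo 90 (``axis_ambiguous`` is always True for 3x3 data);
    ``delta_phys_deg = 180 - delta_meas_deg`` applies only when
    ``delta_phys_applicable`` (axis near horizontal/vertical).
    """

    delta_meas_deg: float
    delta_phys_deg: float
    axis_deg: float
    depolarisation_pct: float
    diattenuation: float
    polarizance: np.ndarray
    m_d: np.ndarray
    m_delta: np.ndarray
    m_r: np.ndarray
    residual: float
    method: str
    axis_ambiguous: bool = True
    delta_phys_applicable: bool = True


def _retarder_2x2(axis_deg: float, delta_deg: float) -> np.ndarray:
    return retarder_block(axis_deg, delta_deg)[1:, 1:]


def _candidate(n: np.ndarray, theta: float, delta: float,
               a: float, b: float) -> tuple[float, tuple]:
    resid = float(np.linalg.norm(
        np.diag([a, b]) @ _retarder_2x2(theta, delta) - n))
    return resid, (theta, delta, a, b)


def _solve_diag_times_retarder(n: np.ndarray) -> list[tuple[float, tuple]]:
    """All valid (theta, delta, a, b) with ``diag(a, b) . B(theta, delta) = n``.

    Closed form: with ``t = 1 - cos delta``, ``p = s^2 t``, ``q = c^2 t``
    and ``u = s c t``, the off-diagonal ratios ``alpha = n12/n11``,
    ``beta = n21/n22`` give ``u = alpha (1 - p) = beta (1 - q)`` and
    ``u^2 = p q``, a quadratic in u.  Returns candidates sorted by
    reconstruction residual (empty when the model does not fit).
    """
    scale = max(np.max(np.abs(n)), 1e-300)
    off_tol = 1e-11 * scale
    cands: list[tuple[float, tuple]] = []

    if abs(n[0, 1]) <= off_tol and abs(n[1, 0]) <= off_tol:
        # Diagonal block: retarder axis on a cardinal/diagonal direction.
        n1, n2 = n[0, 0], n[1, 1]
        if n1 >= -off_tol and n2 >= -off_tol:
            # no sign flip => interpret as a pure depolariser (delta = 0)
            cands.append(_candidate(n, 0.0, 0.0, max(n1, 0.0), max(n2, 0.0)))
        elif n1 > 0.0 > n2:
            # cos(delta) < 0 along the second axis => retarder axis at 0/90;
            # the split between b and cos(delta) is not identifiable, so the
            # depolariser is taken isotropic: D = n1 * I.
            cd = np.clip(n2 / n1, -1.0, 1.0)
            cands.append(_candidate(
                n, 0.0, float(np.rad2deg(np.arccos(cd))), n1, n1))
        elif n2 > 0.0 > n1:
            cd = np.clip(n1 / n2, -1.0, 1.0)
            cands.append(_candidate(
                n, 45.0, float(np.rad2deg(np.arccos(cd))), n2, n2))
        return sorted(cands, key=lambda c: c[0])

    if abs(n[0, 0]) <= off_tol or abs(n[1, 1]) <= off_tol:
        return []  # ratios undefined; caller falls back to direct formulas

    alpha = n[0, 1] / n[0, 0]
    beta = n[1, 0] / n[1, 1]
    # u^2 (alpha beta - 1) + u (alpha + beta) - alpha beta = 0
    qa = alpha * beta - 1.0
    qb = alpha + beta
    qc = -alpha * beta
    if abs(qa) < 1e-14:
        roots = [-qc / qb] if abs(qb) > 1e-14 else []
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0.0:
            return []
        sq = np.sqrt(disc)
        roots = [(-qb + sq) / (2.0 * qa), (-qb - sq) / (2.0 * qa)]

    for u in roots:
        p = 1.0 - u / alpha
        q = 1.0 - u / beta
        t = p + q
        if p < -1e-10 or q < -1e-10 or not -1e-10 <= t <= 2.0 + 1e-10:
            continue
        p, q = max(p, 0.0), max(q, 0.0)
        t = p + q
        if t <= 1e-14:
            continue  # delta ~ 0 handled by the diagonal branch
        cd = np.clip(1.0 - t, -1.0, 1.0)
        s2t = np.sqrt(p / t)            # |sin 2 theta|
        c2t = np.sign(u) * np.sqrt(q / t)
        theta = float(np.rad2deg(0.5 * np.arctan2(s2t, c2t)))
        denom_a, denom_b = 1.0 - p, 1.0 - q
        if abs(denom_a) < 1e-12 or abs(denom_b) < 1e-12:
            continue
        a = n[0, 0] / denom_a
        b = n[1, 1] / denom_b
        if a <= 0.0 or b <= 0.0:
            continue
        delta = float(np.rad2deg(np.arccos(cd)))
        cands.append(_candidate(n, theta, delta, a, b))
    return sorted(cands, key=lambda c: c[0])


def _clamped_arccos(x: float) -> float:
    if abs(x) > 1.0 + _CLAMP_WARN:
        warnings.warn(
            f"arccos argument {x:.6g} clamped to [-1, 1]; the matrix is "
            "outside the decomposable class (noise?)", stacklevel=3)
    return float(np.rad2deg(np.arccos(np.clip(x, -1.0, 1.0))))


def polar_decompose(m: np.ndarray) -> DecompositionResult:
    """Factor a 3x3 linear Mueller matrix into ``M_Delta . M_R . M_D``.

    Requires ``m11 > 0`` and diattenuation < 1.  Exactly recovers the
    generating parameters (retardance, axis modulo 90 deg, depolariser
    factors, diattenuation) of any matrix composed from those factors;
    other matrices are handled by the direct trace-formula fallback with
    the mismatch absorbed into the depolariser factor.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix contains non-finite entries")
    if m[0, 0] <= 0.0:
        raise ValueError("decomposition requires m11 > 0")
    mn = m / m[0, 0]

    # --- diattenuator from the first row
    dvec = mn[0, 1:]
    d = float(np.linalg.norm(dvec))
    if d >= 1.0:
        raise ValueError(f"diattenuation {d:.6g} >= 1: matrix not decomposable")
    if d > 1e-14:
        dhat = dvec / d
        rt = np.sqrt(1.0 - d * d)
        md = np.eye(3)
        md[0, 1:] = dvec
        md[1:, 0] = dvec
        md[1:, 1:] = rt * np.eye(2) + (1.0 - rt) * np.outer(dhat, dhat)
        mp = mn @ np.linalg.inv(md)
    else:
        md = np.eye(3)
        mp = mn.copy()

    polarizance = mp[1:, 0].copy()
    n = mp[1:, 1:]

    # --- separate depolariser and retarder
    cands = _solve_diag_times_retarder(n)
    exact = bool(cands) and cands[0][0] <= 1e-8 * max(1.0, np.max(np.abs(n)))
    if exact:
        _, (theta, delta_meas, a, b) = cands[0]
        m_delta = np.eye(3)
        m_delta[1:, 0] = polarizance
        m_delta[1, 1] = a
        m_delta[2, 2] = b
        m_r = retarder_block(theta, delta_meas)
        method = "parametric"
    else:
        # Direct trace formulas; the depolariser absorbs whatever remains.
        delta_meas = _clamped_arccos(
            np.hypot(n[0, 0] + n[1, 1], n[1, 0] - n[0, 1]) - 1.0)
        theta = float(np.rad2deg(
            0.25 * np.arctan2(n[0, 1] + n[1, 0], n[0, 0] - n[1, 1])))
        m_r = retarder_block(theta, delta_meas)
        br = m_r[1:, 1:]
        if abs(np.cos(np.deg2rad(delta_meas))) < _SINGULAR_RETARDER_TOL:
            block = n @ np.linalg.pinv(br)
            block = 0.5 * (block + block.T)  # symmetrize the singular case
        else:
            block = n @ np.linalg.inv(br)
        m_delta = np.eye(3)
        m_delta[1:, 0] = polarizance
        m_delta[1:, 1:] = block
        method = "direct"

    theta = float(np.mod(theta, 90.0))
    depol = depolarisation_percent(
        np.block([[np.ones((1, 1)), np.zeros((1, 2))],
                  [np.zeros((2, 1)), m_delta[1:, 1:]]]))
    residual = float(np.linalg.norm(m_delta @ m_r @ md - mn))

    # 180 - delta rule applies for fast/slow axis horizontal or vertical
    axis_off_cardinal = min(theta, 90.0 - theta)
    return DecompositionResult(
        delta_meas_deg=float(delta_meas),
        delta_phys_deg=physical_retardance(float(delta_meas)),
        axis_deg=theta,
        depolarisation_pct=depol,
        diattenuation=d,
        polarizance=polarizance,
        m_d=md,
        m_delta=m_delta,
        m_r=m_r,
        residual=residual,
        method=method,
        axis_ambiguous=True,
        delta_phys_applicable=bool(axis_off_cardinal <= 5.0),
    )
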
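"""Stokes/Mueller algebra for linear polarimetry in reflection geometry.

Conventions
-----------
* Angles are in degrees, measured from the horizontal lab axis, positive
  counter-clockwise as seen facing the oncoming beam.  Polariser and
  retarder axes are canonicalized to ``[0, 180)``; the probe's B channels
  sit nominally at 135 deg (displayed as "-45 deg").
* A Stokes vector is a length-4 float array ``[I, Q, U, V]``.  The linear
  analysis only ever consumes the first three components, but every
  optical element is composed in the *full* 4x4 Mueller calculus before
  the 3x3 linear (I, Q, U) block is extracted.  Composing 3x3 blocks
  pass-by-pass is wrong for retarders: the linear block of a retarder is
  not orthogonal, so chaining blocks yields cos^2(delta) terms where the
  true double-pass element is cos(2*delta).
* Reflection off the mirror is handled exclusively by the helicity-flip
  matrix ``diag(1, 1, -1, -1)`` together with the theta -> 180 - theta
  rule for elements traversed on the return pass.  No other implicit
  frame flips exist anywhere in the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "canonical_axis",
    "stokes_linear_state",
    "degree_of_polarisation",
    "linear_polariser",
    "linear_retarder",
    "mirror",
    "rotator",
    "double_pass",
    "linear_submatrix",
    "embed_linear",
    "apply_mueller",
    "rotate_sample_frame",
]


def canonical_axis(theta_deg: float) -> float:
    """Canonicalize an element axis to the half-open interval [0, 180) degrees.

    A linear polariser or retarder axis is only defined modulo 180 deg.
    """
    return float(np.mod(theta_deg, 180.0))


def stokes_linear_state(theta_deg: float, dop: float = 1.0,
                        intensity: float = 1.0) -> np.ndarray:
    """Stokes vector of a partially linearly polarised beam.

    Parameters
    ----------
    theta_deg
        Azimuth of the polarised component, degrees from horizontal.
    dop
        Degree of polarisation in [0, 1]; the unpolarised remainder
        carries no Q/U/V.
    intensity
        Total beam intensity (I component), arbitrary units >= 0.

    Returns
    -------
    ndarray, shape (4,)
        ``intensity * [1, dop*cos(2 theta), dop*sin(2 theta), 0]``.
    """
    if not 0.0 <= dop <= 1.0:
        raise ValueError(f"degree of polarisation must be in [0, 1], got {dop}")
    if intensity < 0.0:
        raise ValueError(f"intensity must be >= 0, got {intensity}")
    th = np.deg2rad(theta_deg)
    return intensity * np.array([1.0, dop * np.cos(2 * th),
                                 dop * np.sin(2 * th), 0.0])


def degree_of_polarisation(s: np.ndarray) -> float:
    """DOP = sqrt(Q^2 + U^2 + V^2) / I of a 4-component Stokes vector.

    For a 3-component (linear) vector the V term is taken as zero.
    """
    s = np.asarray(s, dtype=float)
    if s[0] <= 0.0:
        raise ValueError("DOP undefined for non-positive intensity")
    return float(np.linalg.norm(s[1:]) / s[0])


def linear_polariser(theta_deg: float) -> np.ndarray:
    """Ideal linear polariser, unit maximum transmittance.

    Unpolarised light is transmitted at 1/2; the V row/column is zero
    (an ideal linear polariser fully extinguishes circular structure).
    """
    th = np.deg2rad(canonical_axis(theta_deg))
    c, s = np.cos(2 * th), np.sin(2 * th)
    m = 0.5 * np.array([
        [1.0, c,     s,     0.0],
        [c,   c * c, c * s, 0.0],
        [s,   c * s, s * s, 0.0],
        [0.0, 0.0,   0.0,   0.0],
    ])
    return m


def linear_retarder(theta_deg: float, delta_deg: float) -> np.ndarray:
    """Ideal non-absorbing linear retarder: fast axis ``theta``, retardance ``delta``.

    The lower-right 3x3 (Q, U, V) block is a proper rotation (orthogonal,
    det +1); m11 = 1.
    """
    th = np.deg2rad(canonical_axis(theta_deg))
    d = np.deg2rad(delta_deg)
    c, s = np.cos(2 * th), np.sin(2 * th)
    cd, sd = np.cos(d), np.sin(d)
    return np.array([
        [1.0, 0.0,                  0.0,                  0.0],
        [0.0, c * c + s * s * cd,   s * c * (1.0 - cd),   -s * sd],
        [0.0, s * c * (1.0 - cd),   s * s + c * c * cd,   c * sd],
        [0.0, s * sd,               -c * sd,              cd],
    ])


def mirror() -> np.ndarray:
    """Ideal front-surface mirror at normal incidence: ``diag(1, 1, -1, -1)``.

    The sign flips on U and V encode the helicity reversal when the
    propagation direction reverses; Q is referenced to the unchanged
    horizontal/vertical axes.
    """
    return np.diag([1.0, 1.0, -1.0, -1.0])


def rotator(phi_deg: float) -> np.ndarray:
    """Optical rotation of the polarisation plane by ``phi`` (4x4)."""
    ph = np.deg2rad(phi_deg)
    c, s = np.cos(2 * ph), np.sin(2 * ph)
    return np.array([
        [1.0, 0.0, 0.0, 0.0],
        [0.0, c,   -s,  0.0],
        [0.0, s,   c,   0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])


def double_pass(element_kind: str, theta_deg: float,
                delta_deg: float | None = None) -> np.ndarray:
    """Element -> mirror -> element round trip, composed fully in 4x4.

    On the return pass the element's axis is seen at ``180 - theta``
    because the light's reference frame flips at the mirror, so the
    product is ``M(180 - theta) . M_mirror . M(theta)``.

    Parameters
    ----------
    element_kind
        ``"polariser"`` or ``"retarder"``.
    theta_deg
        Element axis on the first pass.
    delta_deg
        Retardance; required for a retarder, rejected for a polariser.
    """
    if element_kind == "polariser":
        if delta_deg is not None:
            raise ValueError("delta_deg is meaningless for a polariser")
        first = linear_polariser(theta_deg)
        second = linear_polariser(180.0 - theta_deg)
    elif element_kind == "retarder":
        if delta_deg is None:
            raise ValueError("delta_deg is required for a retarder")
        first = linear_retarder(theta_deg, delta_deg)
        second = linear_retarder(180.0 - theta_deg, delta_deg)
    else:
        raise ValueError(f"unknown element kind {element_kind!r}")
    return second @ mirror() @ first


def linear_submatrix(m: np.ndarray) -> np.ndarray:
    """Upper-left 3x3 (I, Q, U) block of a 4x4 Mueller matrix."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"expected a 4x4 Mueller matrix, got shape {m.shape}")
    return m[:3, :3].copy()


def embed_linear(m3: np.ndarray) -> np.ndarray:
    """Embed a 3x3 linear block into 4x4 with a zero-filled V row/column."""
    m3 = np.asarray(m3, dtype=float)
    if m3.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m3.shape}")
    out = np.zeros((4, 4))
    out[:3, :3] = m3
    return out


def apply_mueller(m: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Apply a Mueller matrix to a Stokes vector (dimensions must agree)."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] not in (3, 4):
        raise ValueError(f"expected a 3x3 or 4x4 matrix, got shape {m.shape}")
    if s.shape != (m.shape[0],):
        raise ValueError(
            f"Stokes vector of length {s.shape} does not match {m.shape} matrix")
    return m @ s


def rotate_sample_frame(m3: np.ndarray, phi_deg: float) -> np.ndarray:
    """Conjugate a 3x3 linear Mueller matrix by a frame rotation ``phi``.

    Rotating the sample by ``phi`` shifts every element axis by ``phi``:
    a retarder at ``theta`` becomes a retarder at ``theta + phi``.
    """
    m3 = np.asarray(m3, dtype=float)
    if m3.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m3.shape}")
    ph = np.deg2rad(phi_deg)
    c, s = np.cos(2 * ph), np.sin(2 * ph)
    r = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    return r @ m3 @ r.T
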
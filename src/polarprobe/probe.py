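"""Virtual six-fibre probe: channels, analyzer rows, forward model, geometry.

The probe carries six multimode fibres, each terminated by a distal
micro-polariser: two horizontal (H1, H2), two vertical (V1, V2) and two
at -45 deg (B1, B2).  Nine illuminate/collect pairs determine the linear
3x3 Mueller matrix of whatever sits in front of the probe.  Because the
polarisers sit at the distal tip, fibre bending perturbs only intensity
coupling, never the polarisation states — the per-pair coupling gains in
:class:`ProbeModel` are exactly the quantities the calibration module
later estimates (as their reciprocals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mueller import (
    canonical_axis,
    double_pass,
    linear_polariser,
    linear_retarder,
    linear_submatrix,
    mirror,
    stokes_linear_state,
)

__all__ = [
    "PAIR_SCHEME",
    "PAIR_CHANNELS",
    "CHANNEL_LABELS",
    "NOMINAL_ANGLES",
    "Channel",
    "ProbeGeometry",
    "NoiseModel",
    "ProbeModel",
    "MeasurementSet",
    "build_probe",
    "analyzer_row",
    "simulate_intensity",
    "simulate_measurement_set",
    "footprint",
    "TissueSample",
    "make_synthetic_tissue",
]

#: The fixed nine-pair measurement scheme: first label illuminates, second
#: collects.  Redundant pairs (H2V1, ...) are representable through
#: :func:`simulate_intensity` but excluded from this default scheme.
PAIR_SCHEME: tuple[str, ...] = (
    "H1H2", "H1V2", "H1B1",
    "V2H1", "V2V1", "V2B1",
    "B1H1", "B1V2", "B1B2",
)

PAIR_CHANNELS: dict[str, tuple[str, str]] = {
    p: (p[:2], p[2:]) for p in PAIR_SCHEME
}

CHANNEL_LABELS: tuple[str, ...] = ("H1", "H2", "V1", "V2", "B1", "B2")

#: Nominal micro-polariser orientations; B channels are stored at 135 deg
#: (the canonical alias of -45 deg).
NOMINAL_ANGLES: dict[str, float] = {
    "H1": 0.0, "H2": 0.0, "V1": 90.0, "V2": 90.0, "B1": 135.0, "B2": 135.0,
}


@dataclass(frozen=True)
class Channel:
    """One probe fibre: its micro-polariser axis and normalized exit state.

    ``exit_stokes`` is the linear Stokes triplet ``[1, Q, U]`` of light
    emanating from the channel into free space, normalized to unit
    intensity.  For an ideal channel it equals ``[1, cos 2a, sin 2a]``
    with DOP exactly 1 regardless of the source's partial polarisation.
    """

    label: str
    polariser_angle: float
    exit_stokes: np.ndarray

    def __post_init__(self) -> None:
        es = np.asarray(self.exit_stokes, dtype=float)
        if es.shape != (3,):
            raise ValueError(f"exit_stokes must have 3 components, got {es.shape}")
        if abs(es[0] - 1.0) > 1e-9:
            raise ValueError("exit_stokes must be normalized to I = 1")
        if es[1] ** 2 + es[2] ** 2 > 1.0 + 1e-9:
            raise ValueError("exit_stokes implies DOP > 1")
        object.__setattr__(self, "exit_stokes", es)
        object.__setattr__(self, "polariser_angle",
                           canonical_axis(self.polariser_angle))

    @property
    def display_angle(self) -> str:
        """Human-facing axis label; 135 deg is shown as its -45 deg alias."""
        if abs(self.polariser_angle - 135.0) < 1e-9:
            return "-45.0"
        return f"{self.polariser_angle:g}"


@dataclass(frozen=True)
class ProbeGeometry:
    """First-order distal geometry used by :func:`footprint`.

    Defaults describe 400-um-core fibres of NA 0.39 on a ring with
    900 um centre-to-centre spacing between neighbouring channels
    (400 um core plus ~500 um of printed holder wall), working into air.
    """

    core_um: float = 400.0
    na: float = 0.39
    pitch_um: float = 900.0
    medium_ri: float = 1.0


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: multiplicative Gaussian plus a constant dark floor.

    ``cv`` is the relative standard deviation of the multiplicative term
    (coefficient of variation); ``dark`` is an additive offset in the
    same arbitrary units as the intensities.  Results are clamped at 0.
    """

    cv: float = 0.0
    dark: float = 0.0

    def apply(self, value: float, rng: np.random.Generator) -> float:
        noisy = value * (1.0 + self.cv * rng.standard_normal()) + self.dark
        return max(0.0, float(noisy))


@dataclass(frozen=True)
class ProbeModel:
    """Complete virtual probe description.

    ``couplings`` holds the true per-pair intensity gains g (unknown to
    the reconstruction; calibration estimates coefficients c ~ 1/g up to
    a global scale).  ``source_dop``/``source_axis_deg`` describe the
    residual partial polarisation of the seed laser, which modulates the
    exit intensity of each channel depending on its polariser axis.
    """

    channels: dict[str, Channel]
    source_dop: float = 0.15
    source_axis_deg: float = 0.0
    couplings: dict[str, float] = field(
        default_factory=lambda: {p: 1.0 for p in PAIR_SCHEME})
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)

    def __post_init__(self) -> None:
        missing = [l for l in CHANNEL_LABELS if l not in self.channels]
        if missing:
            raise ValueError(f"missing channel(s): {missing}")
        if set(self.couplings) != set(PAIR_SCHEME):
            raise ValueError(
                "couplings must cover exactly the nine-pair scheme, got "
                f"{sorted(self.couplings)}")
        for pair, g in self.couplings.items():
            if g <= 0.0:
                raise ValueError(f"coupling for {pair} must be > 0, got {g}")
        if not 0.0 <= self.source_dop <= 1.0:
            raise ValueError("source_dop must lie in [0, 1]")

    @classmethod
    def ideal(cls, source_dop: float = 0.15, source_axis_deg: float = 0.0,
              couplings: dict[str, float] | None = None,
              geometry: ProbeGeometry | None = None) -> "ProbeModel":
        """Probe with exactly cardinal micro-polarisers and ideal exit states."""
        channels = {
            label: Channel(label, angle, _ideal_exit_stokes(angle))
            for label, angle in NOMINAL_ANGLES.items()
        }
        return cls(
            channels=channels,
            source_dop=source_dop,
            source_axis_deg=source_axis_deg,
            couplings=dict(couplings) if couplings is not None
            else {p: 1.0 for p in PAIR_SCHEME},
            geometry=geometry if geometry is not None else ProbeGeometry(),
        )

    def source_weight(self, label: str) -> float:
        """Relative exit intensity of a channel given the partly polarised source.

        A channel whose polariser is aligned with the source's residual
        polarisation transmits more light than a crossed one; for a
        source of DOP p at axis a_s and a polariser at axis a the weight
        is ``1 + p cos 2(a - a_s)`` — normalized to 1 for an unpolarised
        source, and pure intensity modulation: the exit *polarisation*
        stays that of the polariser.
        """
        ch = self.channels[label]
        src = stokes_linear_state(self.source_axis_deg, self.source_dop)
        out = linear_polariser(ch.polariser_angle) @ src
        return float(2.0 * out[0])

    def effective_gain(self, pair: str) -> float:
        """Total forward-model gain of a pair: coupling times source weight."""
        illum, _ = PAIR_CHANNELS[pair]
        return self.couplings[pair] * self.source_weight(illum)

    def with_couplings(self, couplings: dict[str, float]) -> "ProbeModel":
        return replace(self, couplings=dict(couplings))


def _ideal_exit_stokes(angle_deg: float) -> np.ndarray:
    th = np.deg2rad(angle_deg)
    return np.array([1.0, np.cos(2 * th), np.sin(2 * th)])


def build_probe(config: dict) -> ProbeModel:
    """Build a :class:`ProbeModel` from a plain configuration mapping.

    Expected keys: ``channels`` (mapping label -> {polariser_angle_deg,
    optional exit_stokes}), optional ``source`` {dop, axis_deg}, optional
    ``gains`` ({pairs: {...}} or {fibres: {...}}; per-fibre gains are
    expanded to pairs by products), optional ``geometry``.  Unknown keys
    are rejected.
    """
    known = {"channels", "source", "gains", "geometry", "seed"}
    unknown = set(config) - known
    if unknown:
        raise ValueError(f"unknown probe config key(s): {sorted(unknown)}")

    chan_cfg = config.get("channels")
    if chan_cfg is None:
        raise ValueError("probe config requires a 'channels' section")
    channels: dict[str, Channel] = {}
    for label in CHANNEL_LABELS:
        if label not in chan_cfg:
            raise ValueError(f"missing channel {label!r} in config")
        entry = dict(chan_cfg[label])
        unknown = set(entry) - {"polariser_angle_deg", "exit_stokes"}
        if unknown:
            raise ValueError(
                f"unknown key(s) {sorted(unknown)} for channel {label}")
        angle = float(entry.get("polariser_angle_deg", NOMINAL_ANGLES[label]))
        if "exit_stokes" in entry:
            es = np.asarray(entry["exit_stokes"], dtype=float)
            if es.shape != (3,):
                raise ValueError(f"exit_stokes of {label} must have 3 entries")
            if es[0] <= 0.0:
                raise ValueError(
                    f"exit_stokes of {label} has non-positive intensity")
            es = es / es[0]
        else:
            es = _ideal_exit_stokes(angle)
        channels[label] = Channel(label, angle, es)

    source = dict(config.get("source", {}))
    unknown = set(source) - {"dop", "axis_deg"}
    if unknown:
        raise ValueError(f"unknown source key(s): {sorted(unknown)}")
    dop = float(source.get("dop", 0.15))
    axis = float(source.get("axis_deg", 0.0))

    gains_cfg = dict(config.get("gains", {}))
    unknown = set(gains_cfg) - {"pairs", "fibres"}
    if unknown:
        raise ValueError(f"unknown gains key(s): {sorted(unknown)}")
    if "pairs" in gains_cfg and "fibres" in gains_cfg:
        raise ValueError("give gains per pair or per fibre, not both")
    if "pairs" in gains_cfg:
        couplings = {p: float(g) for p, g in gains_cfg["pairs"].items()}
        if set(couplings) != set(PAIR_SCHEME):
            raise ValueError("per-pair gains must cover the nine-pair scheme")
    elif "fibres" in gains_cfg:
        per_fibre = {l: float(g) for l, g in gains_cfg["fibres"].items()}
        if set(per_fibre) != set(CHANNEL_LABELS):
            raise ValueError("per-fibre gains must cover all six channels")
        couplings = {
            p: per_fibre[PAIR_CHANNELS[p][0]] * per_fibre[PAIR_CHANNELS[p][1]]
            for p in PAIR_SCHEME
        }
    else:
        couplings = {p: 1.0 for p in PAIR_SCHEME}

    geom_cfg = dict(config.get("geometry", {}))
    unknown = set(geom_cfg) - {"core_um", "na", "pitch_um", "medium_ri"}
    if unknown:
        raise ValueError(f"unknown geometry key(s): {sorted(unknown)}")
    geometry = ProbeGeometry(**{k: float(v) for k, v in geom_cfg.items()})

    return ProbeModel(channels=channels, source_dop=dop, source_axis_deg=axis,
                      couplings=couplings, geometry=geometry)


def analyzer_row(ch: Channel) -> np.ndarray:
    """Collection-side analyzer triplet ``(1/2)[1, Q, -U]``.

    The exit Stokes vector of a channel is measured for light emanating
    *out* of the probe; for light travelling *into* the channel the U
    reference sense is reversed (the axis appears at 180 - theta in the
    frame of the travelling light), hence the sign flip on U.
    """
    es = ch.exit_stokes
    return 0.5 * np.array([es[0], es[1], -es[2]])


@dataclass(frozen=True)
class MeasurementSet:
    """The nine pair-labelled intensities of one probe acquisition."""

    intensities: dict[str, float]
    noise: NoiseModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if set(self.intensities) != set(PAIR_SCHEME):
            missing = sorted(set(PAIR_SCHEME) - set(self.intensities))
            extra = sorted(set(self.intensities) - set(PAIR_SCHEME))
            raise ValueError(
                f"measurement set must contain each of the 9 pairs exactly "
                f"once (missing {missing}, unexpected {extra})")
        for pair, v in self.intensities.items():
            if v < 0.0:
                raise ValueError(f"negative intensity for {pair}: {v}")

    def vector(self, pairs: tuple[str, ...] = PAIR_SCHEME) -> np.ndarray:
        return np.array([self.intensities[p] for p in pairs])

    def scaled(self, factors: dict[str, float]) -> "MeasurementSet":
        """Per-pair rescaled copy (factors default to 1 where absent)."""
        return MeasurementSet({
            p: v * factors.get(p, 1.0) for p, v in self.intensities.items()
        })


def simulate_intensity(illum: Channel, collect: Channel, sample: np.ndarray,
                       gain: float = 1.0, noise: NoiseModel | None = None,
                       rng: np.random.Generator | None = None) -> float:
    """Detected intensity for one illuminate/collect pair.

    ``sample`` is the 3x3 linear block of a physically (4x4) composed
    sample.  The collection fibre itself never alters the total detected
    intensity, so the full chain reduces to
    ``gain * a_collect . M_sample . s_illum`` with ``a_collect`` the
    analyzer row; negative model values are clamped to zero.
    """
    if gain < 0.0:
        raise ValueError(f"gain must be >= 0, got {gain}")
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (3, 3):
        raise ValueError(f"sample must be a 3x3 linear block, got {sample.shape}")
    value = float(analyzer_row(collect) @ sample @ illum.exit_stokes) * gain
    value = max(0.0, value)
    if noise is not None:
        if rng is None:
            raise ValueError("a seeded Generator is required when noise is on")
        value = noise.apply(value, rng)
    return value


def simulate_measurement_set(probe: ProbeModel, sample: np.ndarray,
                             noise: NoiseModel | None = None,
                             seed: int | None = None) -> MeasurementSet:
    """Run the nine-pair scheme over a sample with the probe's true gains.

    The effective gain of each pair is the per-pair coupling times the
    illumination channel's source weight (partial source polarisation
    modulates exit intensity only).  Deterministic for a fixed seed.
    """
    rng = None
    if noise is not None:
        if seed is None:
            raise ValueError("an explicit seed is required when noise is on")
        rng = np.random.default_rng(seed)
    intensities = {}
    for pair in PAIR_SCHEME:
        illum_label, collect_label = PAIR_CHANNELS[pair]
        intensities[pair] = simulate_intensity(
            probe.channels[illum_label], probe.channels[collect_label],
            sample, gain=probe.effective_gain(pair), noise=noise, rng=rng)
    return MeasurementSet(intensities, noise=noise, seed=seed)


# --- distal footprint geometry -------------------------------------------

# Fixed first-order layout: channels evenly spaced on a ring so that
# neighbouring fibres sit one pitch apart (centre-to-centre).
_RING_ORDER = ("H1", "V2", "B1", "H2", "V1", "B2")


def _circle_overlap_fraction(separation: float, diameter: float) -> float:
    """Intersection area of two equal circles over single-circle area."""
    r = diameter / 2.0
    if r <= 0.0:
        return 1.0 if separation == 0.0 else 0.0
    d = separation
    if d >= 2.0 * r:
        return 0.0
    if d <= 0.0:
        return 1.0
    lens = 2.0 * r * r * np.arccos(d / (2.0 * r)) - 0.5 * d * np.sqrt(
        4.0 * r * r - d * d)
    return float(lens / (np.pi * r * r))


def footprint(working_distance_mm: float,
              geometry: ProbeGeometry) -> dict:
    """Surface illumination/collection spots versus working distance.

    First-order cone spread from the fibre NA: the spot diameter grows as
    ``core + 2 d tan(asin(NA / n_medium))`` and the overlap between the
    spots of each measurement pair is the circle-circle intersection
    fraction at that pair's centre separation on the ring layout.
    Volumetric scattering in tissue spreads light beyond these surface
    contours, so real overlaps are somewhat greater.
    """
    if working_distance_mm < 0.0:
        raise ValueError("working distance must be >= 0")
    ratio = geometry.na / geometry.medium_ri
    if not 0.0 < ratio <= 1.0:
        raise ValueError("NA / medium_ri must lie in (0, 1]")
    half_angle = np.arcsin(ratio)
    core_mm = geometry.core_um / 1000.0
    spot = core_mm + 2.0 * working_distance_mm * np.tan(half_angle)

    # ring circumradius giving nearest-neighbour spacing = pitch
    n = len(_RING_ORDER)
    pitch_mm = geometry.pitch_um / 1000.0
    circumradius = pitch_mm / (2.0 * np.sin(np.pi / n))
    pos = {
        label: circumradius * np.array([np.cos(2 * np.pi * k / n),
                                        np.sin(2 * np.pi * k / n)])
        for k, label in enumerate(_RING_ORDER)
    }
    overlaps = {}
    for pair in PAIR_SCHEME:
        a, b = PAIR_CHANNELS[pair]
        sep = float(np.linalg.norm(pos[a] - pos[b]))
        overlaps[pair] = _circle_overlap_fraction(sep, spot)
    return {
        "spot_diameter_mm": float(spot),
        "half_angle_deg": float(np.rad2deg(half_angle)),
        "pairwise_overlap_fraction": overlaps,
    }


# --- tissue-like synthetic samples ---------------------------------------

@dataclass(frozen=True)
class TissueSample:
    """A synthetic tissue-like 3x3 sample with its generating parameters.

    Composed in 4x4 as depolariser . retarder . diattenuator (the
    retarder is a mirror double pass when ``reflection`` is set, in which
    case ``delta_deg`` is the *physical* round-trip retardance), then
    truncated to the linear block.  The recorded parameters are the
    ground truth for decomposition-recovery tests.
    """

    matrix: np.ndarray
    delta_deg: float
    axis_deg: float
    depol_factors: tuple[float, float]
    diatten: float
    diatten_axis_deg: float
    reflection: bool


def _depolariser4(a: float, b: float) -> np.ndarray:
    return np.diag([1.0, a, b, min(a, b)])


def _diattenuator4(d: float, axis_deg: float) -> np.ndarray:
    rt = np.sqrt(1.0 - d * d)
    base = np.array([
        [1.0, d,   0.0, 0.0],
        [d,   1.0, 0.0, 0.0],
        [0.0, 0.0, rt,  0.0],
        [0.0, 0.0, 0.0, rt],
    ])
    th = np.deg2rad(axis_deg)
    c, s = np.cos(2 * th), np.sin(2 * th)
    r = np.array([
        [1.0, 0.0, 0.0, 0.0],
        [0.0, c,   -s,  0.0],
        [0.0, s,   c,   0.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    return r @ base @ r.T


def make_synthetic_tissue(delta_deg: float | None = None,
                          axis_deg: float | None = None,
                          depol_factors: tuple[float, float] | None = None,
                          diatten: float = 0.0,
                          diatten_axis_deg: float = 0.0,
                          reflection: bool = False,
                          seed: int | None = None) -> TissueSample:
    """Tissue-like sample: weak diattenuator, linear retarder, depolariser.

    Parameters left as ``None`` are drawn from tissue-plausible ranges
    (retardance 10-170 deg, any axis, depolariser factors 0.3-1) using
    ``seed``; explicitly given parameters are honoured as-is.
    """
    if any(v is None for v in (delta_deg, axis_deg, depol_factors)):
        if seed is None:
            raise ValueError("seed is required when drawing random parameters")
        rng = np.random.default_rng(seed)
        if delta_deg is None:
            delta_deg = float(rng.uniform(10.0, 170.0))
        if axis_deg is None:
            axis_deg = float(rng.uniform(0.0, 180.0))
        if depol_factors is None:
            depol_factors = (float(rng.uniform(0.3, 1.0)),
                             float(rng.uniform(0.3, 1.0)))
    a, b = depol_factors
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError(f"depolariser factors must lie in [0, 1], got {depol_factors}")
    if not 0.0 <= diatten < 1.0:
        raise ValueError(f"diattenuation must lie in [0, 1), got {diatten}")
    if delta_deg < 0.0:
        raise ValueError("retardance must be >= 0")

    if reflection:
        ret = double_pass("retarder", axis_deg, delta_deg / 2.0)
    else:
        ret = linear_retarder(axis_deg, delta_deg)
    m4 = _depolariser4(a, b) @ ret @ _diattenuator4(diatten, diatten_axis_deg)
    return TissueSample(
        matrix=linear_submatrix(m4),
        delta_deg=float(delta_deg),
        axis_deg=canonical_axis(axis_deg),
        depol_factors=(float(a), float(b)),
        diatten=float(diatten),
        diatten_axis_deg=float(diatten_axis_deg),
        reflection=bool(reflection),
    )
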
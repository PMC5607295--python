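"""File formats: probe configs, measurement/session CSV, result JSON, manifests.

All angles are serialized in degrees; pair labels are the canonical
uppercase keys H1H2 ... B1B2 in the frozen scheme order.  CSV files are
comma-separated UTF-8 with a mandatory header row and dot decimals.
Matrices are stored as row-major nested arrays.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult, CalibrationSession
from .decomposition import DecompositionResult
from .probe import PAIR_SCHEME, MeasurementSet, ProbeModel, build_probe
from .reconstruction import ReconstructionResult, SystemMatrix

__all__ = [
    "load_probe_config",
    "read_measurements",
    "write_measurements",
    "read_calibration_session",
    "write_calibration_session",
    "write_calibration_result",
    "read_calibration_result",
    "write_matrix",
    "read_matrix",
    "write_decomposition",
    "write_system_matrix",
    "RunManifest",
    "write_manifest",
]


def load_probe_config(path: str | Path) -> tuple[ProbeModel, dict]:
    """Read a probe description (YAML or JSON by extension) into a model.

    Returns the model and the raw config mapping (for seeds/manifests).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        config = yaml.safe_load(text)
    elif path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        raise ValueError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(config, dict):
        raise ValueError("probe config must be a mapping")
    return build_probe(config), config


def read_measurements(path: str | Path) -> MeasurementSet:
    """Read a 9-row measurement CSV with header ``pair,intensity``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["pair", "intensity"]:
        raise ValueError(
            f"expected columns ['pair', 'intensity'], got {list(df.columns)}")
    intensities = {str(r.pair): float(r.intensity) for r in df.itertuples()}
    missing = sorted(set(PAIR_SCHEME) - set(intensities))
    if missing:
        raise ValueError(f"measurement file is missing pair(s): {missing}")
    return MeasurementSet(intensities)


def write_measurements(meas: MeasurementSet, path: str | Path) -> None:
    df = pd.DataFrame({
        "pair": list(PAIR_SCHEME),
        "intensity": [meas.intensities[p] for p in PAIR_SCHEME],
    })
    df.to_csv(path, index=False)


def read_calibration_session(path: str | Path) -> CalibrationSession:
    """Read a session CSV with header ``angle_deg,pair,intensity``."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["angle_deg", "pair", "intensity"]:
        raise ValueError(
            "expected columns ['angle_deg', 'pair', 'intensity'], got "
            f"{list(df.columns)}")
    measurements = {}
    for angle, group in df.groupby("angle_deg", sort=True):
        intensities = {str(r.pair): float(r.intensity)
                       for r in group.itertuples()}
        missing = sorted(set(PAIR_SCHEME) - set(intensities))
        if missing:
            raise ValueError(
                f"session at angle {angle} is missing pair(s): {missing}")
        measurements[float(angle)] = MeasurementSet(intensities)
    return CalibrationSession(tuple(measurements), measurements)


def write_calibration_session(session: CalibrationSession,
                              path: str | Path) -> None:
    rows = []
    for angle in session.angles:
        for pair in PAIR_SCHEME:
            rows.append({"angle_deg": angle, "pair": pair,
                         "intensity": session.intensity(angle, pair)})
    pd.DataFrame(rows, columns=["angle_deg", "pair", "intensity"]).to_csv(
        path, index=False)


def write_calibration_result(result: CalibrationResult,
                             path: str | Path) -> None:
    payload = {
        "pair_order": list(PAIR_SCHEME),
        "c": [result.coefficients[p] for p in PAIR_SCHEME],
        "gauge": result.gauge,
        "objective_value": result.objective_value,
        "converged": result.converged,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_calibration_result(path: str | Path) -> CalibrationResult:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    pairs = payload["pair_order"]
    return CalibrationResult(
        coefficients={p: float(c) for p, c in zip(pairs, payload["c"])},
        gauge=payload.get("gauge", "unspecified"),
        objective_value=float(payload.get("objective_value", float("nan"))),
        converged=bool(payload.get("converged", True)),
    )


def write_matrix(result: ReconstructionResult, path: str | Path) -> None:
    """Write both raw and m11-normalized matrices (row-major, m11..m33)."""
    payload = {
        "element_order": "row-major m11..m33",
        "m": result.m.tolist(),
        "m_normalized": result.m_normalized.tolist(),
        "normalized": False,  # "m" carries the raw solver scale
        "residual": result.residual,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def read_matrix(path: str | Path, normalized: bool = False) -> np.ndarray:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    key = "m_normalized" if normalized else "m"
    m = np.asarray(payload[key], dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"matrix in {path} has shape {m.shape}, expected 3x3")
    return m


def write_decomposition(result: DecompositionResult, path: str | Path) -> None:
    payload = {
        "delta_meas_deg": result.delta_meas_deg,
        "delta_phys_deg": result.delta_phys_deg,
        "delta_phys_applicable": result.delta_phys_applicable,
        "axis_deg": result.axis_deg,
        "axis_ambiguous": result.axis_ambiguous,
        "depolarisation_pct": result.depolarisation_pct,
        "diattenuation": result.diattenuation,
        "factors": {
            "m_d": result.m_d.tolist(),
            "m_delta": result.m_delta.tolist(),
            "m_r": result.m_r.tolist(),
        },
        "residual": result.residual,
        "method": result.method,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n",
                          encoding="utf-8")


def write_system_matrix(system: SystemMatrix, path: str | Path) -> None:
    """Z as CSV: pair-label row index, m_ij column headers."""
    df = pd.DataFrame(system.z, index=list(system.pairs),
                      columns=["m11", "m12", "m13", "m21", "m22", "m23",
                               "m31", "m32", "m33"])
    df.to_csv(path, index_label="pair")


@dataclass(frozen=True)
class RunManifest:
    """Provenance of one CLI run; equal inputs imply equal outputs."""

    command: str
    arguments: dict
    seed: int | None
    config_sha256: str | None
    versions: dict
    timestamp: str


def write_manifest(out_path: str | Path, command: str, arguments: dict,
                   seed: int | None,
                   config_path: str | Path | None = None) -> Path:
    """Write ``<out>.manifest.json`` next to a CLI output file."""
    config_hash = None
    if config_path is not None:
        config_hash = hashlib.sha256(
            Path(config_path).read_bytes()).hexdigest()
    from . import __version__
    manifest = RunManifest(
        command=command,
        arguments={k: str(v) for k, v in arguments.items()},
        seed=seed,
        config_sha256=config_hash,
        versions={
            "polarprobe": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    path = Path(str(out_path) + ".manifest.json")
    path.write_text(json.dumps(manifest.__dict__, indent=2) + "\n",
                    encoding="utf-8")
    return path
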
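"""File formats and schema validation for every pipeline interface.

Tabular data travel as CSV, reference distributions and ground truth as
JSON, stimulus protocols as YAML/JSON, image stacks and movies as
multi-page TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .protocol import StimulusProtocol
from .specialization import PresynapticCluster

__all__ = [
    "read_cluster_csv",
    "write_cluster_csv",
    "read_reference_json",
    "write_reference_json",
    "read_protocol",
    "write_protocol",
    "read_stack",
    "write_stack",
    "ValidationReport",
    "validate_io",
]

CLUSTER_COLUMNS = ("cell_id", "eye", "type_label")


def read_cluster_csv(path: str | Path, postsynaptic_id: str | None = None) -> PresynapticCluster:
    df = pd.read_csv(path)
    return PresynapticCluster(postsynaptic_id or Path(path).stem, df)


def write_cluster_csv(cluster: PresynapticCluster, path: str | Path) -> None:
    cluster.cells.to_csv(path, index=False)


def read_reference_json(path: str | Path) -> dict[str, float]:
    with open(path) as fh:
        dist = json.load(fh)
    if not isinstance(dist, dict):
        raise ValueError("reference distribution must be a JSON object {label: prob}")
    return {str(k): float(v) for k, v in dist.items()}


def write_reference_json(dist: dict[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dist, fh, indent=1, sort_keys=True)


def read_protocol(path: str | Path) -> StimulusProtocol:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for key in ("directions", "speeds_um_s"):
        if key in raw:
            raw[key] = tuple(float(v) for v in raw[key])
    return StimulusProtocol(**raw)


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    data = {
        "directions": list(protocol.directions),
        "speeds_um_s": list(protocol.speeds_um_s),
        "spatial_period_um": protocol.spatial_period_um,
        "n_cycles": protocol.n_cycles,
        "interstim_s": protocol.interstim_s,
        "n_trials": protocol.n_trials,
        "eye_axis_offset_deg": protocol.eye_axis_offset_deg,
        "shuffle_order": protocol.shuffle_order,
        "order_seed": protocol.order_seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def read_stack(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)))


def write_stack(arr: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32))


@dataclass
class ValidationReport:
    passed: bool = True
    messages: list[str] = field(default_factory=list)

    def fail(self, msg: str) -> None:
        self.passed = False
        self.messages.append(msg)

    def note(self, msg: str) -> None:
        self.messages.append(msg)


def _validate_cluster_file(path: Path, report: ValidationReport) -> None:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        report.fail(f"{path}: unreadable CSV ({exc})")
        return
    missing = set(CLUSTER_COLUMNS) - set(df.columns)
    if missing:
        report.fail(f"{path}: missing columns {sorted(missing)}")
        return
    for i, eye in df["eye"].items():
        if eye not in ("contra", "ipsi"):
            report.fail(f"{path}: row {i}: eye={eye!r} (must be contra/ipsi)")
    if "eccentricity_deg" in df.columns:
        bad = df.index[(df["eccentricity_deg"] < 0) | (df["eccentricity_deg"] > 115)]
        for i in bad:
            report.fail(f"{path}: row {i}: eccentricity_deg outside [0, 115]")
    if report.passed:
        report.note(f"{path}: cluster table OK ({len(df)} cells)")


def _validate_reference_file(path: Path, report: ValidationReport) -> None:
    try:
        dist = read_reference_json(path)
    except Exception as exc:
        report.fail(f"{path}: unreadable reference JSON ({exc})")
        return
    total = sum(dist.values())
    if any(v < 0 for v in dist.values()):
        report.fail(f"{path}: negative probabilities")
    elif abs(total - 1.0) > 1e-6:
        report.fail(f"{path}: probabilities sum to {total:.6g}, not 1")
    else:
        report.note(f"{path}: reference distribution OK ({len(dist)} types)")


def _validate_tiff_file(path: Path, report: ValidationReport) -> None:
    try:
        arr = read_stack(path)
    except Exception as exc:
        report.fail(f"{path}: unreadable TIFF ({exc})")
        return
    if arr.ndim not in (3, 4):
        report.fail(f"{path}: expected a 3D stack/movie or 4D multi-channel stack, got {arr.ndim}D")
    else:
        report.note(f"{path}: TIFF OK, shape {arr.shape}")


def _validate_protocol_file(path: Path, report: ValidationReport) -> None:
    try:
        read_protocol(path)
    except Exception as exc:
        report.fail(f"{path}: invalid protocol ({exc})")
        return
    report.note(f"{path}: protocol OK")


def validate_io(files: list[str | Path]) -> ValidationReport:
    """Schema checks for every file interface, with row-level messages.

    File kinds are inferred from suffix and name: ``*.csv`` with cluster
    columns → cluster table; ``*.json`` → reference distribution;
    ``*.yaml``/``*.yml`` or names containing ``protocol`` → stimulus
    protocol; ``*.tif``/``*.tiff`` → stack/movie.
    """
    report = ValidationReport()
    for f in files:
        path = Path(f)
        if not path.exists():
            report.fail(f"{path}: file not found")
            continue
        suffix = path.suffix.lower()
        if suffix == ".csv":
            _validate_cluster_file(path, report)
        elif suffix in (".yaml", ".yml") or "protocol" in path.name.lower():
            _validate_protocol_file(path, report)
        elif suffix == ".json":
            _validate_reference_file(path, report)
        elif suffix in (".tif", ".tiff"):
            _validate_tiff_file(path, report)
        else:
            report.fail(f"{path}: unrecognized file kind")
    return report
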
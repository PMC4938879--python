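"""Reading and writing time-activity datasets, physiology configs and fit results.

Datasets are whole-body-scintigraphy (WBS) organ time-activity tables: an
administered activity and a list of ``(time [h], organ, value [Bq])``
observations for the organs segmented on the planar images (liver, kidney,
brain).  Count rate [counts/s] and activity [Bq] are treated as synonymous
here: the clinical tables report normalized count rates in Bq.

Four clinical reference datasets (patients treated with 7400 MBq of
Lu-177 DOTATATE, imaged over 0-120 h) ship as packaged CSV fixtures and are
available through :func:`builtin_dataset`.

File formats are plain text: CSV for datasets (with ``# key: value``
metadata header lines), YAML for physiology, JSON for fit results.  Readers
validate and reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .physiology import PhysiologySpec, default_physiology

__all__ = [
    "WBSDataset",
    "ORGANS",
    "builtin_dataset",
    "read_dataset",
    "write_dataset",
    "read_physiology",
    "write_physiology",
    "write_fit_result",
    "read_fit_result",
    "SchemaError",
]

#: Organs quantified on the whole-body images, with their compartment codes.
ORGANS: dict[str, str] = {"liver": "L", "kidney": "K", "brain": "BR"}

#: Administered activity common to the four clinical datasets [Bq].
ADMINISTERED_ACTIVITY_BQ = 7.4e9

_FIT_SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """A structured file does not match the expected schema/version."""


@dataclass(frozen=True)
class WBSDataset:
    """One patient's organ time-activity observations.

    observations
        Tuples ``(time_h, organ, value_bq)`` with unique (time, organ)
        pairs; organ labels are the long names in :data:`ORGANS`.
    """

    patient_id: str
    a0_bq: float
    observations: tuple[tuple[float, str, float], ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.a0_bq < 0:
            raise ValueError("administered activity must be >= 0")
        seen = set()
        for i, (t, organ, value) in enumerate(self.observations):
            if organ not in ORGANS:
                raise ValueError(
                    f"observation {i}: unknown organ {organ!r} "
                    f"(expected one of {sorted(ORGANS)})"
                )
            if t < 0:
                raise ValueError(f"observation {i}: negative time {t}")
            if value < 0:
                raise ValueError(f"observation {i}: negative value {value}")
            key = (t, organ)
            if key in seen:
                raise ValueError(f"observation {i}: duplicate (time, organ) {key}")
            seen.add(key)

    @property
    def times_h(self) -> np.ndarray:
        """Sorted unique observation times [h]."""
        return np.unique([t for t, _, _ in self.observations])

    def organ_series(self, organ: str) -> tuple[np.ndarray, np.ndarray]:
        """(times_h, values_bq) for one organ, time-sorted."""
        rows = sorted((t, v) for t, o, v in self.observations if o == organ)
        if not rows:
            return np.array([]), np.array([])
        t, v = zip(*rows)
        return np.array(t), np.array(v)

    def nonzero_time_observations(self) -> tuple[tuple[float, str, float], ...]:
        """Observations at t > 0; the t = 0 rows (all zero by construction
        of the imaging protocol) carry no kinetic information."""
        return tuple(obs for obs in self.observations if obs[0] > 0)


def _data_path(name: str):
    return resources.files("radiopbpk").joinpath("data", name)


def builtin_dataset(index: int) -> WBSDataset:
    """Return packaged clinical dataset 1-4 (administered activity 7400 MBq)."""
    if index not in (1, 2, 3, 4):
        raise ValueError(f"builtin dataset index must be 1..4, got {index}")
    with resources.as_file(_data_path(f"dataset{index}.csv")) as path:
        return read_dataset(path)


def read_dataset(path) -> WBSDataset:
    """Parse a dataset CSV (columns time_h, organ, value_bq; ``# key: value``
    metadata lines for patient_id / a0_bq / provenance)."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, str, float]] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            continue
        parts = [p.strip() for p in line.split(",")]
        if not header_seen:
            if parts != ["time_h", "organ", "value_bq"]:
                raise ValueError(
                    f"{path}:{lineno}: expected header "
                    f"'time_h,organ,value_bq', got {line!r}"
                )
            header_seen = True
            continue
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns, got {line!r}")
        try:
            t = float(parts[0])
            v = float(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field: {exc}") from None
        if parts[1] not in ORGANS:
            raise ValueError(f"{path}:{lineno}: unknown organ {parts[1]!r}")
        if v < 0:
            raise ValueError(f"{path}:{lineno}: negative value {v}")
        rows.append((t, parts[1], v))
    if "a0_bq" not in meta:
        raise ValueError(f"{path}: missing '# a0_bq:' metadata line")
    try:
        return WBSDataset(
            patient_id=meta.get("patient_id", path.stem),
            a0_bq=float(meta["a0_bq"]),
            observations=tuple(rows),
            provenance=meta.get("provenance", ""),
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_dataset(ds: WBSDataset, path) -> None:
    """Write a dataset CSV that :func:`read_dataset` round-trips exactly."""
    lines = [
        f"# patient_id: {ds.patient_id}",
        f"# a0_bq: {ds.a0_bq!r}",
    ]
    if ds.provenance:
        lines.append(f"# provenance: {ds.provenance}")
    lines.append("time_h,organ,value_bq")
    for t, organ, v in ds.observations:
        lines.append(f"{t!r},{organ},{v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_physiology(path) -> PhysiologySpec:
    """Load a physiology spec from a flat YAML/JSON document."""
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    try:
        return PhysiologySpec(**doc)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_physiology(spec: PhysiologySpec, path) -> None:
    doc = {
        "organ_masses": dict(spec.organ_masses),
        "flow_fractions": dict(spec.flow_fractions),
        "tissue_density": spec.tissue_density,
        "cardiac_output_coeff": spec.cardiac_output_coeff,
        "cardiac_output_exponent": spec.cardiac_output_exponent,
        "body_weight": spec.body_weight,
        "brain_cbv_fraction": spec.brain_cbv_fraction,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def default_physiology_file():
    """Path-like handle on the packaged reference physiology YAML."""
    return _data_path("physiology_default.yaml")


def write_fit_result(result, path) -> None:
    """Serialize a :class:`~radiopbpk.calibration.FitResult` to JSON."""
    doc = {"schema_version": _FIT_SCHEMA_VERSION, **result.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_fit_result(path):
    """Load a fit result JSON written by :func:`write_fit_result`."""
    from .calibration import FitResult

    doc = json.loads(Path(path).read_text())
    version = doc.pop("schema_version", None)
    if version != _FIT_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: fit-result schema version {version!r}, "
            f"expected {_FIT_SCHEMA_VERSION}"
        )
    try:
        return FitResult.from_dict(doc)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: malformed fit result: {exc}") from None
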
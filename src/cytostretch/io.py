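"""Readers/writers for curve CSVs and chip/network configuration files.

Curve files are plain CSV with the fixed column order
``force_N,strain_mean,strain_se,n`` (the last two optional), SI units in
files, and ``#``-prefixed header comments carrying the seed and config
hash needed to regenerate the artifact.  Floats are serialized with 9
significant digits, so write-read round-trips are exact to that
precision and byte-deterministic for fixed input.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .actin_network import NetworkParams, StrainForceCurve
from .electrokinetics import CellDielectric, DielectricMaterial, Drive
from .field_solver import ChipModel, ElectrodeSegment

_COLUMNS = ("force_N", "strain_mean", "strain_se", "n")


class CurveParseError(ValueError):
    """Malformed curve CSV (message carries the offending line number)."""


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_curve(
    curve: StrainForceCurve,
    path: str | Path,
    seed: int | None = None,
    extra_comments: dict | None = None,
) -> None:
    """Write a curve CSV with commented provenance header."""
    path = Path(path)
    meta = {"label": curve.label}
    if seed is not None:
        meta["seed"] = seed
    if extra_comments:
        meta.update(extra_comments)
    lines = [f"# {k}: {v}" for k, v in meta.items() if v != ""]
    lines.append(f"# config_hash: {config_hash(meta)}")
    has_se = curve.strain_se is not None
    has_n = curve.n is not None
    cols = ["force_N", "strain_mean"] + (["strain_se"] if has_se else []) + (
        ["n"] if has_n else []
    )
    lines.append(",".join(cols))
    for i in range(len(curve.force)):
        row = [f"{curve.force[i]:.9g}", f"{curve.strain_mean[i]:.9g}"]
        if has_se:
            row.append(f"{curve.strain_se[i]:.9g}")
        if has_n:
            row.append(str(int(curve.n[i])))
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> StrainForceCurve:
    """Read a curve CSV; validates header, numerics and force ordering."""
    path = Path(path)
    label = ""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if stripped[1:].strip().startswith("label:"):
                label = stripped.split("label:", 1)[1].strip()
            continue
        cells = next(csv.reader([stripped]))
        if header is None:
            header = [c.strip() for c in cells]
            if header[:2] != ["force_N", "strain_mean"] or any(
                c not in _COLUMNS for c in header
            ):
                raise CurveParseError(
                    f"{path}:{lineno}: bad header {header}; expected columns "
                    f"{_COLUMNS} starting with force_N,strain_mean"
                )
            continue
        if len(cells) != len(header):
            raise CurveParseError(
                f"{path}:{lineno}: expected {len(header)} cells, got {len(cells)}"
            )
        rows.append((lineno, cells))
    if header is None or not rows:
        raise CurveParseError(f"{path}: no data rows")

    data: dict[str, list[float]] = {c: [] for c in header}
    for lineno, cells in rows:
        for col, cell in zip(header, cells):
            try:
                data[col].append(float(cell))
            except ValueError as err:
                raise CurveParseError(
                    f"{path}:{lineno}: non-numeric value {cell!r} in column {col}"
                ) from err
    return StrainForceCurve(
        force=np.array(data["force_N"]),
        strain_mean=np.array(data["strain_mean"]),
        strain_se=np.array(data["strain_se"]) if "strain_se" in header else None,
        n=np.array(data["n"], dtype=int) if "n" in header else None,
        label=label,
    )


# ---------------------------------------------------------------------------
# Configuration loading (YAML, which is a superset of JSON)
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level config must be a mapping")
    return cfg


def material_from_config(cfg: dict) -> DielectricMaterial:
    return DielectricMaterial(
        rel_permittivity=float(cfg["rel_permittivity"]),
        conductivity=float(cfg["conductivity_S_per_m"]),
    )


def cell_from_config(cfg: dict) -> CellDielectric:
    kwargs = {}
    if "radius_m" in cfg:
        kwargs["radius"] = float(cfg["radius_m"])
    if "cytoplasm" in cfg:
        kwargs["cytoplasm"] = material_from_config(cfg["cytoplasm"])
    return CellDielectric(**kwargs)


def drive_from_config(cfg: dict) -> Drive:
    return Drive(
        voltage_amplitude=float(cfg["voltage_amplitude_V"]),
        frequency=float(cfg["frequency_Hz"]),
    )


def chip_from_config(cfg: dict) -> ChipModel:
    electrodes = tuple(
        ElectrodeSegment(
            wall=e.get("wall", "bottom"),
            start=float(e["start_m"]),
            end=float(e["end_m"]),
            potential=float(e["potential_V"]),
        )
        for e in cfg.get("electrodes", ())
    )
    kwargs = dict(electrodes=electrodes)
    for key, attr in (
        ("domain_width_m", "domain_width"),
        ("domain_height_m", "domain_height"),
        ("gap_m", "gap"),
        ("grid_spacing_m", "grid_spacing"),
        ("out_of_plane_thickness_m", "out_of_plane_thickness"),
    ):
        if key in cfg:
            kwargs[attr] = float(cfg[key])
    return ChipModel(**kwargs)


def params_from_config(cfg: dict) -> NetworkParams:
    valid = {f.name for f in NetworkParams.__dataclass_fields__.values()}
    unknown = set(cfg) - valid
    if unknown:
        raise ValueError(f"unknown network parameter(s): {sorted(unknown)}")
    typed = {k: (int(v) if k == "N_AF" else float(v)) for k, v in cfg.items()}
    return NetworkParams(**typed)
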
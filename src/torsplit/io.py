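"""File I/O: torsion scans, peak lists, .dpt spectra, reports, configs.

All energies and wavenumbers in output files are cm^-1 (energy understood
via E = h c nu).  Scan files may carry kJ/mol energies with a units flag.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .potential import PeriodicPotential, find_stationary_points, fit_fourier

__all__ = [
    "KJ_PER_MOL_TO_CM1",
    "RunConfig",
    "read_scan",
    "read_peak_list",
    "read_dpt_spectrum",
    "pick_peaks",
    "write_report",
    "write_potential",
    "read_potential_sidecar",
]

#: 1 kJ/mol in cm^-1: 1000 / (N_A h c), CODATA 2018
KJ_PER_MOL_TO_CM1 = 83.59347


@dataclass
class RunConfig:
    """Resolved settings of a CLI run, written next to the outputs."""

    command: str
    inputs: dict = field(default_factory=dict)
    rotor: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    output_dir: str = "."

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        return cls(**yaml.safe_load(Path(path).read_text()))


def _parse_two_columns(path, what="row"):
    """Whitespace- or comma-delimited numeric pairs; '#' starts a comment."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed {what}: {line!r}") from exc
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"{path}:{lineno}: non-finite {what}")
            rows.append((x, y))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def read_scan(path, units: str = "cm-1"):
    """Read a two-column torsional scan (angle deg, energy).

    ``units`` is ``"cm-1"`` or ``"kJ/mol"``; energies are returned in cm^-1.
    """
    rows = _parse_two_columns(path, what="scan point")
    if units in ("cm-1", "cm^-1", "wavenumber"):
        factor = 1.0
    elif units in ("kJ/mol", "kj/mol", "kjmol"):
        factor = KJ_PER_MOL_TO_CM1
    else:
        raise ValueError(f"unknown energy unit {units!r}")
    return [(angle, energy * factor) for angle, energy in rows]


def read_peak_list(path):
    """One wavenumber per line, '#' comments."""
    vals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                vals.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed wavenumber {line!r}") from exc
    if not vals:
        raise ValueError(f"{path}: no peaks")
    return vals


def read_dpt_spectrum(path):
    """Two-column (wavenumber, intensity) spectrum; x need not be monotone."""
    return _parse_two_columns(path, what="spectrum point")


def pick_peaks(spectrum, min_prominence: float = 0.0, n_strongest: int | None = None):
    """Local-maximum peak positions of a (wavenumber, intensity) spectrum.

    Sorts by wavenumber first; returns peak wavenumbers, strongest first.
    """
    from scipy.signal import find_peaks

    arr = np.asarray(spectrum, dtype=float)
    order = np.argsort(arr[:, 0])
    x, y = arr[order, 0], arr[order, 1]
    idx, props = find_peaks(y, prominence=min_prominence or None)
    strength = props.get("prominences", y[idx])
    rank = np.argsort(strength)[::-1]
    peaks = x[idx][rank]
    if n_strongest is not None:
        peaks = peaks[:n_strongest]
    return list(peaks)


def write_report(results: dict, path):
    """Write results as JSON (sorted keys) and a flat CSV alongside.

    Returns the JSON path.  Nested dicts are flattened with dotted keys in
    the CSV; reading the JSON back yields the input dict.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True) + "\n")
    flat = _flatten(results)
    with open(path.with_suffix(".csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["key", "value"])
        for k in sorted(flat):
            writer.writerow([k, flat[k]])
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _flatten(obj, prefix=""):
    out = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}." if prefix or True else k))
    elif isinstance(obj, (list, tuple, np.ndarray)):
        for i, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}{i}."))
    else:
        out[prefix.rstrip(".")] = obj
    return out


def write_potential(pot: PeriodicPotential, path, grid_step: float = 1.0):
    """Two-column (angle, energy) file plus a JSON sidecar.

    The sidecar records the Fourier coefficients and the stationary points
    of the smooth part; overlays are evaluated into the two-column grid.
    """
    path = Path(path)
    grid = np.arange(0.0, 360.0, grid_step)
    vals = pot(grid)
    lines = ["# angle_deg  energy_cm-1"]
    lines += [f"{a:10.4f}  {v:18.10f}" for a, v in zip(grid, vals)]
    path.write_text("\n".join(lines) + "\n")
    try:
        stat = [
            {"angle": p.angle, "energy": p.energy, "kind": p.kind}
            for p in find_stationary_points(pot)
        ]
    except ValueError:
        stat = []
    sidecar = {
        "a0": float(pot.a0),
        "a": list(np.asarray(pot.a, dtype=float)),
        "b": list(np.asarray(pot.b, dtype=float)),
        "stationary_points": stat,
    }
    side_path = path.with_suffix(path.suffix + ".json")
    side_path.write_text(json.dumps(_jsonable(sidecar), indent=2, sort_keys=True) + "\n")
    return path, side_path


def read_potential_sidecar(path) -> PeriodicPotential:
    """Rebuild the smooth Fourier part from a sidecar written above."""
    data = json.loads(Path(path).read_text())
    return PeriodicPotential(
        a0=float(data["a0"]), a=np.asarray(data["a"]), b=np.asarray(data["b"])
    )


def potential_from_scan(path, units: str = "cm-1", order: int = 12) -> PeriodicPotential:
    """Convenience: read a scan file and fit the default-order Fourier series."""
    return fit_fourier(read_scan(path, units=units), order=order)
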
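"""Plain-text I/O: year×age tables, sidecar configs, fit reports, scenarios.

Table format: tab-separated, first header column ``year``, remaining header
cells the integer ages; one row per observation year; missing cells empty or
``NA``. Floats are written with Python's shortest round-trip repr, so a
write/read cycle is bit-exact.

Sidecar config and scenario files are flat ``key = value`` text; fit reports
are JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .cohorts import AgeLengthTable
from .errors import MalformedInputError
from .simulate import EnvironmentalKSeries

_NA = ("", "NA", "na", "NaN", "nan")


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "NA"
    return repr(float(x))


def write_age_length_table(table: AgeLengthTable, path: str | Path) -> None:
    """Write a table as TSV (``year`` + one column per age; NA for missing)."""
    path = Path(path)
    lines = ["year\t" + "\t".join(str(int(a)) for a in table.ages)]
    for i, y in enumerate(table.years):
        cells = [_fmt(v) for v in table.lengths[i]]
        lines.append(str(int(y)) + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def read_age_length_table(
    path: str | Path, unit: str = "mm", abundance_path: str | Path | None = None
) -> AgeLengthTable:
    """Read a TSV year×age table; diagnostics name the offending line/column."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise MalformedInputError(f"{path}: line 1: empty file, expected a header row")
    header = lines[0].split("\t")
    if len(header) < 2 or header[0].strip().lower() != "year":
        raise MalformedInputError(
            f"{path}: line 1: header must be 'year' followed by age columns"
        )
    try:
        ages = np.array([int(h) for h in header[1:]])
    except ValueError as e:
        raise MalformedInputError(f"{path}: line 1: non-integer age column: {e}") from e
    years, rows = [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise MalformedInputError(
                f"{path}: line {lineno}: expected {len(header)} columns, got {len(cells)}"
            )
        try:
            years.append(int(cells[0]))
        except ValueError as e:
            raise MalformedInputError(
                f"{path}: line {lineno}: column 1: non-integer year {cells[0]!r}"
            ) from e
        row = []
        for col, cell in enumerate(cells[1:], start=2):
            cell = cell.strip()
            if cell in _NA:
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError as e:
                raise MalformedInputError(
                    f"{path}: line {lineno}: column {col}: bad length {cell!r}"
                ) from e
        rows.append(row)
    abundance = None
    if abundance_path is not None:
        ab = read_age_length_table(abundance_path, unit=unit)
        abundance = ab.lengths
    try:
        return AgeLengthTable(
            years=np.array(years),
            ages=ages,
            lengths=np.array(rows, dtype=float),
            abundance=abundance,
            unit=unit,
        )
    except Exception as e:
        raise MalformedInputError(f"{path}: {e}") from e


def write_config(config: dict, path: str | Path) -> None:
    """Flat ``key = value`` sidecar file."""
    lines = [f"{k} = {v}" for k, v in config.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise MalformedInputError(
                f"{path}: line {lineno}: expected 'key = value', got {ln!r}"
            )
        k, v = ln.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_k_series(value: str, base_dir: Path | None = None) -> EnvironmentalKSeries:
    """Parse an inline comma list of k values, or a path to one-per-line file."""
    value = value.strip()
    if "," in value or _is_number(value):
        vals = [float(v) for v in value.split(",") if v.strip()]
    else:
        p = Path(value)
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        if not p.exists():
            raise MalformedInputError(f"k series file not found: {p}")
        vals = [float(v) for v in p.read_text().split()]
    return EnvironmentalKSeries(np.array(vals))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved config, for provenance lines."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    """Serialize a fit/simulation report (dataclasses welcome) as JSON."""
    payload = _jsonable(report)
    payload.setdefault("provenance", {})
    payload["provenance"].setdefault("package_version", __version__)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def report_to_json(report: dict) -> str:
    payload = _jsonable(report)
    return json.dumps(payload, indent=2, sort_keys=True)
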
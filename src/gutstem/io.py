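"""Readers and writers for the pipeline's text dialects.

All tables are UTF-8 tab-separated with a header row and '.' decimals;
structured results are JSON.  Spectrum files carry ``# key=value`` header
lines (span_ghz, channels, optional region/animal) before the two-column
channel/counts body.  Readers validate and report the offending line number
instead of silently coercing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .brillouin import N_CHANNELS, SPAN_GHZ, BrillouinSpectrum
from .simulate import SECTION_COLUMNS

__all__ = [
    "read_section_table",
    "write_section_table",
    "read_growth_series",
    "write_growth_series",
    "read_spectrum",
    "write_spectrum",
    "write_cluster_calls",
    "read_cluster_calls",
    "write_estimates",
    "read_estimates",
    "file_digest",
]

_ZONES = {"IFR", "FOLD_LOWER", "FOLD_UPPER", "APEX"}
GROWTH_COLUMNS = ("animal_id", "age_weeks", "measure", "value", "unit")
CLUSTER_COLUMNS = (
    "animal_id",
    "section_id",
    "unit_id",
    "first_index",
    "last_index",
    "span_cell_count",
    "isc_count",
    "double_positive_count",
    "centroid_zone",
)


def write_section_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(SECTION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_section_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} in header (line 1)")
    for col in ("dapi", "brdu", "edu", "pcna"):
        vals = df[col].to_numpy()
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
            raise ValueError(f"{path}: non-binary {col}={vals[bad][0]!r} at line {line}")
    bad = ~df["zone"].isin(_ZONES)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: unknown zone at line {line}")
    nondapi = df["dapi"].to_numpy() != 1
    if nondapi.any():
        line = int(np.flatnonzero(nondapi)[0]) + 2
        raise ValueError(f"{path}: every row must be DAPI-positive (line {line})")
    return df[list(SECTION_COLUMNS)]


def write_growth_series(df: pd.DataFrame, path: str | Path) -> None:
    df[list(GROWTH_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_growth_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} in header (line 1)")
    vals = df["value"].to_numpy(dtype=float)
    bad = ~(vals > 0)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"{path}: non-positive value at line {line}")
    ages = df["age_weeks"].to_numpy(dtype=float)
    if (ages < 0).any():
        line = int(np.flatnonzero(ages < 0)[0]) + 2
        raise ValueError(f"{path}: negative age at line {line}")
    return df[list(GROWTH_COLUMNS)]


def write_spectrum(spectrum: BrillouinSpectrum, path: str | Path) -> None:
    lines = [f"# span_ghz={spectrum.span_ghz:g}", f"# channels={spectrum.counts.size}"]
    if spectrum.region:
        lines.append(f"# region={spectrum.region}")
    if spectrum.animal_id:
        lines.append(f"# animal_id={spectrum.animal_id}")
    lines.append("channel_index\tcounts")
    lines += [f"{i}\t{c:g}" for i, c in enumerate(spectrum.counts)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> BrillouinSpectrum:
    meta: dict[str, str] = {}
    rows: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
                continue
            if line.startswith("channel_index"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: expected 2 columns at line {lineno}")
            try:
                idx, cnt = int(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed row at line {lineno}") from exc
            if idx != len(rows):
                raise ValueError(f"{path}: non-contiguous channel index at line {lineno}")
            rows.append(cnt)
    n = int(meta.get("channels", N_CHANNELS))
    if len(rows) != n:
        raise ValueError(f"{path}: expected {n} channels, found {len(rows)}")
    return BrillouinSpectrum(
        np.asarray(rows),
        span_ghz=float(meta.get("span_ghz", SPAN_GHZ)),
        region=meta.get("region"),
        animal_id=meta.get("animal_id"),
    )


def write_cluster_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls[list(CLUSTER_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_cluster_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLUSTER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)} in header (line 1)")
    return df[list(CLUSTER_COLUMNS)]


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_estimates(estimates, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(estimates), indent=2, sort_keys=True) + "\n")


def read_estimates(path: str | Path):
    return json.loads(Path(path).read_text())


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
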
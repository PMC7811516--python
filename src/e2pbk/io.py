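"""CSV and config round-tripping for time courses and observed series.

Observed-series files are plain `time_h,value` CSV with the series metadata
(endpoint, dose, label, optionally route/infusion duration) carried in
`# key: value` header comments, so a file is self-describing:

    # endpoint: blood
    # dose_ng_per_kg: 81.0
    # label: morikawa_blood
    time_h,value
    0.125,0.00153
    ...

Simulated time courses export as `time_h,blood_umol_per_L,bile_pct_dose`.
Numeric output is written at 6 significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import ObservedSeries
from .model import TimeCourse
from .params import ParameterError

__all__ = [
    "read_observed_csv",
    "write_observed_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "load_config",
]

_FMT = "%.6g"


class ParseError(ValueError):
    """Malformed observed-series or time-course file."""


def write_observed_csv(series: ObservedSeries, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# endpoint: {series.endpoint}",
        f"# dose_ng_per_kg: {series.dose:.6g}",
        f"# label: {series.label}",
        f"# route: {series.route}",
        f"# infusion_duration_h: {series.infusion_duration:.6g}",
        "time_h,value",
    ]
    for t, v in zip(series.times, series.values):
        lines.append(f"{t:.6g},{v:.6g}")
    path.write_text("\n".join(lines) + "\n")


def _read_header_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                k, v = line.lstrip("# ").split(":", 1)
                meta[k.strip()] = v.strip()
    return meta


def read_observed_csv(path: str | Path) -> ObservedSeries:
    """Parse and validate one observed series; errors name the offending row."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    meta = _read_header_meta(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # empty file, bad CSV
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    for col in ("time_h", "value"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")
    times = df["time_h"].to_numpy(float)
    values = df["value"].to_numpy(float)
    bad = np.flatnonzero(np.diff(times) <= 0)
    if bad.size:
        raise ParseError(f"{path}: times not strictly increasing at data row {bad[0] + 2}")
    neg = np.flatnonzero(values < 0)
    if neg.size:
        raise ParseError(f"{path}: negative value at data row {neg[0] + 1}")
    try:
        return ObservedSeries(
            endpoint=meta.get("endpoint", "blood"),
            times=times,
            values=values,
            dose=float(meta.get("dose_ng_per_kg", "0")),
            label=meta.get("label", path.stem),
            route=meta.get("route", "bolus"),
            infusion_duration=float(meta.get("infusion_duration_h", "0")),
        )
    except ParameterError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timecourse_csv(tc: TimeCourse, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_h": tc.times,
            "blood_umol_per_L": tc.blood_conc,
            "bile_pct_dose": tc.cumulative_bile_pct,
        }
    )
    df.to_csv(path, index=False, float_format=_FMT)


def read_timecourse_csv(path: str | Path) -> TimeCourse:
    df = pd.read_csv(path, comment="#")
    for col in ("time_h", "blood_umol_per_L", "bile_pct_dose"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return TimeCourse(
        times=df["time_h"].to_numpy(float),
        blood_conc=df["blood_umol_per_L"].to_numpy(float),
        cumulative_bile_pct=df["bile_pct_dose"].to_numpy(float),
    )


def load_config(path: str | Path) -> dict:
    """Load a nested key/value YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg
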
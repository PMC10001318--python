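"""Plain-text I/O: dense CSV fields with a metadata header, JSON reports.

Field files are row-major dense CSV with one leading metadata line of
the form ``# key=value;key=value;...`` recording grid shape, cell size
and units.  Region masks use an integer coding (0 = out-of-field,
1 = in-beam, 2 = penumbra).  Reports are JSON with sorted keys so a
scenario re-run with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .grid import RegionMasks

__all__ = [
    "write_field_csv",
    "read_field_csv",
    "write_masks_csv",
    "write_report_json",
    "read_report_json",
]


def _format_metadata(metadata: Mapping[str, Any]) -> str:
    return "# " + ";".join(f"{k}={v}" for k, v in metadata.items())


def _parse_value(raw: str) -> Any:
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def write_field_csv(path: str | Path, values: np.ndarray, metadata: Mapping[str, Any]) -> None:
    """Write a per-cell field as dense CSV with a one-line metadata header."""
    meta = dict(metadata)
    meta.setdefault("n_y", values.shape[0])
    meta.setdefault("n_x", values.shape[1])
    np.savetxt(path, values, delimiter=",", fmt="%.10g",
               header=_format_metadata(meta), comments="")


def read_field_csv(path: str | Path) -> tuple[np.ndarray, dict[str, Any]]:
    """Read a dense CSV field, returning (values, metadata)."""
    with open(path) as fh:
        first = fh.readline().strip()
    metadata: dict[str, Any] = {}
    if first.startswith("#"):
        for item in first.lstrip("# ").split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                metadata[k.strip()] = _parse_value(v.strip())
    values = np.loadtxt(path, delimiter=",", skiprows=1 if first.startswith("#") else 0)
    return np.atleast_2d(values), metadata


def write_masks_csv(path: str | Path, masks: RegionMasks, metadata: Mapping[str, Any]) -> None:
    """Write beam-region masks as integer-coded CSV (0=out, 1=beam, 2=penumbra)."""
    coded = np.zeros(masks.in_beam.shape, dtype=np.int64)
    coded[masks.in_beam] = 1
    coded[masks.penumbra] = 2
    meta = dict(metadata)
    meta.setdefault("coding", "0=out,1=beam,2=penumbra")
    np.savetxt(path, coded, delimiter=",", fmt="%d",
               header=_format_metadata(meta), comments="")


def write_report_json(path: str | Path, report: Mapping[str, Any]) -> None:
    """Write a report dict as deterministic (sorted-key) JSON."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report_json(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
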
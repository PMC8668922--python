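"""Plain-text readers and writers for the pipeline's file formats.

Traces travel as CSV (``time_ms,voltage_uV`` for an averaged recording,
``sweep,time_ms,voltage_uV`` for raw sweeps) with a JSON or YAML
metadata sidecar carrying sample rate, pre-stimulus window and stimulus
condition. Visual fields are CSV with ``# key=value`` header lines for
the mean deviation; models, RGC estimates and comparison reports are
JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .rgc import OCTSummary, RGCEstimate, VisualField
from .waveform import ERGTrace, MarkerSet

TRACE_META_DEFAULTS = {"sample_rate": 4000.0, "pre_stimulus_ms": 30.0, "condition": "chromatic"}


def write_trace_csv(trace: ERGTrace, path: str | Path) -> None:
    pd.DataFrame({"time_ms": trace.times_ms, "voltage_uV": trace.samples}).to_csv(
        path, index=False
    )
    _write_sidecar(Path(path), trace)


def write_sweeps_csv(sweeps: Sequence[ERGTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"sweep": i, "time_ms": s.times_ms, "voltage_uV": s.samples}
        )
        for i, s in enumerate(sweeps)
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    _write_sidecar(Path(path), sweeps[0])


def _write_sidecar(csv_path: Path, trace: ERGTrace) -> None:
    meta = {
        "sample_rate": trace.sample_rate,
        "pre_stimulus_ms": trace.pre_stimulus_ms,
        "condition": trace.condition,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def _read_sidecar(csv_path: Path) -> dict:
    for suffix, loader in ((".json", json.loads), (".yaml", yaml.safe_load), (".yml", yaml.safe_load)):
        sidecar = csv_path.with_suffix(suffix)
        if sidecar.exists():
            return {**TRACE_META_DEFAULTS, **loader(sidecar.read_text())}
    return dict(TRACE_META_DEFAULTS)


def read_trace_csv(path: str | Path) -> ERGTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    return ERGTrace(
        df["voltage_uV"].to_numpy(dtype=float),
        sample_rate=meta["sample_rate"],
        pre_stimulus_ms=meta["pre_stimulus_ms"],
        condition=meta["condition"],
    )


def read_sweeps_csv(path: str | Path) -> list[ERGTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    meta = _read_sidecar(path)
    out = []
    for _, grp in df.groupby("sweep", sort=True):
        out.append(
            ERGTrace(
                grp.sort_values("time_ms")["voltage_uV"].to_numpy(dtype=float),
                sample_rate=meta["sample_rate"],
                pre_stimulus_ms=meta["pre_stimulus_ms"],
                condition=meta["condition"],
            )
        )
    return out


def write_visual_field_csv(fieldv: VisualField, path: str | Path,
                           coords: Sequence[tuple[float, float]] | None = None) -> None:
    """Write a field as ``x_deg,y_deg,sensitivity_db`` with an
    ``# md_db=`` header. When the per-location (x, y) are unknown, the
    eccentricity is written into x_deg with y_deg = 0."""
    lines = [f"# md_db={fieldv.md}", "x_deg,y_deg,sensitivity_db"]
    if coords is None:
        coords = [(loc.ec, 0.0) for loc in fieldv.locations]
    for (x, y), loc in zip(coords, fieldv.locations):
        lines.append(f"{x},{y},{loc.s}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_visual_field_csv(path: str | Path) -> VisualField:
    text = Path(path).read_text().splitlines()
    meta = {}
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition("=")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    if "md_db" not in meta:
        raise ValueError(f"{path}: missing '# md_db=' header metadata")
    df = pd.read_csv(Path(path), skiprows=body_start)
    coords = list(zip(df["x_deg"], df["y_deg"]))
    return VisualField.from_grid(
        df["sensitivity_db"].tolist(), md=float(meta["md_db"]), coords=coords
    )


def write_oct_json(oct_summary: OCTSummary, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"mean_rnfl_um": oct_summary.rnfl, "age_years": oct_summary.age}, indent=2)
    )


def read_oct_json(path: str | Path) -> OCTSummary:
    d = json.loads(Path(path).read_text())
    return OCTSummary(rnfl=float(d["mean_rnfl_um"]), age=float(d["age_years"]))


def write_rgc_estimate_json(estimate: RGCEstimate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(estimate.to_dict(), indent=2))


MARKER_TABLE_COLUMNS = [
    "eye_id", "condition",
    "a_uV", "b_uV", "i_uV", "phnr1_uV", "phnr2_uV",
    "a_ms", "b_ms", "i_ms", "phnr1_ms", "phnr2_ms",
]


def marker_row(eye_id: str, markers: MarkerSet) -> dict:
    short = {"a_wave": "a", "b_wave": "b", "i_wave": "i", "phnr1": "phnr1", "phnr2": "phnr2"}
    row = {"eye_id": eye_id, "condition": markers.condition}
    for name, s in short.items():
        row[f"{s}_uV"] = markers[name].amplitude_uV
        row[f"{s}_ms"] = markers[name].time_ms
    return row


def write_marker_table(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(rows, columns=MARKER_TABLE_COLUMNS).to_csv(path, index=False)


def write_model_json(model, path: str | Path, **metadata) -> None:
    payload = model.to_dict()
    payload.update(metadata)
    Path(path).write_text(json.dumps(payload, indent=2))


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
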
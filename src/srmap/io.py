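"""Table, NIfTI and report I/O.

Events are written as a BIDS-events-like tab-delimited table; voxel time
series either as delimited voxel-by-volume tables with a small commented
header or as NIfTI with voxels unrolled on a synthetic grid.  Delimited
round trips are bit-exact; NIfTI round trips are float32-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import SessionDesign, StimulusLayout, SequenceSpec
from .synth import VoxelTimeSeries

EVENT_COLUMNS = ["run", "trial_index", "trial_type", "delayed",
                 "onset_s", "duration_s", "iti_s"]


class ParseError(ValueError):
    pass


def events_frame(design: SessionDesign) -> pd.DataFrame:
    rows = []
    for r, trials in enumerate(design.runs):
        for i, t in enumerate(trials):
            rows.append((r, i, t.trial_type, int(t.delayed),
                         t.onset, t.duration, t.iti))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(design: SessionDesign, path) -> None:
    events_frame(design).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse events table {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: line 1: missing columns {missing}")
    return df


def write_sidecar(path, layout: StimulusLayout, spec: SequenceSpec,
                  tr: float) -> None:
    payload = {
        "radius_dva": layout.radius,
        "polar_angles_deg": list(layout.polar_angles),
        "dot_diameter_dva": layout.dot_diameter,
        "sequence_indices": list(spec.sequence_indices),
        "control_indices": list(spec.control_indices),
        "tr_s": tr,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_series(ts: VoxelTimeSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# roi\t{ts.roi}\n")
        fh.write(f"# tr\t{ts.tr!r}\n")
        fh.write("# run_volumes\t" + ",".join(map(str, ts.run_volumes)) + "\n")
        if ts.preferred_location is not None:
            fh.write("# preferred_location\t"
                     + ",".join(map(str, ts.preferred_location.tolist())) + "\n")
        np.savetxt(fh, ts.values, delimiter="\t", fmt="%.17g")


def read_series(path) -> VoxelTimeSeries:
    meta, data_start = {}, 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            data_start = i
            break
        parts = line[1:].strip().split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: line {i + 1}: malformed header {line!r}")
        meta[parts[0]] = parts[1]
    for key in ("roi", "tr", "run_volumes"):
        if key not in meta:
            raise ParseError(f"{path}: line {data_start}: missing header {key!r}")
    try:
        values = np.loadtxt(lines[data_start:], delimiter="\t", ndmin=2)
    except Exception as exc:
        raise ParseError(
            f"{path}: line {data_start + 1}: cannot parse data ({exc})") from exc
    run_volumes = [int(v) for v in meta["run_volumes"].split(",")]
    if sum(run_volumes) != values.shape[1]:
        raise ParseError(f"{path}: line {data_start + 1}: run volumes "
                         f"{run_volumes} do not match {values.shape[1]} columns")
    pref = None
    if "preferred_location" in meta:
        pref = np.array([int(v) for v in meta["preferred_location"].split(",")])
    return VoxelTimeSeries(values=values, tr=float(meta["tr"]),
                           run_volumes=run_volumes, roi=meta["roi"],
                           preferred_location=pref)


def write_series_nifti(ts: VoxelTimeSeries, path) -> None:
    data = ts.values.astype(np.float32)[:, np.newaxis, np.newaxis, :]
    img = nib.Nifti1Image(data, affine=np.eye(4))
    img.header["pixdim"][4] = ts.tr
    img.header.set_xyzt_units(xyz="mm", t="sec")
    extra = {"roi": ts.roi, "run_volumes": list(map(int, ts.run_volumes))}
    if ts.preferred_location is not None:
        extra["preferred_location"] = [int(v) for v in ts.preferred_location]
    img.header.extensions.append(
        nib.nifti1.Nifti1Extension("comment", json.dumps(extra).encode()))
    nib.save(img, str(path))


def read_series_nifti(path) -> VoxelTimeSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    values = data[:, 0, 0, :].astype(np.float64)
    meta = {"roi": "unknown", "run_volumes": [values.shape[1]]}
    for ext in img.header.extensions:
        try:
            meta.update(json.loads(bytes(ext.get_content()).decode()))
        except (ValueError, TypeError):
            continue
    pref = meta.get("preferred_location")
    return VoxelTimeSeries(
        values=values, tr=float(img.header["pixdim"][4]),
        run_volumes=[int(v) for v in meta["run_volumes"]], roi=meta["roi"],
        preferred_location=None if pref is None else np.asarray(pref, int))


def config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
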
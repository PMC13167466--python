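"""File formats: localization CSV, movie TIFF + metadata sidecar, reports.

Localization CSV dialect (ThunderSTORM-style): header
``frame,x_nm,y_nm,z_nm,sigma_nm,photons,background,uncertainty_nm``;
frames are 1-based on disk (the de-facto SMLM convention) and 0-based in
memory — conversion happens here and nowhere else.  ``z_nm`` is blank for
2D data.  Round-trips are lossless to 1e-3 nm (coordinates are written
with four decimals).  CSV files may carry ``#``-prefixed provenance
header lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .camera import CameraModel
from .errors import SchemaError
from .simulate import FrameStack, TitrationCurve

__all__ = ["read_localizations", "write_localizations", "read_movie",
           "write_movie", "write_events", "read_titration",
           "write_titration", "write_json_report", "config_hash"]

CSV_COLUMNS = ["frame", "x_nm", "y_nm", "z_nm", "sigma_nm", "photons",
               "background", "uncertainty_nm"]
MANDATORY = ["frame", "x_nm", "y_nm"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _provenance_lines(meta: dict | None) -> str:
    head = {"generator": f"blinkkit {__version__}"}
    if meta:
        head.update(meta)
    return "".join(f"# {k}: {v}\n" for k, v in head.items())


def write_localizations(path, table: pd.DataFrame,
                        meta: dict | None = None) -> None:
    """Write a localization table (frames converted to 1-based on disk)."""
    out = pd.DataFrame()
    out["frame"] = table["frame"].astype(int) + 1
    for col in CSV_COLUMNS[1:]:
        out[col] = table[col] if col in table else np.nan
    sidecar = dict(meta or {})
    for key in ("pixel_nm", "cycle_s"):
        if key in table.attrs:
            sidecar[key] = table.attrs[key]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_provenance_lines(sidecar))
        out.to_csv(fh, index=False, float_format="%.4f")


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV (frames converted to 0-based in memory)."""
    df = pd.read_csv(path, comment="#")
    for col in MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    out = pd.DataFrame()
    out["frame"] = df["frame"].astype(int) - 1
    for col in CSV_COLUMNS[1:]:
        out[col] = df[col] if col in df.columns else np.nan
    out["fit_ok"] = True
    # recover metadata from provenance header if present
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].partition(":")
            k = k.strip()
            if k in ("pixel_nm", "cycle_s"):
                out.attrs[k] = float(v)
    return out


def write_movie(path, stack: FrameStack, meta: dict | None = None) -> None:
    """Write a movie as 16-bit unsigned multi-frame TIFF + JSON sidecar."""
    path = Path(path)
    data = np.clip(np.rint(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    cam = stack.camera
    sidecar = {
        "generator": f"blinkkit {__version__}",
        "pixel_size_nm": cam.pixel_size, "exposure_s": cam.exposure,
        "cycle_s": cam.cycle, "em_gain": cam.em_gain,
        "quantum_efficiency": cam.quantum_efficiency,
        "read_noise_e": cam.read_noise, "offset_adu": cam.offset,
        "conversion_adu_per_e": cam.conversion,
        "n_frames": stack.n_frames,
    }
    sidecar.update(meta or {})
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str))


def read_movie(path) -> FrameStack:
    """Read a multi-frame TIFF with its JSON metadata sidecar."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    side = path.with_suffix(path.suffix + ".json")
    if not side.exists():
        raise SchemaError(f"missing metadata sidecar {side}")
    meta = json.loads(side.read_text())
    try:
        cam = CameraModel(
            pixel_size=meta["pixel_size_nm"], exposure=meta["exposure_s"],
            cycle=meta["cycle_s"], em_gain=meta.get("em_gain", 1.0),
            quantum_efficiency=meta.get("quantum_efficiency", 0.9),
            read_noise=meta.get("read_noise_e", 0.0),
            offset=meta.get("offset_adu", 0.0),
            conversion=meta.get("conversion_adu_per_e", 1.0))
    except KeyError as exc:
        raise SchemaError(f"metadata sidecar missing key {exc}") from exc
    return FrameStack(data.astype(np.float64), cam)


def write_events(path, groups, cycle: float, meta: dict | None = None):
    """Write on-events as CSV, one row per gap-closed event."""
    rows = []
    for g in groups:
        for eid, ev in enumerate(g.events):
            rows.append((g.id, eid, ev.first_frame + 1, ev.last_frame + 1,
                         ev.n_localizations, ev.photons_total,
                         ev.duration(cycle)))
    df = pd.DataFrame(rows, columns=["molecule_id", "event_id",
                                     "first_frame", "last_frame", "n_locs",
                                     "photons", "duration_s"])
    with open(path, "w") as fh:
        fh.write(_provenance_lines(meta))
        df.to_csv(fh, index=False)


def read_titration(path) -> TitrationCurve:
    """Read a pH-titration CSV with columns ``pH,absorbance``."""
    df = pd.read_csv(path, comment="#")
    cols = {c.lower(): c for c in df.columns}
    if "ph" not in cols or "absorbance" not in cols:
        raise SchemaError("titration CSV needs columns pH, absorbance")
    return TitrationCurve(df[cols["ph"]].to_numpy(float),
                          df[cols["absorbance"]].to_numpy(float))


def write_titration(path, curve: TitrationCurve,
                    meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(meta))
        pd.DataFrame({"pH": curve.ph, "absorbance": curve.absorbance}
                     ).to_csv(fh, index=False, float_format="%.6g")


def write_json_report(path, payload: dict, config: dict | None = None):
    """Write a machine-readable result with provenance fields."""
    doc = {"generator": f"blinkkit {__version__}"}
    if config is not None:
        doc["config_hash"] = config_hash(config)
    doc.update(payload)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True,
                                     default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
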
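"""Trial container and file I/O for motion-capture formats.

Supported on-disk formats are TRC and wide CSV (plain text) and, when the
optional ``ezc3d`` package is installed, C3D point data.  Positions are
kept in millimetres in a y-up lab frame; z-up sources are rotated on read.
Gaps are explicit NaNs.
"""

from __future__ import annotations

import csv as _csv
import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from .errors import AfmError
from .model import MarkerSet, canonical_marker_name, load_marker_aliases

_ZUP_TO_YUP = np.array([[1.0, 0.0, 0.0],
                        [0.0, 0.0, 1.0],
                        [0.0, -1.0, 0.0]])

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


@dataclasses.dataclass
class Trial:
    """Rectangular marker-trajectory block: ``data[frame, marker, xyz]`` in
    mm at a fixed sampling rate, y-up lab frame.  Gaps are NaN."""

    labels: List[str]
    data: np.ndarray
    rate: float
    meta: Dict[str, object] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("trial data must have shape (n_frames, n_markers, 3)")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("label count does not match data")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != len(self.labels):
            raise ValueError("duplicate marker labels in trial")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def has_marker(self, name: str) -> bool:
        return name in self._index

    def positions(self, name: str) -> np.ndarray:
        """(n_frames, 3) trajectory of one marker."""
        try:
            return self.data[:, self._index[name], :]
        except KeyError:
            from .errors import MissingMarkerError
            raise MissingMarkerError(name) from None

    def marker_set(self, frame: int) -> MarkerSet:
        """Markers visible at one frame (NaN markers are dropped)."""
        row = self.data[frame]
        return MarkerSet({
            lab: row[i] for lab, i in self._index.items()
            if np.all(np.isfinite(row[i]))
        })

    def mean_marker_set(self, frames: Sequence[int] | None = None) -> MarkerSet:
        """Markers averaged over frames; frames with a gap in a marker are
        excluded for that marker only."""
        block = self.data if frames is None else self.data[list(frames)]
        out = {}
        for lab, i in self._index.items():
            traj = block[:, i, :]
            ok = np.all(np.isfinite(traj), axis=1)
            if np.any(ok):
                out[lab] = traj[ok].mean(axis=0)
        return MarkerSet(out)

    def canonicalized(self) -> "Trial":
        """Copy with lab labels mapped to model marker names where
        possible; unmapped labels are preserved unchanged."""
        aliases = load_marker_aliases()["aliases"]
        new = []
        seen = set()
        for lab in self.labels:
            canon = canonical_marker_name(lab, aliases)
            name = canon if canon is not None and canon not in seen else lab
            seen.add(name)
            new.append(name)
        return Trial(new, self.data.copy(), self.rate, dict(self.meta))


def read_trial(path, fmt: str | None = None, *, vertical_axis: str | None = None,
               units: str | None = None, rate: float | None = None,
               canonicalize: bool = True) -> Trial:
    """Read a trial from TRC, wide CSV, or C3D.

    ``vertical_axis`` names the source's up axis ('y' or 'z'); defaults
    are 'y' for TRC/CSV and 'z' for C3D.  ``units`` overrides the file's
    units (required for CSV, which has no unit metadata, unless 'mm' is
    acceptable as a default... it is not: pass units explicitly or rely on
    the 'units' comment row written by :func:`write_trial_csv`).
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lower().lstrip(".")
    if fmt == "trc":
        trial = _read_trc(path, units)
        default_up = "y"
    elif fmt == "csv":
        trial = _read_csv(path, units, rate)
        default_up = "y"
    elif fmt == "c3d":
        trial = _read_c3d(path, units)
        default_up = "z"
    else:
        raise AfmError(f"unknown trial format {fmt!r} (expected trc, csv or c3d)")
    up = (vertical_axis or default_up).lower()
    if up == "z":
        trial.data = trial.data @ _ZUP_TO_YUP.T
    elif up != "y":
        raise AfmError(f"unsupported vertical axis {up!r}")
    return trial.canonicalized() if canonicalize else trial


def _read_trc(path: Path, units: str | None) -> Trial:
    with open(path, newline="") as fh:
        rows = list(_csv.reader(fh, delimiter="\t"))
    if len(rows) < 5:
        raise AfmError(f"{path}: not a TRC file (too short)")
    header_keys = rows[1]
    header_vals = rows[2]
    hdr = dict(zip(header_keys, header_vals))
    rate = float(hdr.get("DataRate", 0))
    file_units = (units or hdr.get("Units", "mm")).lower()
    try:
        scale = _UNIT_TO_MM[file_units]
    except KeyError:
        raise AfmError(f"{path}: ambiguous units {file_units!r}; pass units=") from None
    labels = [lab for lab in rows[3][2:] if lab]
    data_rows = [r for r in rows[4:] if len(r) > 2 and r[0].strip()]
    n = len(data_rows)
    data = np.full((n, len(labels), 3), np.nan)
    for fi, r in enumerate(data_rows):
        vals = r[2:2 + 3 * len(labels)]
        for mi in range(len(labels)):
            trip = vals[3 * mi:3 * mi + 3]
            if len(trip) == 3 and all(v.strip() for v in trip):
                data[fi, mi] = [float(v) for v in trip]
    return Trial(labels, data * scale, rate, {"source": str(path), "format": "trc"})


def write_trial_trc(trial: Trial, path) -> None:
    path = Path(path)
    n, m = trial.n_frames, len(trial.labels)
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh, delimiter="\t")
        w.writerow(["PathFileType", "4", "(X/Y/Z)", path.name])
        w.writerow(["DataRate", "CameraRate", "NumFrames", "NumMarkers",
                    "Units", "OrigDataRate", "OrigDataStartFrame", "OrigNumFrames"])
        w.writerow([trial.rate, trial.rate, n, m, "mm", trial.rate, 1, n])
        head = ["Frame#", "Time"]
        sub = ["", ""]
        for i, lab in enumerate(trial.labels, start=1):
            head += [lab, "", ""]
            sub += [f"X{i}", f"Y{i}", f"Z{i}"]
        w.writerow(head)
        w.writerow(sub)
        for fi in range(n):
            row = [fi + 1, f"{fi / trial.rate:.6f}"]
            for mi in range(m):
                p = trial.data[fi, mi]
                row += [f"{v:.6f}" for v in p] if np.all(np.isfinite(p)) else ["", "", ""]
            w.writerow(row)


def _read_csv(path: Path, units: str | None, rate: float | None) -> Trial:
    with open(path, newline="") as fh:
        rows = list(_csv.reader(fh))
    meta = {}
    while rows and rows[0] and rows[0][0].startswith("#"):
        key, _, val = rows.pop(0)[0].lstrip("# ").partition("=")
        meta[key.strip()] = val.strip()
    if not rows:
        raise AfmError(f"{path}: empty CSV")
    header = rows[0]
    file_units = (units or meta.get("units", "")).lower()
    if file_units not in _UNIT_TO_MM:
        raise AfmError(f"{path}: units unknown; pass units= or add a '# units=mm' row")
    scale = _UNIT_TO_MM[file_units]
    file_rate = rate or (float(meta["rate"]) if "rate" in meta else None)
    labels = []
    cols = {}
    for ci, name in enumerate(header):
        if name.endswith(("_X", "_Y", "_Z")):
            lab, axis = name[:-2], name[-1]
            cols.setdefault(lab, {})[axis] = ci
    labels = [lab for lab, ax in cols.items() if set(ax) == {"X", "Y", "Z"}]
    if not labels:
        raise AfmError(f"{path}: no <name>_X/_Y/_Z marker columns found")
    time_col = next((ci for ci, nm in enumerate(header) if nm.lower() == "time"), None)
    body = [r for r in rows[1:] if any(c.strip() for c in r)]
    n = len(body)
    data = np.full((n, len(labels), 3), np.nan)
    times = []
    for fi, r in enumerate(body):
        if time_col is not None:
            times.append(float(r[time_col]))
        for mi, lab in enumerate(labels):
            try:
                trip = [r[cols[lab][a]] for a in "XYZ"]
            except IndexError:
                continue
            if all(v.strip() for v in trip):
                data[fi, mi] = [float(v) for v in trip]
    if file_rate is None:
        if len(times) >= 2:
            file_rate = 1.0 / float(np.mean(np.diff(times)))
        else:
            raise AfmError(f"{path}: sampling rate unknown; pass rate= or add a Time column")
    return Trial(labels, data * scale, file_rate, {"source": str(path), "format": "csv"})


def write_trial_csv(trial: Trial, path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("# units=mm\n")
        fh.write(f"# rate={trial.rate}\n")
        w = _csv.writer(fh)
        header = ["Frame", "Time"]
        for lab in trial.labels:
            header += [f"{lab}_X", f"{lab}_Y", f"{lab}_Z"]
        w.writerow(header)
        for fi in range(trial.n_frames):
            row = [fi + 1, f"{fi / trial.rate:.6f}"]
            for mi in range(len(trial.labels)):
                p = trial.data[fi, mi]
                row += [f"{v:.6f}" for v in p] if np.all(np.isfinite(p)) else ["", "", ""]
            w.writerow(row)


def _read_c3d(path: Path, units: str | None) -> Trial:
    try:
        import ezc3d
    except ImportError:
        raise AfmError(
            "reading C3D requires the optional 'ezc3d' package "
            "(pip install afmkin[c3d]); TRC and CSV need no extras"
        ) from None
    c3d = ezc3d.c3d(str(path))
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = [l.strip() for l in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    file_units = units
    if file_units is None:
        u = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
        file_units = (u[0] if u else "mm").lower()
    scale = _UNIT_TO_MM.get(file_units)
    if scale is None:
        raise AfmError(f"{path}: ambiguous units {file_units!r}; pass units=")
    data = np.transpose(pts[:3], (2, 1, 0)) * scale
    return Trial(labels, data, rate, {"source": str(path), "format": "c3d"})


# ---------------------------------------------------------------------------
# result serialization

def write_curves_csv(curves, path) -> None:
    """Angle curves as long-format CSV: joint, plane, stride, axis value
    (% gait cycle or seconds), angle in degrees."""
    with open(path, "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["joint", "plane", "stride", "axis", "value_deg"])
        for c in curves:
            stride = getattr(c, "stride", "")
            axis = c.pct_axis() if c.normalized else c.time_axis()
            for x, v in zip(axis, c.values):
                w.writerow([c.joint, c.plane, stride, f"{x:.6g}",
                            "" if not np.isfinite(v) else f"{v:.6f}"])


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_json(obj, path, **meta) -> None:
    """Serialize a result object (dict or dataclass with ``to_dict``) as
    JSON with model-version metadata."""
    from . import __version__
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    doc = {"model_version": __version__, **meta, "payload": obj}
    with open(path, "w") as fh:
        json.dump(doc, fh, cls=_NumpyEncoder, indent=1)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
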
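"""Marker-trajectory and force-plate file handling.

Markers travel in a TRC-dialect tab-separated file (self-describing rate and
units), forces in one plain CSV per plate (``time_s, Fx_N, Fy_N, COPx_m``
with Fx the anterior shear and Fy the vertical component), and subject
metadata in YAML.  Every downstream module consumes the in-memory
:class:`TrialRecording`; nothing else re-parses files.

Conventions: x anterior, y vertical up, z mediolateral; sample indices are
0-based with t = index / rate; intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.interpolate import CubicSpline

from .model import SubjectSpec

#: the planar marker set every DVJ trial must provide (dominant = right side).
REQUIRED_MARKERS = (
    "R_TOE", "R_HEEL", "R_ANK", "R_KNEE", "R_HIP",
    "RASI", "LASI", "RPSI", "LPSI",
)

PELVIS_MARKERS = ("RASI", "LASI", "RPSI", "LPSI")

MAX_GAP_FRAMES = 10


class TrialIOError(ValueError):
    """Malformed or inconsistent trial files."""


@dataclass
class TrialRecording:
    """Synchronized marker and force streams for one trial.

    markers: label -> (n_frames, 3) positions in metres at ``rate_kin`` Hz.
    plates:  plate id -> (n_samples, 3) array of (Fx N, Fy N, COPx m) at
    ``rate_force`` Hz.  Both streams share t = 0 at index 0.
    """

    markers: dict
    plates: dict
    subject: SubjectSpec
    rate_kin: float
    rate_force: float
    trial_kind: str = "dvj"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def n_force_samples(self) -> int:
        return next(iter(self.plates.values())).shape[0]

    @property
    def rate_ratio(self) -> int:
        return int(round(self.rate_force / self.rate_kin))

    def validate(self):
        if not self.markers:
            raise TrialIOError("trial has no markers")
        if not self.plates:
            raise TrialIOError("trial has no force plates")
        if self.rate_kin <= 0:
            raise TrialIOError(f"rate_kin must be > 0, got {self.rate_kin}")
        if self.rate_force < self.rate_kin:
            raise TrialIOError("rate_force must be >= rate_kin")
        ratio = self.rate_force / self.rate_kin
        if abs(ratio - round(ratio)) > 1e-9:
            raise TrialIOError(
                f"rate_force/rate_kin must be an integer, got {ratio:.6g}")
        missing = [m for m in REQUIRED_MARKERS if m not in self.markers]
        if missing:
            raise TrialIOError(f"missing required markers: {missing}")
        n = {v.shape[0] for v in self.markers.values()}
        if len(n) != 1:
            raise TrialIOError("marker streams have unequal lengths")
        for label, arr in self.markers.items():
            if np.isnan(arr).any():
                raise TrialIOError(f"marker {label} still has missing frames")
        nf = {v.shape[0] for v in self.plates.values()}
        if len(nf) != 1:
            raise TrialIOError("plate streams have unequal lengths")

    def total_vertical_grf(self) -> np.ndarray:
        """Summed vertical force over all plates, at the force rate."""
        return sum(p[:, 1] for p in self.plates.values())

    def time_kin(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate_kin

    def time_force(self) -> np.ndarray:
        return np.arange(self.n_force_samples) / self.rate_force


def fill_marker_gaps(arr: np.ndarray, max_gap: int = MAX_GAP_FRAMES,
                     label: str = "?") -> np.ndarray:
    """Cubic-spline fill of NaN dropouts up to ``max_gap`` frames.

    The spline is fitted through all valid frames of each coordinate, so
    filled samples lie on the cubic interpolant of their neighbours.  Gaps
    longer than ``max_gap`` (or gaps touching either end) raise.
    """
    arr = np.asarray(arr, dtype=float).copy()
    bad = np.isnan(arr).any(axis=1)
    if not bad.any():
        return arr
    # measure each contiguous gap
    idx = np.flatnonzero(bad)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for gap in splits:
        if len(gap) > max_gap:
            raise TrialIOError(
                f"marker {label}: gap of {len(gap)} frames at {gap[0]} "
                f"exceeds the {max_gap}-frame limit")
        if gap[0] == 0 or gap[-1] == arr.shape[0] - 1:
            raise TrialIOError(
                f"marker {label}: gap at the trial boundary cannot be filled")
    good = ~bad
    t = np.arange(arr.shape[0])
    for c in range(arr.shape[1]):
        arr[bad, c] = CubicSpline(t[good], arr[good, c])(t[bad])
    return arr


# ---------------------------------------------------------------------------
# TRC dialect
# ---------------------------------------------------------------------------

def write_trc(path, markers: dict, rate: float, units: str = "mm"):
    labels = list(markers)
    n = markers[labels[0]].shape[0]
    scale = 1000.0 if units == "mm" else 1.0
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{Path(path).name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(labels)}\t{units}\t"
                 f"{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(labels) + "\t\t\t\n")
        comp = "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(labels)))
        fh.write("\t\t" + comp + "\n")
        for i in range(n):
            row = [str(i + 1), f"{i / rate:.6f}"]
            for lab in labels:
                p = markers[lab][i] * scale
                row.extend("" if math.isnan(v) else f"{v:.8g}" for v in p)
            fh.write("\t".join(row) + "\n")


def read_trc(path):
    """Parse a TRC-dialect file; returns (markers in metres, rate)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 5:
        raise TrialIOError(f"{path}: truncated TRC file")
    header_names = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_names, header_vals))
    if "Units" not in header or not header.get("Units"):
        raise TrialIOError(f"{path}: TRC header is missing the Units field")
    units = header["Units"]
    if units not in ("mm", "m"):
        raise TrialIOError(f"{path}: unsupported TRC units {units!r}")
    rate = float(header["DataRate"])
    n_frames = int(header["NumFrames"])
    labels = [s for s in lines[3].split("\t")[2:] if s]
    scale = 1e-3 if units == "mm" else 1.0
    data = np.full((n_frames, 3 * len(labels)), np.nan)
    for i, line in enumerate(lines[5:5 + n_frames]):
        cells = line.split("\t")[2:]
        for j, cell in enumerate(cells[:data.shape[1]]):
            if cell.strip():
                data[i, j] = float(cell)
    markers = {}
    for k, lab in enumerate(labels):
        markers[lab] = fill_marker_gaps(data[:, 3 * k:3 * k + 3] * scale,
                                        label=lab)
    return markers, rate


# ---------------------------------------------------------------------------
# force CSV and subject metadata
# ---------------------------------------------------------------------------

def write_force_csv(path, plate: np.ndarray, rate: float):
    t = np.arange(plate.shape[0]) / rate
    with open(path, "w") as fh:
        fh.write("time_s,Fx_N,Fy_N,COPx_m\n")
        for ti, (fx, fy, cop) in zip(t, plate):
            fh.write(f"{ti:.6f},{fx:.8g},{fy:.8g},{cop:.8g}\n")


def read_force_csv(path):
    raw = np.genfromtxt(path, delimiter=",", names=True)
    if raw.dtype.names is None or "time_s" not in raw.dtype.names:
        raise TrialIOError(f"{path}: force CSV must have a time_s header")
    t = np.atleast_1d(raw["time_s"])
    if t.size < 1:
        raise TrialIOError(f"{path}: empty force file")
    rate = 1.0 / np.mean(np.diff(t)) if t.size > 1 else None
    plate = np.column_stack([np.atleast_1d(raw["Fx_N"]),
                             np.atleast_1d(raw["Fy_N"]),
                             np.atleast_1d(raw["COPx_m"])])
    return plate, rate


def write_subject_yaml(path, subject: SubjectSpec, extra: dict | None = None):
    doc = {"mass_kg": float(subject.mass), "height_m": float(subject.height)}
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_subject_yaml(path) -> SubjectSpec:
    doc = yaml.safe_load(Path(path).read_text())
    try:
        return SubjectSpec(mass=float(doc["mass_kg"]),
                           height=float(doc["height_m"]))
    except (KeyError, TypeError) as exc:
        raise TrialIOError(f"{path}: invalid subject metadata ({exc})") from exc


# ---------------------------------------------------------------------------
# whole-trial round trip
# ---------------------------------------------------------------------------

def write_trial(trial: TrialRecording, out_dir, stem: str = "trial"):
    """Emit TRC + per-plate CSV + subject YAML; returns the file map."""
    trial.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"markers": out_dir / f"{stem}_markers.trc",
             "subject": out_dir / f"{stem}_subject.yaml"}
    write_trc(paths["markers"], trial.markers, trial.rate_kin, units="mm")
    for pid, plate in trial.plates.items():
        p = out_dir / f"{stem}_force_{pid}.csv"
        write_force_csv(p, plate, trial.rate_force)
        paths[f"force_{pid}"] = p
    write_subject_yaml(paths["subject"], trial.subject,
                       extra={"trial_kind": trial.trial_kind,
                              "rate_force_hz": float(trial.rate_force)})
    return paths


def read_trial(marker_path, force_paths: dict, subject_path) -> TrialRecording:
    """Load and validate one trial.

    ``force_paths`` maps plate id (e.g. ``"R"``, ``"L"``) to its CSV path.
    """
    markers, rate_kin = read_trc(marker_path)
    doc = yaml.safe_load(Path(subject_path).read_text())
    subject = read_subject_yaml(subject_path)
    plates = {}
    rate_force = doc.get("rate_force_hz")
    for pid, path in force_paths.items():
        plate, inferred = read_force_csv(path)
        plates[pid] = plate
        if rate_force is None:
            rate_force = inferred
    if rate_force is None:
        raise TrialIOError("force rate could not be determined")
    return TrialRecording(markers=markers, plates=plates, subject=subject,
                          rate_kin=rate_kin, rate_force=float(rate_force),
                          trial_kind=doc.get("trial_kind", "dvj"))
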
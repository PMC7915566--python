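"""Subject anthropometry, segment inertial parameters, and the planar chain.

The whole package works on a sagittal-plane link-segment model of a bilateral
landing: a foot-shank-thigh chain per leg (the two legs move identically and
mirror each other mediolaterally) topped by a pelvis that carries the lumped
head-arms-trunk (HAT) remainder.  Coordinates are x anterior (+), y vertical
up (+), z mediolateral; all joint angles follow the clinical sagittal
conventions used throughout:

* knee flexion positive, 0 deg at full extension;
* hip flexion positive, 0 deg in neutral standing;
* ankle dorsiflexion positive, 0 deg in neutral standing;
* pelvic anterior tilt positive, 0 deg in neutral standing (anterior pelvis
  markers drop below the posterior markers as anterior tilt increases).

Internally poses are described by the CCW orientation angles of each segment:
``a_t`` thigh (hip->knee from straight down, anterior positive), ``a_s`` shank
(knee->ankle), and the foot rotation ``phi`` away from its flat neutral.  The
mapping to joint angles is::

    a_t  = hip - tilt
    a_s  = a_t - knee
    phi  = ankle + a_s

which makes all four joint angles invariant under rigid rotation of the body.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

GRAVITY = 9.81  # m/s^2

#: segment lengths and marker offsets as fractions of standing height,
#: after the classical anthropometric proportionality tables.
LENGTH_FRACTIONS = {
    "thigh": 0.245,        # hip joint centre to knee joint centre
    "shank": 0.246,        # knee joint centre to ankle joint centre
    "ankle_height": 0.039,  # ankle joint centre above the sole
    "toe": 0.112,          # ankle to toe marker, horizontal, anterior
    "heel": 0.040,         # ankle to heel marker, horizontal, posterior
    "pelvis_half_depth": 0.050,   # mid-hip to ASIS/PSIS pair, horizontal
    "pelvis_marker_rise": 0.028,  # pelvis markers above the hip joint centre
    "hat_forward": 0.010,  # HAT CoM offset, pelvis frame, anterior
    "hat_up": 0.180,       # HAT CoM offset, pelvis frame, vertical
    "hip_half_width": 0.055,  # mediolateral hip joint offset (z)
}

_TABLE_FILES = {
    "deLeva1996": "deleva_1996_male.tsv",
    "dempster1955": "dempster_1955.tsv",
}


class ModelError(ValueError):
    """Invalid subject, table, or pose input."""


@dataclass(frozen=True)
class SubjectSpec:
    """A participant: mass in kg, standing height in m.

    Segment lengths default to fixed fractions of height but can be
    overridden per segment through ``segment_lengths``.
    """

    mass: float
    height: float
    segment_lengths: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.mass > 0:
            raise ModelError(f"subject mass must be > 0, got {self.mass}")
        if not self.height > 0:
            raise ModelError(f"subject height must be > 0, got {self.height}")
        lengths = {k: f * self.height for k, f in LENGTH_FRACTIONS.items()}
        lengths.update(self.segment_lengths)
        if any(v <= 0 for v in lengths.values()):
            raise ModelError("all segment lengths must be > 0")
        object.__setattr__(self, "segment_lengths", lengths)

    def length(self, name: str) -> float:
        return self.segment_lengths[name]


def _load_fraction_table(table: str) -> dict:
    try:
        fname = _TABLE_FILES[table]
    except KeyError:
        raise ModelError(
            f"unknown anthropometric table {table!r}; "
            f"valid tables: {sorted(_TABLE_FILES)}"
        ) from None
    rows = {}
    text = resources.files("dvjmech.data").joinpath(fname).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("segment\t"):
            continue
        seg, mf, cf, gf, count = line.split("\t")
        rows[seg] = {
            "mass_fraction": float(mf),
            "com_fraction": float(cf),
            "gyration_fraction": float(gf),
            "count": int(count),
        }
    return rows


@dataclass(frozen=True)
class BodyModel:
    """Per-segment inertial parameters resolved for one subject.

    ``segments`` maps segment name to a dict with mass (kg), CoM fraction
    from the proximal end, length (m), and moment of inertia about the
    segment CoM (kg m^2).
    """

    subject: SubjectSpec
    table: str
    segments: dict

    @property
    def hat_mass(self) -> float:
        return self.segments["hat"]["mass"]


def build_body_model(subject: SubjectSpec, table: str = "deLeva1996") -> BodyModel:
    """Resolve a published fraction table against one subject.

    Raises :class:`ModelError` for an unknown table id.  The bundled tables
    satisfy sum(mass fractions) == 1 to 1e-3 including the HAT remainder.
    """
    fractions = _load_fraction_table(table)
    total = sum(r["mass_fraction"] * r["count"] for r in fractions.values())
    if abs(total - 1.0) > 1e-3:
        raise ModelError(f"mass fractions of table {table} sum to {total:.4f}, not 1")
    seg_length = {
        "foot": subject.length("toe") + subject.length("heel"),
        "shank": subject.length("shank"),
        "thigh": subject.length("thigh"),
        "hat": 0.5 * subject.height,
    }
    segments = {}
    for name, row in fractions.items():
        m = row["mass_fraction"] * subject.mass
        length = seg_length[name]
        r_gyr = row["gyration_fraction"] * length
        segments[name] = {
            "mass": m,
            "com_fraction": row["com_fraction"],
            "gyration_fraction": row["gyration_fraction"],
            "length": length,
            "inertia": m * r_gyr**2,
        }
    return BodyModel(subject=subject, table=table, segments=segments)


def _rot(phi):
    """Apply the CCW rotation of angle phi (rad, array) to offsets later."""
    return np.cos(phi), np.sin(phi)


def forward_kinematics(angles_deg: np.ndarray, subject: SubjectSpec,
                       model: BodyModel, toe_anchor: float = 0.0) -> dict:
    """Planar pose(s) of the chain with the toe pinned to the ground.

    Parameters
    ----------
    angles_deg : array, shape (4,) or (4, n)
        Rows are pelvic tilt, hip flexion, knee flexion, ankle dorsiflexion
        in degrees (clinical conventions above).
    toe_anchor : float
        Ground x position of the pinned toe marker.

    Returns
    -------
    dict of arrays, each shape (2,) or (2, n): joint centres ``toe, heel,
    ankle, knee, hip``, pelvis markers ``asis, psis``, ``pelvis_centroid``,
    segment CoMs ``com_foot/shank/thigh/hat`` and the whole-body ``com``.

    The static neutral pose (all angles zero) stacks the leg vertically with
    a flat foot, which defines every joint's zero.
    """
    ang = np.deg2rad(np.atleast_2d(np.asarray(angles_deg, dtype=float).reshape(4, -1)))
    tilt, hip, knee, ankle = ang
    a_t = hip - tilt
    a_s = a_t - knee
    phi = ankle + a_s

    L_t = subject.length("thigh")
    L_s = subject.length("shank")
    h_a = subject.length("ankle_height")
    d_toe = subject.length("toe")
    d_heel = subject.length("heel")
    p_d = subject.length("pelvis_half_depth")
    p_r = subject.length("pelvis_marker_rise")
    hat_off = np.array([subject.length("hat_forward"), subject.length("hat_up")])

    def rotate(dx, dy, c, s):
        return np.stack([c * dx - s * dy, s * dx + c * dy])

    c_f, s_f = np.cos(phi), np.sin(phi)
    toe = np.stack([np.full_like(phi, toe_anchor), np.zeros_like(phi)])
    ankle_p = toe - rotate(d_toe, -h_a, c_f, s_f)
    heel = ankle_p + rotate(-d_heel, -h_a, c_f, s_f)
    knee_p = ankle_p - L_s * np.stack([np.sin(a_s), -np.cos(a_s)])
    hip_p = knee_p - L_t * np.stack([np.sin(a_t), -np.cos(a_t)])

    # pelvis rotates CW (line dips anteriorly) for positive anterior tilt
    c_p, s_p = np.cos(-tilt), np.sin(-tilt)
    asis = hip_p + rotate(p_d, p_r, c_p, s_p)
    psis = hip_p + rotate(-p_d, p_r, c_p, s_p)
    pelvis_centroid = 0.5 * (asis + psis)

    segs = model.segments
    com_foot = heel + segs["foot"]["com_fraction"] * (toe - heel)
    com_shank = knee_p + segs["shank"]["com_fraction"] * (ankle_p - knee_p)
    com_thigh = hip_p + segs["thigh"]["com_fraction"] * (knee_p - hip_p)
    com_hat = hip_p + rotate(hat_off[0], hat_off[1], c_p, s_p)

    m_f = segs["foot"]["mass"] * 2
    m_s = segs["shank"]["mass"] * 2
    m_t = segs["thigh"]["mass"] * 2
    m_h = segs["hat"]["mass"]
    total = m_f + m_s + m_t + m_h
    com = (m_f * com_foot + m_s * com_shank + m_t * com_thigh + m_h * com_hat) / total

    out = {
        "toe": toe, "heel": heel, "ankle": ankle_p, "knee": knee_p,
        "hip": hip_p, "asis": asis, "psis": psis,
        "pelvis_centroid": pelvis_centroid,
        "com_foot": com_foot, "com_shank": com_shank,
        "com_thigh": com_thigh, "com_hat": com_hat, "com": com,
    }
    if np.ndim(angles_deg) == 1:
        out = {k: v[:, 0] for k, v in out.items()}
    return out
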
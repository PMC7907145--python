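"""Standard 10-10 electrode label sets and template 3-D unit-sphere positions.

Positions are generated analytically on a unit sphere (head apex at z = +1,
+y toward the nasion, +x toward the right ear): each electrode lies on the
arc obtained by rotating the midline point of its row about the naso-inial
axis, with the lateral-most electrode of every row landing on the outer
10-20 circle (polar angle 72 degrees from the vertex).  This reproduces the
familiar 10-10 layout closely enough for topographic mapping and can be
overridden by a user-supplied montage file.
"""

from __future__ import annotations

import math
import re

import numpy as np

#: polar angle (from vertex) of the outer 10-20 circle, radians
_OUTER_POLAR = math.radians(72.0)

# anterior fraction of each row along the nasion -> inion midline arc
_ROW_FRACTION = {
    "FP": 0.1,
    "AF": 0.2,
    "F": 0.3,
    "FT": 0.4,
    "FC": 0.4,
    "T": 0.5,
    "C": 0.5,
    "TP": 0.6,
    "CP": 0.6,
    "P": 0.7,
    "PO": 0.8,
    "O": 0.9,
}

#: the four ocular channels recorded alongside the scalp montage
OCULAR_LABELS = ("HEOGL", "HEOGR", "VEOGL", "VEOGU")

# fixed unit-sphere stand-ins near the eyes (polar angle, azimuth-from-front), degrees
_OCULAR_ANGLES = {
    "HEOGL": (100.0, -35.0),
    "HEOGR": (100.0, 35.0),
    "VEOGL": (105.0, -12.0),
    "VEOGU": (82.0, -12.0),
}

DEFAULT_60_LABELS = (
    "Fp1", "Fpz", "Fp2",
    "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

DEFAULT_64_LABELS = DEFAULT_60_LABELS + OCULAR_LABELS

#: compact montage for fast desk-scale experiments (7 frontal, 4 central, 5 posterior)
SMALL_16_LABELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "C3", "Cz", "C4",
    "P7", "P3", "Pz", "P4",
    "O1", "O2",
)

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|Z|\d+)$")


def _sph(polar_deg: float, azim_deg: float) -> np.ndarray:
    """Unit vector from polar angle (from +z) and azimuth measured from +y (front)."""
    th = math.radians(polar_deg)
    az = math.radians(azim_deg)
    return np.array([math.sin(th) * math.sin(az), math.sin(th) * math.cos(az), math.cos(th)])


def _parse(label: str) -> tuple[str, int]:
    """Split a 10-10 label into (row prefix, signed column index).

    Column index: 0 on the midline, negative left (odd numbers), positive
    right (even numbers); magnitude 1..4 moving laterally.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse 10-10 label {label!r}")
    row = m.group(1).upper()
    suffix = m.group(2)
    if row not in _ROW_FRACTION:
        raise ValueError(f"unknown 10-10 row in label {label!r}")
    if suffix.lower() == "z":
        return row, 0
    num = int(suffix)
    col = (num + 1) // 2
    if row in ("T", "FT", "TP") or (row in ("F", "P") and num in (7, 8)):
        col = 4  # temporal line / lateral-most F- and P-row electrodes
    elif row in ("FP", "O"):
        col = 1
    return row, (-col if num % 2 == 1 else col)


def position_for(label: str) -> np.ndarray:
    """Template unit-sphere position for one 10-10 (or ocular) label."""
    if label.upper() in _OCULAR_ANGLES:
        return _sph(*_OCULAR_ANGLES[label.upper()])
    row, col = _parse(label)
    frac = _ROW_FRACTION[row]
    a = (0.5 - frac) * math.pi  # signed midline angle from vertex, >0 anterior
    if row in ("FP", "O"):
        # outer-circle rows: spaced at 18 degrees of azimuth on the 72-degree circle
        base = 0.0 if frac < 0.5 else 180.0
        step = 18.0 if frac < 0.5 else -18.0
        return _sph(72.0, base + step * col)
    mid = np.array([0.0, math.sin(a), math.cos(a)])
    if col == 0:
        return mid
    cos_beta_max = math.cos(_OUTER_POLAR) / math.cos(a)
    beta_max = math.acos(min(1.0, max(-1.0, cos_beta_max)))
    beta = beta_max * col / 4.0
    # rotation about the naso-inial (y) axis
    return np.array([math.cos(a) * math.sin(beta), math.sin(a), math.cos(a) * math.cos(beta)])


def standard_positions(labels) -> np.ndarray:
    """(n, 3) template positions for a sequence of labels."""
    return np.vstack([position_for(lab) for lab in labels])
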